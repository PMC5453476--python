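"""Core data model for time-normalized gait curves.

Conventions
-----------
A gait cycle spans 0-100% with initial contact at 0%; every curve is
sampled at 2% increments, giving 51 points.  Stance covers [0, toe_off]
and swing [toe_off, 100], both closed (the boundary sample is shared).
Knee flexion and ankle dorsiflexion additionally carry stance- and
swing-normalized curves (51 points over each sub-phase), because the
knee/ankle joint-motion patterns are defined on those sub-phases.

Angles are in degrees with the following positive directions: anterior
pelvic tilt, pelvic elevation, internal rotation (pelvis, hip and foot
progression), hip/knee flexion, hip adduction, ankle dorsiflexion.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

N_SAMPLES = 51
GRID = np.linspace(0.0, 100.0, N_SAMPLES)


class ValidationError(ValueError):
    """Raised when input data violates the data-model contracts."""


class InsufficientDataError(ValueError):
    """Raised when there is not enough data to compute a statistic."""


class Track(str, enum.Enum):
    """The nine kinematic angle tracks."""

    PELVIC_TILT = "pelvic_tilt"
    PELVIC_OBLIQUITY = "pelvic_obliquity"
    PELVIC_ROTATION = "pelvic_rotation"
    HIP_FLEXION = "hip_flexion"
    HIP_ABDUCTION = "hip_abduction"
    HIP_ROTATION = "hip_rotation"
    KNEE_FLEXION = "knee_flexion"
    ANKLE_DORSIFLEXION = "ankle_dorsiflexion"
    FOOT_PROGRESSION = "foot_progression"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Domain(str, enum.Enum):
    FULL_CYCLE = "full_cycle"
    STANCE = "stance"
    SWING = "swing"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Tracks that carry stance- and swing-normalized curves in addition to
#: the full-cycle curve.
PHASE_TRACKS = (Track.KNEE_FLEXION, Track.ANKLE_DORSIFLEXION)


@dataclass(frozen=True)
class JointMotionDef:
    """One of the eleven classified joint motions."""

    code: str
    classes: tuple[str, ...]
    source_track: Track
    normalization: Domain


def _jm(code, n, track, domain):
    return JointMotionDef(code, tuple(f"{code}{i}" for i in range(n)), track, domain)


#: The eleven joint motions with their pattern classes (the two
#: stance-knee patterns that differ only in kinetics are merged, hence
#: six stance-knee classes).
JOINT_MOTIONS: dict[str, JointMotionDef] = {
    jm.code: jm
    for jm in (
        _jm("PS", 6, Track.PELVIC_TILT, Domain.FULL_CYCLE),
        _jm("HS", 3, Track.HIP_FLEXION, Domain.FULL_CYCLE),
        _jm("KSTS", 6, Track.KNEE_FLEXION, Domain.STANCE),
        _jm("KSWS", 6, Track.KNEE_FLEXION, Domain.SWING),
        _jm("ASTS", 5, Track.ANKLE_DORSIFLEXION, Domain.STANCE),
        _jm("ASWS", 4, Track.ANKLE_DORSIFLEXION, Domain.SWING),
        _jm("PC", 4, Track.PELVIC_OBLIQUITY, Domain.FULL_CYCLE),
        _jm("HC", 4, Track.HIP_ABDUCTION, Domain.FULL_CYCLE),
        _jm("PT", 4, Track.PELVIC_ROTATION, Domain.FULL_CYCLE),
        _jm("HT", 3, Track.HIP_ROTATION, Domain.FULL_CYCLE),
        _jm("FPA", 3, Track.FOOT_PROGRESSION, Domain.FULL_CYCLE),
    )
}

#: Observed clinical prevalence (%) of each pattern class, used as the
#: default class prior of the synthetic generator.
CLASS_FREQUENCIES: dict[str, dict[str, float]] = {
    "PS": {"PS0": 16.3, "PS1": 29.4, "PS2": 16.0, "PS3": 35.8, "PS4": 1.4, "PS5": 1.0},
    "HS": {"HS0": 55.4, "HS1": 27.5, "HS2": 17.1},
    "KSTS": {"KSTS0": 15.9, "KSTS1": 8.1, "KSTS2": 25.4, "KSTS3": 8.0,
             "KSTS4": 10.8, "KSTS5": 31.8},
    "KSWS": {"KSWS0": 35.4, "KSWS1": 21.5, "KSWS2": 12.6, "KSWS3": 9.4,
             "KSWS4": 10.8, "KSWS5": 10.2},
    "ASTS": {"ASTS0": 38.6, "ASTS1": 27.9, "ASTS2": 9.4, "ASTS3": 4.2, "ASTS4": 19.8},
    "ASWS": {"ASWS0": 40.0, "ASWS1": 6.7, "ASWS2": 18.6, "ASWS3": 34.7},
    "PC": {"PC0": 48.5, "PC1": 29.1, "PC2": 11.8, "PC3": 10.6},
    "HC": {"HC0": 62.8, "HC1": 21.6, "HC2": 9.2, "HC3": 6.5},
    "PT": {"PT0": 44.5, "PT1": 30.3, "PT2": 13.0, "PT3": 12.2},
    "HT": {"HT0": 75.3, "HT1": 9.0, "HT2": 15.7},
    "FPA": {"FPA0": 66.4, "FPA1": 15.6, "FPA2": 17.9},
}


def _as_curve(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.shape[0] != N_SAMPLES:
        raise ValidationError(
            f"a gait curve must have exactly {N_SAMPLES} samples, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError("gait curve contains non-finite values")
    return arr


@dataclass(frozen=True)
class GaitCurve:
    """A 51-sample angle curve over its normalization domain."""

    values: np.ndarray
    domain: Domain

    def __post_init__(self):
        object.__setattr__(self, "values", _as_curve(self.values))
        object.__setattr__(self, "domain", Domain(self.domain))


@dataclass
class GaitTrial:
    """One limb's gait cycle: curves, identifiers and pattern labels.

    ``curves`` maps ``(track, domain)`` to a 51-sample array.  All nine
    tracks must be present with full-cycle curves; knee flexion and
    ankle dorsiflexion must also carry stance and swing curves.
    ``labels`` maps joint-motion codes to pattern codes; a missing
    label simply excludes the trial from that joint motion's analysis.
    """

    trial_id: str
    session_id: str
    patient_id: str
    toe_off_pct: float
    curves: dict[tuple[Track, Domain], np.ndarray]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.patient_id:
            raise ValidationError(f"trial {self.trial_id!r}: empty patient_id")
        if not 0.0 < self.toe_off_pct < 100.0:
            raise ValidationError(
                f"trial {self.trial_id!r}: toe_off_pct must be in (0, 100), "
                f"got {self.toe_off_pct}"
            )
        curves = {}
        for key, values in self.curves.items():
            track, domain = Track(key[0]), Domain(key[1])
            curves[(track, domain)] = _as_curve(values)
        self.curves = curves
        for track in Track:
            if (track, Domain.FULL_CYCLE) not in self.curves:
                raise ValidationError(
                    f"trial {self.trial_id!r}: missing full-cycle curve for {track.value}"
                )
        for track in PHASE_TRACKS:
            for domain in (Domain.STANCE, Domain.SWING):
                if (track, domain) not in self.curves:
                    raise ValidationError(
                        f"trial {self.trial_id!r}: missing {domain.value} curve "
                        f"for {track.value}"
                    )
        for jm_code, pattern in self.labels.items():
            if jm_code not in JOINT_MOTIONS:
                raise ValidationError(
                    f"trial {self.trial_id!r}: unknown joint motion {jm_code!r}"
                )
            if pattern not in JOINT_MOTIONS[jm_code].classes:
                raise ValidationError(
                    f"trial {self.trial_id!r}: unknown pattern code {pattern!r} "
                    f"for joint motion {jm_code}"
                )

    def curve(self, track: Track, domain: Domain = Domain.FULL_CYCLE) -> np.ndarray:
        return self.curves[(Track(track), Domain(domain))]


@dataclass
class Dataset:
    """A collection of gait trials grouped by patient."""

    trials: list[GaitTrial]

    def __post_init__(self):
        seen = set()
        for t in self.trials:
            if t.trial_id in seen:
                raise ValidationError(f"duplicate trial_id {t.trial_id!r}")
            seen.add(t.trial_id)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def patients(self) -> dict[str, list[GaitTrial]]:
        out: dict[str, list[GaitTrial]] = {}
        for t in self.trials:
            out.setdefault(t.patient_id, []).append(t)
        return out

    def labeled(self, jm_code: str) -> list[GaitTrial]:
        """Trials carrying a ground-truth label for the given joint motion."""
        return [t for t in self.trials if jm_code in t.labels]


@dataclass
class NormativeBand:
    """Mean +/- SD reference envelope from a typically developing cohort.

    ``mean``/``sd`` map ``(track, domain)`` to 51-sample curves; the
    scalar summaries hold the across-subject mean and SD of each
    track's cycle-averaged angle, used by the band-flag features.
    """

    mean: dict[tuple[Track, Domain], np.ndarray]
    sd: dict[tuple[Track, Domain], np.ndarray]
    cycle_mean_mean: dict[Track, float]
    cycle_mean_sd: dict[Track, float]

    def __post_init__(self):
        for key in self.mean:
            m, s = _as_curve(self.mean[key]), _as_curve(self.sd[key])
            if np.any(s <= 0):
                raise ValidationError(
                    f"normative band for {key}: sd curve must be strictly positive"
                )
            self.mean[key], self.sd[key] = m, s

    def curves(self, track: Track, domain: Domain = Domain.FULL_CYCLE):
        key = (Track(track), Domain(domain))
        return self.mean[key], self.sd[key]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def resample_curve(samples, domain: Domain = Domain.FULL_CYCLE) -> np.ndarray:
    """Linearly resample a uniformly spaced angle sequence to 51 points.

    The input is assumed to span the whole domain (its first and last
    samples sit at 0% and 100%); endpoints are preserved exactly.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 1 or arr.shape[0] < 2:
        raise ValidationError("resample_curve requires at least 2 samples")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("resample_curve: non-finite input samples")
    if arr.shape[0] == N_SAMPLES:
        return arr.copy()
    src = np.linspace(0.0, 100.0, arr.shape[0])
    return np.interp(GRID, src, arr)


def phase_split(full_cycle, toe_off_pct: float) -> tuple[np.ndarray, np.ndarray]:
    """Split a full-cycle curve into 51-sample stance and swing curves.

    Stance covers [0, toe_off], swing [toe_off, 100]; each sub-curve is
    re-interpolated to 51 uniform samples over its own phase.
    """
    curve = _as_curve(full_cycle)
    if not 0.0 < toe_off_pct < 100.0:
        raise ValidationError(f"toe_off_pct must be in (0, 100), got {toe_off_pct}")
    stance_t = np.linspace(0.0, toe_off_pct, N_SAMPLES)
    swing_t = np.linspace(toe_off_pct, 100.0, N_SAMPLES)
    stance = np.interp(stance_t, GRID, curve)
    swing = np.interp(swing_t, GRID, curve)
    return stance, swing


def sample_at_pct(curve, pct: float) -> float:
    """Linearly interpolated curve value at a percentage of its domain."""
    arr = _as_curve(curve)
    if not 0.0 <= pct <= 100.0:
        raise ValidationError(f"pct must be in [0, 100], got {pct}")
    return float(np.interp(pct, GRID, arr))


def compute_normative_band(reference: Dataset, sd_floor: float = 0.5) -> NormativeBand:
    """Pointwise mean/SD band and cycle-mean summaries from a reference cohort.

    SD values of zero (degenerate, identical reference trials) are
    replaced by ``sd_floor`` degrees with a logged warning so that
    band-exceedance features remain defined.
    """
    if len(reference) < 2:
        raise InsufficientDataError(
            "at least 2 reference trials are required to compute a normative band"
        )
    keys = [(t, Domain.FULL_CYCLE) for t in Track]
    keys += [(t, d) for t in PHASE_TRACKS for d in (Domain.STANCE, Domain.SWING)]
    mean, sd = {}, {}
    for key in keys:
        stack = np.stack([t.curves[key] for t in reference.trials])
        mean[key] = stack.mean(axis=0)
        s = stack.std(axis=0, ddof=1)
        if np.any(s <= 0):
            logger.warning(
                "zero SD in normative band for %s/%s; applying floor of %g deg",
                key[0].value, key[1].value, sd_floor,
            )
            s = np.maximum(s, sd_floor)
        sd[key] = s
    cmm, cms = {}, {}
    for track in Track:
        means = np.array(
            [t.curves[(track, Domain.FULL_CYCLE)].mean() for t in reference.trials]
        )
        cmm[track] = float(means.mean())
        s = float(means.std(ddof=1))
        if s <= 0:
            logger.warning(
                "zero cycle-mean SD for %s; applying floor of %g deg",
                track.value, sd_floor,
            )
            s = max(s, sd_floor)
        cms[track] = s
    return NormativeBand(mean=mean, sd=sd, cycle_mean_mean=cmm, cycle_mean_sd=cms)
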