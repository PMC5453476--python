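"""Synthetic gait-data generator.

Produces labeled cerebral-palsy-like datasets and a typically
developing (TD) reference cohort with the statistical structure the
classification pipeline assumes, replacing the non-public clinical
database.

Design
------
Each of the nine angle tracks has an analytic normative template
(shape-preserving cubics through anatomically plausible knots, or
low-order sinusoids).  Every pattern class of every joint motion is a
documented deformation of the source track's template -- offsets,
range-of-motion scaling, timing shifts and localized bumps -- calibrated
so that, noise-free, each expert feature lands at the midpoint of the
bin named by the pattern's clinical description (or, for localized
deformations, at a margin-maximizing point well inside that bin).
Distinct classes of a joint motion therefore map to distinct expert-bin
combinations and are separable by construction.

Variability has three layers, all smooth in time:

* between-subject spread of the TD cohort (constant offset per track
  plus low-order harmonics), which fixes the width of the normative
  band;
* a per-patient effect (offset plus a small shape component);
* per-trial noise (small offset plus up to ``noise_harmonics`` random
  harmonics).

Pattern codes are drawn once per patient session (a child's pattern
does not flip between consecutive trials) and independently across
joint motions.  Knee and ankle full-cycle curves are assembled from the
stance-pattern and swing-pattern sub-curves at the trial's toe-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .core import (
    CLASS_FREQUENCIES,
    Dataset,
    Domain,
    GaitTrial,
    GRID,
    JOINT_MOTIONS,
    PHASE_TRACKS,
    Track,
)

# ---------------------------------------------------------------------------
# Normative templates
# ---------------------------------------------------------------------------

_TWO_PI = 2.0 * np.pi
_T = GRID  # 0..100 in 2% steps


def _pchip(knots: list[tuple[float, float]]) -> np.ndarray:
    x, y = zip(*knots)
    return PchipInterpolator(np.asarray(x, float), np.asarray(y, float))(_T)


def _sine(mean: float, amplitude: float, cycles: float, phase: float = 0.0) -> np.ndarray:
    return mean + amplitude * np.sin(_TWO_PI * cycles * _T / 100.0 + phase)


#: Stance/swing-phase templates for the knee and ankle (51 samples over
#: the respective phase).
_PHASE_TEMPLATE_KNOTS = {
    (Track.KNEE_FLEXION, Domain.STANCE): [
        (0, 5), (12, 10), (25, 18), (40, 11), (70, 3), (100, 38)],
    (Track.KNEE_FLEXION, Domain.SWING): [
        (0, 38), (13, 50), (25, 60), (40, 49), (100, 8)],
    (Track.ANKLE_DORSIFLEXION, Domain.STANCE): [
        (0, 0), (20, -15.2), (80, 10), (100, -15)],
    (Track.ANKLE_DORSIFLEXION, Domain.SWING): [
        (0, -15), (30, 1), (60, 2), (100, 2)],
}

DEFAULT_TOE_OFF = 60.0


def phase_template(track: Track, domain: Domain) -> np.ndarray:
    """Noise-free stance or swing template for the knee or ankle."""
    return _pchip(_PHASE_TEMPLATE_KNOTS[(Track(track), Domain(domain))])


def _assemble_full_cycle(stance: np.ndarray, swing: np.ndarray,
                         toe_off: float) -> np.ndarray:
    """Join phase curves into a full-cycle curve on the 2% grid."""
    out = np.empty_like(_T)
    st = _T <= toe_off
    out[st] = np.interp(100.0 * _T[st] / toe_off, _T, stance)
    sw = ~st
    out[sw] = np.interp(100.0 * (_T[sw] - toe_off) / (100.0 - toe_off), _T, swing)
    return out


def normative_template(track: Track) -> np.ndarray:
    """Noise-free full-cycle template curve for a track (degrees)."""
    track = Track(track)
    if track is Track.PELVIC_TILT:
        # near-constant anterior tilt with a small double bump (ROM 2 deg)
        return _sine(12.0, 1.0, 2.0)
    if track is Track.PELVIC_OBLIQUITY:
        return _sine(0.0, 2.0, 2.0, np.pi / 6)
    if track is Track.PELVIC_ROTATION:
        return _sine(0.0, 4.0, 1.0)
    if track is Track.HIP_FLEXION:
        # flexed at initial contact, peak extension ~40% GC, peak flexion ~90%
        return 7.5 + 17.5 * np.cos(_TWO_PI * (_T - 90.0) / 100.0)
    if track is Track.HIP_ABDUCTION:
        return _sine(0.0, 1.5, 1.0, -0.5)
    if track is Track.HIP_ROTATION:
        return _sine(5.0, 3.0, 1.0)
    if track is Track.FOOT_PROGRESSION:
        return _sine(-5.0, 2.0, 1.0)
    # knee and ankle: double-bump / three-rocker profiles from the phase
    # templates, joined at the default toe-off
    stance = phase_template(track, Domain.STANCE)
    swing = phase_template(track, Domain.SWING)
    return _assemble_full_cycle(stance, swing, DEFAULT_TOE_OFF)


# ---------------------------------------------------------------------------
# Pattern templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternTemplate:
    """Deformation of the source track's template for one pattern class.

    ``offset`` shifts the whole curve; ``rom_scale`` scales it about its
    mean (leaving the cycle average unchanged); ``knots``, when given,
    replace the phase template entirely (knee/ankle patterns);
    ``bump``/``dip`` add a localized deviation.
    """

    joint_motion: str
    pattern_code: str
    offset: float = 0.0
    rom_scale: float = 1.0
    knots: tuple[tuple[float, float], ...] | None = None
    # (center, width) Gaussian bump of given amplitude, full-cycle tracks
    bump: tuple[float, float, float] | None = None  # (center, width, amplitude)
    # plateau window (start, end, edge, depth): raised-cosine edged dip
    window: tuple[float, float, float, float] | None = None

    def apply(self, base: np.ndarray) -> np.ndarray:
        curve = base if self.knots is None else _pchip(list(self.knots))
        if self.rom_scale != 1.0:
            m = curve.mean()
            curve = m + self.rom_scale * (curve - m)
        if self.bump is not None:
            c, w, a = self.bump
            curve = curve + a * np.exp(-(((_T - c) / w) ** 2))
        if self.window is not None:
            t0, t1, edge, depth = self.window
            w = np.clip(np.minimum((_T - t0) / edge, (t1 - _T) / edge), 0.0, 1.0)
            curve = curve + depth * 0.5 * (1.0 - np.cos(np.pi * w * 1.0)) * (w > 0)
        return curve + self.offset


def _interval_templates(jm: str, spec: dict[str, dict]) -> dict[str, PatternTemplate]:
    return {
        code: PatternTemplate(joint_motion=jm, pattern_code=code, **kwargs)
        for code, kwargs in spec.items()
    }


#: Offset (deg) used by every pattern whose signature is a band flag;
#: 12 deg sits well beyond the TD cohort's cycle-mean SD (5 deg).
FLAG_OFFSET = 12.0

# Full-cycle track pattern deformations.  ROM targets are the midpoints
# of the "increased range" bins; offsets are +/-FLAG_OFFSET.
PATTERN_TEMPLATES: dict[str, dict[str, PatternTemplate]] = {
    "PS": _interval_templates("PS", {
        "PS0": {},
        "PS1": {"rom_scale": 14.2 / 2.0},
        "PS2": {"offset": FLAG_OFFSET},
        "PS3": {"offset": FLAG_OFFSET, "rom_scale": 14.2 / 2.0},
        "PS4": {"offset": -FLAG_OFFSET},
        "PS5": {"offset": -FLAG_OFFSET, "rom_scale": 14.2 / 2.0},
    }),
    "PC": _interval_templates("PC", {
        "PC0": {},
        "PC1": {"rom_scale": 19.4 / 4.0},
        "PC2": {"offset": FLAG_OFFSET},
        "PC3": {"offset": -FLAG_OFFSET},
    }),
    "PT": _interval_templates("PT", {
        "PT0": {},
        "PT1": {"rom_scale": 35.5 / 8.0},
        "PT2": {"offset": -FLAG_OFFSET},   # excessive external rotation
        "PT3": {"offset": FLAG_OFFSET},    # excessive internal rotation
    }),
    "HT": _interval_templates("HT", {
        "HT0": {},
        "HT1": {"offset": -FLAG_OFFSET},
        "HT2": {"offset": FLAG_OFFSET},
    }),
    "FPA": _interval_templates("FPA", {
        "FPA0": {},
        "FPA1": {"offset": -FLAG_OFFSET},  # out-toeing (external)
        "FPA2": {"offset": FLAG_OFFSET},   # in-toeing (internal)
    }),
    "HS": _interval_templates("HS", {
        "HS0": {},
        # extension deficit: lift the midstance extension trough
        "HS1": {"bump": (40.0, 16.0, 18.0)},
        # continuous excessive flexion
        "HS2": {"offset": FLAG_OFFSET},
    }),
    "HC": _interval_templates("HC", {
        "HC0": {},
        # excessive abduction in swing only (plateau dip over ~80% of swing;
        # deep enough that >50% of swing sits below the -1SD band under
        # noise, shallow enough not to trip the cycle-mean below flag)
        "HC1": {"window": (64.0, 100.0, 6.0, -11.0)},
        "HC2": {"offset": -FLAG_OFFSET},   # continuous excessive abduction
        "HC3": {"offset": FLAG_OFFSET},    # continuous excessive adduction
    }),
    # Knee/ankle phase patterns replace the phase template with their
    # own knots; feature-defining knots sit at target bin midpoints.
    "KSTS": _interval_templates("KSTS", {
        "KSTS0": {"knots": ((0, 5), (12, 10), (25, 18), (40, 11), (70, 3), (100, 38))},
        "KSTS1": {"knots": ((0, 45.3), (20, 52), (35, 45), (60, 10), (80, 3), (100, 38))},
        "KSTS2": {"knots": ((0, 45.3), (30, 15), (60, 3), (80, 3), (100, 38))},
        "KSTS3": {"knots": ((0, 5), (12, 10), (25, 18), (45, 0), (65, -18.4), (100, 38))},
        "KSTS4": {"knots": ((0, 45.3), (30, 5), (60, -18.4), (80, -10), (100, 38))},
        "KSTS5": {"knots": ((0, 45.3), (20, 52), (35, 47), (70, 38.95), (100, 55))},
    }),
    "KSWS": _interval_templates("KSWS", {
        "KSWS0": {"knots": ((0, 38), (13, 50), (25, 60), (40, 49), (100, 8))},
        "KSWS1": {"knots": ((0, 38), (50, 49), (67, 60), (82, 49), (100, 8))},
        "KSWS2": {"knots": ((0, 38), (13, 65), (25, 82.5), (40, 65), (100, 8))},
        "KSWS3": {"knots": ((0, 38), (50, 60), (67, 82.5), (82, 60), (100, 8))},
        "KSWS4": {"knots": ((0, 15), (13, 24), (25, 29.7), (40, 22), (100, 5))},
        "KSWS5": {"knots": ((0, 12), (50, 20), (67, 29.7), (82, 20), (100, 5))},
    }),
    "ASTS": _interval_templates("ASTS", {
        # knots put both SRA (v80-v20) and the stance maximum exactly at
        # their intended bin midpoints
        "ASTS0": {"knots": ((0, 0), (20, -15.2), (80, 10), (100, -15))},
        "ASTS1": {"knots": ((0, 0), (20, 3.05), (80, 10), (100, -15))},
        "ASTS2": {"knots": ((0, 0), (20, 10), (80, -3.25), (100, -18))},
        "ASTS3": {"knots": ((0, -28), (20, -26.95), (80, -20), (100, -30))},
        "ASTS4": {"knots": ((0, 6), (20, 3.8), (80, 29), (100, 10))},
    }),
    "ASWS": _interval_templates("ASWS", {
        "ASWS0": {"knots": ((0, -15), (30, 1), (60, 2), (100, 2))},
        "ASWS1": {"knots": ((0, -15), (30, 1), (60, 2), (80, 0), (100, -21.6))},
        "ASWS2": {"knots": ((0, -20), (30, -19), (60, -20), (100, -21.6))},
        "ASWS3": {"knots": ((0, -5), (30, 11), (60, 12), (100, 12))},
    }),
}


def pattern_curve(jm_code: str, pattern_code: str) -> np.ndarray:
    """Noise-free curve (51 samples, joint motion's domain) for a pattern."""
    jm = JOINT_MOTIONS[jm_code]
    tmpl = PATTERN_TEMPLATES[jm_code][pattern_code]
    if jm.normalization is Domain.FULL_CYCLE:
        base = normative_template(jm.source_track)
    else:
        base = phase_template(jm.source_track, jm.normalization)
    return tmpl.apply(base)


# ---------------------------------------------------------------------------
# Trial-count distribution (2..15 trials per session, mean 4)
# ---------------------------------------------------------------------------

TRIALS_MIN, TRIALS_MAX = 2, 15


def _truncated_geometric_probs(mean: float) -> np.ndarray:
    """Probabilities of a geometric distribution truncated to 2..15 with
    the requested mean."""
    k = np.arange(TRIALS_MIN, TRIALS_MAX + 1)

    def m(q):
        w = q ** (k - TRIALS_MIN)
        return (k * w).sum() / w.sum() - mean

    q = brentq(m, 1e-9, 1.0 - 1e-9)
    w = q ** (k - TRIALS_MIN)
    return w / w.sum()


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions of the synthetic study.

    Defaults mirror the clinical study's printed configuration: class
    priors at the observed pattern prevalences, 2-15 trials per session
    with mean 4 (truncated geometric), and a 275/67/14-out-of-356 split
    of patients with one/two/three sessions.  Noise magnitudes are the
    package's own calibration (documented in the methods note).
    """

    n_patients: int = 200
    seed: int = 0
    #: probabilities of a patient having 1, 2 or 3 sessions
    session_probs: tuple[float, ...] = (275 / 356, 67 / 356, 14 / 356)
    mean_trials_per_session: float = 4.0
    class_prior: dict[str, dict[str, float]] = field(default_factory=dict)
    patient_effect_sd: float = 1.5
    trial_noise_sd: float = 1.0
    noise_harmonics: int = 3
    toe_off_mean: float = DEFAULT_TOE_OFF
    toe_off_sd: float = 2.0

    def priors(self) -> dict[str, np.ndarray]:
        """Renormalized class prior per joint motion, in class order."""
        out = {}
        for jm_code, jm in JOINT_MOTIONS.items():
            freq = self.class_prior.get(jm_code) or CLASS_FREQUENCIES[jm_code]
            if set(freq) != set(jm.classes):
                raise ValueError(
                    f"class prior for {jm_code} must cover exactly {jm.classes}"
                )
            p = np.array([freq[c] for c in jm.classes], dtype=float)
            if np.any(p < 0) or p.sum() <= 0:
                raise ValueError(f"invalid class prior for {jm_code}")
            out[jm_code] = p / p.sum()
        return out

    def trial_count_probs(self) -> np.ndarray:
        return _truncated_geometric_probs(self.mean_trials_per_session)


def _smooth_noise(rng: np.random.Generator, sd: float, n_harmonics: int) -> np.ndarray:
    """Zero-mean smooth noise curve: sum of <=n random low-order harmonics
    with 1/m amplitude decay, scaled to the requested time-domain SD."""
    if sd <= 0 or n_harmonics < 1:
        return np.zeros_like(_T)
    m = np.arange(1, n_harmonics + 1)[:, None]
    w = 1.0 / m
    c = rng.standard_normal((n_harmonics, 1))
    s = rng.standard_normal((n_harmonics, 1))
    curve = (w * (c * np.cos(_TWO_PI * m * _T / 100.0)
                  + s * np.sin(_TWO_PI * m * _T / 100.0))).sum(axis=0)
    scale = sd / np.sqrt((w ** 2).sum())
    return scale * curve


# fraction of each noise SD assigned to a constant offset vs shape
_PATIENT_OFFSET_FRAC = 1.0
_PATIENT_SHAPE_SD = 0.3
_TRIAL_OFFSET_FRAC = 0.5
_TRIAL_SHAPE_FRAC = 0.8

_ALL_CURVE_KEYS = [(t, Domain.FULL_CYCLE) for t in Track] + [
    (t, d) for t in PHASE_TRACKS for d in (Domain.STANCE, Domain.SWING)
]


def _noise_curves(rng, offset_sd, shape_sd, n_harmonics):
    """Per-track offset plus smooth shape noise for every curve key.

    Phase curves of a track share the track's offset but draw their own
    shape component (stance and swing are measured independently)."""
    offsets = {t: rng.normal(0.0, offset_sd) if offset_sd > 0 else 0.0 for t in Track}
    out = {}
    for key in _ALL_CURVE_KEYS:
        out[key] = offsets[key[0]] + _smooth_noise(rng, shape_sd, n_harmonics)
    return out


def generate_reference_cohort(
    n: int = 56,
    seed: int = 0,
    offset_sd: float = 5.0,
    shape_sd: float = 0.8,
    n_harmonics: int = 3,
) -> Dataset:
    """TD reference cohort: one trial per child, all labels normal.

    ``offset_sd`` controls the between-subject spread of the cohort and
    therefore the width of the normative band.
    """
    if n < 2:
        raise ValueError("a reference cohort needs at least 2 children")
    rng = np.random.default_rng(seed)
    base = {
        (t, Domain.FULL_CYCLE): normative_template(t) for t in Track
    }
    for t in PHASE_TRACKS:
        for d in (Domain.STANCE, Domain.SWING):
            base[(t, d)] = phase_template(t, d)
    normal_labels = {code: jm.classes[0] for code, jm in JOINT_MOTIONS.items()}
    trials = []
    for i in range(n):
        noise = _noise_curves(rng, offset_sd, shape_sd, n_harmonics)
        toe_off = float(np.clip(rng.normal(DEFAULT_TOE_OFF, 1.5), 55.0, 65.0))
        curves = {}
        for t in Track:
            if t not in PHASE_TRACKS:
                curves[(t, Domain.FULL_CYCLE)] = (
                    base[(t, Domain.FULL_CYCLE)] + noise[(t, Domain.FULL_CYCLE)]
                )
        for t in PHASE_TRACKS:
            st = base[(t, Domain.STANCE)] + noise[(t, Domain.STANCE)]
            sw = base[(t, Domain.SWING)] + noise[(t, Domain.SWING)]
            curves[(t, Domain.STANCE)] = st
            curves[(t, Domain.SWING)] = sw
            curves[(t, Domain.FULL_CYCLE)] = _assemble_full_cycle(st, sw, toe_off)
        trials.append(
            GaitTrial(
                trial_id=f"ref{i:03d}",
                session_id=f"ref{i:03d}-s1",
                patient_id=f"refsubj{i:03d}",
                toe_off_pct=toe_off,
                curves=curves,
                labels=dict(normal_labels),
            )
        )
    return Dataset(trials)


#: joint motions whose pattern curve replaces each curve key
_FULL_CYCLE_JM = {
    Track.PELVIC_TILT: "PS",
    Track.PELVIC_OBLIQUITY: "PC",
    Track.PELVIC_ROTATION: "PT",
    Track.HIP_FLEXION: "HS",
    Track.HIP_ABDUCTION: "HC",
    Track.HIP_ROTATION: "HT",
    Track.FOOT_PROGRESSION: "FPA",
}
_PHASE_JM = {
    (Track.KNEE_FLEXION, Domain.STANCE): "KSTS",
    (Track.KNEE_FLEXION, Domain.SWING): "KSWS",
    (Track.ANKLE_DORSIFLEXION, Domain.STANCE): "ASTS",
    (Track.ANKLE_DORSIFLEXION, Domain.SWING): "ASWS",
}


def _quota_codes(rng: np.random.Generator, classes, prior: np.ndarray,
                 n: int) -> np.ndarray:
    """Shuffled pattern codes whose counts match ``prior`` by largest-
    remainder apportionment, so empirical class frequencies track the
    printed prevalences at any cohort size."""
    ideal = prior * n
    counts = np.floor(ideal).astype(int)
    short = n - counts.sum()
    if short > 0:
        counts[np.argsort(-(ideal - counts), kind="stable")[:short]] += 1
    codes = np.repeat(np.asarray(classes, dtype=object), counts)
    return rng.permutation(codes)


def generate_cp_dataset(config: GeneratorConfig) -> Dataset:
    """Labeled synthetic CP dataset under the given conditions.

    Every patient session gets one pattern code per joint motion --
    held fixed across the session's trials -- via quota sampling from
    the class prior; trial curves are the pattern curves plus patient
    effect and smooth trial noise.
    """
    priors = config.priors()
    trial_probs = config.trial_count_probs()
    session_probs = np.asarray(config.session_probs, dtype=float)
    if np.any(session_probs < 0) or not np.isclose(session_probs.sum(), 1.0):
        raise ValueError("session_probs must be non-negative and sum to 1")
    rng = np.random.default_rng(config.seed)
    trial_counts = np.arange(TRIALS_MIN, TRIALS_MAX + 1)

    sessions_per_patient = 1 + rng.choice(
        len(session_probs), size=config.n_patients, p=session_probs
    )
    n_sessions = int(sessions_per_patient.sum())
    session_codes = {
        jm: _quota_codes(rng, JOINT_MOTIONS[jm].classes, priors[jm], n_sessions)
        for jm in JOINT_MOTIONS
    }

    # pre-compute every pattern's noise-free curve
    pat_curves = {
        (jm, code): pattern_curve(jm, code)
        for jm in JOINT_MOTIONS
        for code in JOINT_MOTIONS[jm].classes
    }

    trials = []
    session_idx = 0
    for p in range(config.n_patients):
        pid = f"p{p:04d}"
        patient_noise = _noise_curves(
            rng,
            config.patient_effect_sd * _PATIENT_OFFSET_FRAC,
            _PATIENT_SHAPE_SD if config.patient_effect_sd > 0 else 0.0,
            config.noise_harmonics,
        )
        for s in range(int(sessions_per_patient[p])):
            sid = f"{pid}-s{s + 1}"
            labels = {jm: session_codes[jm][session_idx] for jm in JOINT_MOTIONS}
            session_idx += 1
            n_trials = int(rng.choice(trial_counts, p=trial_probs))
            for k in range(n_trials):
                toe_off = float(np.clip(
                    rng.normal(config.toe_off_mean, config.toe_off_sd), 55.0, 65.0
                ))
                trial_noise = _noise_curves(
                    rng,
                    config.trial_noise_sd * _TRIAL_OFFSET_FRAC,
                    config.trial_noise_sd * _TRIAL_SHAPE_FRAC,
                    config.noise_harmonics,
                )
                curves = {}
                for t, jm in _FULL_CYCLE_JM.items():
                    key = (t, Domain.FULL_CYCLE)
                    curves[key] = (
                        pat_curves[(jm, labels[jm])]
                        + patient_noise[key] + trial_noise[key]
                    )
                for t in PHASE_TRACKS:
                    st_key, sw_key = (t, Domain.STANCE), (t, Domain.SWING)
                    st = (pat_curves[(_PHASE_JM[st_key], labels[_PHASE_JM[st_key]])]
                          + patient_noise[st_key] + trial_noise[st_key])
                    sw = (pat_curves[(_PHASE_JM[sw_key], labels[_PHASE_JM[sw_key]])]
                          + patient_noise[sw_key] + trial_noise[sw_key])
                    curves[st_key] = st
                    curves[sw_key] = sw
                    curves[(t, Domain.FULL_CYCLE)] = _assemble_full_cycle(
                        st, sw, toe_off
                    )
                trials.append(
                    GaitTrial(
                        trial_id=f"{sid}-t{k + 1:02d}",
                        session_id=sid,
                        patient_id=pid,
                        toe_off_pct=toe_off,
                        curves=curves,
                        labels=dict(labels),
                    )
                )
    return Dataset(trials)


def noise_free(config: GeneratorConfig) -> GeneratorConfig:
    """The same conditions with patient and trial variability removed."""
    return replace(config, patient_effect_sd=0.0, trial_noise_sd=0.0)
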