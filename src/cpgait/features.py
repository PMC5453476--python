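"""Gait feature extraction.

Two batteries are computed from a trial and a normative band:

* the 24 expert-defined features (18 continuous + 6 boolean composites)
  that the clinical consensus attached to the eleven joint motions; and
* a configurable full battery (default 1047 features): every curve
  sample of every track/domain plus derived statistics (extrema,
  timings, range of motion, band exceedance, values at fixed percents,
  second-rocker-style excursion) per curve window.

Operational definitions that the consensus literature leaves implicit
(second-rocker window, early-stance knee-peak search range, band-flag
rule) sit behind :class:`FeatureConfig` parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    Dataset,
    Domain,
    GaitTrial,
    GRID,
    N_SAMPLES,
    NormativeBand,
    PHASE_TRACKS,
    Track,
    ValidationError,
)


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable operational definitions of the extraction primitives."""

    #: second-rocker window as (start, end) % of stance
    rocker_window: tuple[float, float] = (20.0, 80.0)
    #: search range (% of stance) for the early/mid-stance knee peak
    knee_peak_search: tuple[float, float] = (0.0, 50.0)
    #: % of gait cycle at which the terminal-swing ankle angle is read
    ankle_gc_pct: float = 90.0


DEFAULT_CONFIG = FeatureConfig()


@dataclass(frozen=True)
class FeatureDefinition:
    name: str
    joint_motion: str
    kind: str  # scalar_angle | timing_pct | rom | band_pct | composite
    description: str


_CONTINUOUS = [
    FeatureDefinition("SRA", "ASTS", "scalar_angle",
                      "second-rocker dorsiflexion excursion (deg) over the rocker window of stance"),
    FeatureDefinition("aMaxStSagA", "ASTS", "scalar_angle",
                      "maximum ankle dorsiflexion during stance (deg)"),
    FeatureDefinition("aIc2SagA", "ASWS", "scalar_angle",
                      "ankle angle at terminal swing / second initial contact (deg)"),
    FeatureDefinition("aSagA-pct-GC-900", "ASWS", "scalar_angle",
                      "ankle angle at 90% of the gait cycle (deg)"),
    FeatureDefinition("aBelow1SDSwSagApct", "ASWS", "band_pct",
                      "% of swing samples with ankle angle below the -1SD band"),
    FeatureDefinition("aAbove1SDSwSagApct", "ASWS", "band_pct",
                      "% of swing samples with ankle angle above the +1SD band"),
    FeatureDefinition("aIcSagK", "KSTS", "scalar_angle",
                      "knee flexion at initial contact (deg)"),
    FeatureDefinition("pctaMaxMStSagK", "KSTS", "timing_pct",
                      "timing (% of stance) of the early/mid-stance knee flexion peak"),
    FeatureDefinition("aMinStSagK", "KSTS", "scalar_angle",
                      "minimum knee flexion during stance (deg)"),
    FeatureDefinition("aMaxSwSagK", "KSWS", "scalar_angle",
                      "peak knee flexion during swing (deg)"),
    FeatureDefinition("DeFlKpctSw", "KSWS", "timing_pct",
                      "timing (% of swing) of peak knee flexion"),
    FeatureDefinition("ARomSagP", "PS", "rom",
                      "pelvic tilt range of motion over the cycle (deg)"),
    FeatureDefinition("aMinStSagH", "HS", "scalar_angle",
                      "minimum hip flexion during stance (deg)"),
    FeatureDefinition("aRomStSagH", "HS", "rom",
                      "hip flexion range of motion during stance (deg)"),
    FeatureDefinition("aAbove1SDSagHpct", "HS", "band_pct",
                      "% of cycle samples with hip flexion above the +1SD band"),
    FeatureDefinition("aRomCorP", "PC", "rom",
                      "pelvic obliquity range of motion over the cycle (deg)"),
    FeatureDefinition("aBelow1SDSwCorHpct", "HC", "band_pct",
                      "% of swing samples with hip adduction below the -1SD band"),
    FeatureDefinition("aRomTransP", "PT", "rom",
                      "pelvic rotation range of motion over the cycle (deg)"),
]

#: composite name -> (joint motion, track, (above constituent, below constituent))
_COMPOSITES = {
    "PS-f2": ("PS", Track.PELVIC_TILT, ("aAbove1SDSagP", "aBelow1SDSagP")),
    "PC-f2": ("PC", Track.PELVIC_OBLIQUITY, ("aAbove1SDCorP", "aBelow1SDCorP")),
    "HC-f2": ("HC", Track.HIP_ABDUCTION, ("aAbove1SDCorHpct", "aBelow1SDCorHpct")),
    "PT-f2": ("PT", Track.PELVIC_ROTATION, ("aAbove1SDTransP", "aBelow1SDTransP")),
    "HT-f1": ("HT", Track.HIP_ROTATION, ("aAbove1SDTransH", "aBelow1SDTransH")),
    "FT-f1": ("FPA", Track.FOOT_PROGRESSION, ("aAbove1SDStTransF", "aBelow1SDStTransF")),
}

EXPERT_FEATURES: dict[str, FeatureDefinition] = {f.name: f for f in _CONTINUOUS}
EXPERT_FEATURES.update(
    {
        name: FeatureDefinition(
            name, jm, "composite",
            f"band flags ({above}, {below}) on the cycle-averaged angle",
        )
        for name, (jm, _track, (above, below)) in _COMPOSITES.items()
    }
)

#: Table-ordered names of the 24 expert features.
EXPERT_FEATURE_ORDER = [
    "SRA", "aMaxStSagA",
    "aIc2SagA", "aSagA-pct-GC-900", "aBelow1SDSwSagApct", "aAbove1SDSwSagApct",
    "aIcSagK", "pctaMaxMStSagK", "aMinStSagK",
    "aMaxSwSagK", "DeFlKpctSw",
    "ARomSagP", "PS-f2",
    "aMinStSagH", "aRomStSagH", "aAbove1SDSagHpct",
    "aRomCorP", "PC-f2",
    "aBelow1SDSwCorHpct", "HC-f2",
    "aRomTransP", "PT-f2",
    "HT-f1",
    "FT-f1",
]


def expert_feature_names(jm_code: str) -> list[str]:
    """Expert feature names of one joint motion, in table order."""
    return [n for n in EXPERT_FEATURE_ORDER if EXPERT_FEATURES[n].joint_motion == jm_code]


def registry_json() -> list[dict]:
    """Exportable description of the expert feature registry."""
    out = []
    for name in EXPERT_FEATURE_ORDER:
        d = EXPERT_FEATURES[name]
        entry = {"name": d.name, "joint_motion": d.joint_motion, "kind": d.kind,
                 "description": d.description}
        if name in _COMPOSITES:
            entry["constituents"] = list(_COMPOSITES[name][2])
        out.append(entry)
    return out


# ---------------------------------------------------------------------------
# Primitives (single curve)
# ---------------------------------------------------------------------------

def extremum_in_domain(curve, mode: str) -> float:
    """Extremum angle over a 51-sample curve."""
    arr = np.asarray(curve, dtype=float)
    return float(arr.max() if mode == "max" else arr.min())


def timing_of_extremum(curve, mode: str) -> float:
    """Position (% of domain) of the extremum; ties go to the earliest sample."""
    arr = np.asarray(curve, dtype=float)
    idx = int(np.argmax(arr) if mode == "max" else np.argmin(arr))
    return float(GRID[idx])


def angle_at_pct(curve, pct: float) -> float:
    """Linearly interpolated angle at a percentage of the curve's domain."""
    if not 0.0 <= pct <= 100.0:
        raise ValidationError(f"pct must be in [0, 100], got {pct}")
    return float(np.interp(pct, GRID, np.asarray(curve, dtype=float)))


def rom(curve) -> float:
    """Range of motion: max minus min (deg)."""
    arr = np.asarray(curve, dtype=float)
    return float(arr.max() - arr.min())


def band_exceedance_pct(curve, band_mean, band_sd, direction: str, mask=None) -> float:
    """Percentage of (masked) samples outside the mean +/- 1 SD envelope."""
    arr = np.asarray(curve, dtype=float)
    m = np.asarray(band_mean, dtype=float)
    s = np.asarray(band_sd, dtype=float)
    if arr.shape != m.shape or arr.shape != s.shape:
        raise ValidationError("curve and band must share the same domain/shape")
    if direction == "above":
        out = arr > m + s
    elif direction == "below":
        out = arr < m - s
    else:
        raise ValidationError(f"direction must be 'above' or 'below', got {direction!r}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        return 100.0 * float(out[mask].sum()) / float(mask.sum())
    return 100.0 * float(out.mean())


def band_flag(trial: GaitTrial, band: NormativeBand, track: Track) -> tuple[bool, bool]:
    """(above, below) flags on the trial's cycle-averaged angle.

    ``above`` is true when the average exceeds the cohort's cycle-mean
    by more than one between-subject SD, ``below`` symmetrically; at
    most one can be true.
    """
    track = Track(track)
    avg = float(trial.curve(track).mean())
    m, s = band.cycle_mean_mean[track], band.cycle_mean_sd[track]
    return avg > m + s, avg < m - s


def second_rocker_slope(stance_curve, window: tuple[float, float] = (20.0, 80.0)) -> float:
    """Net dorsiflexion excursion (deg) over the second-rocker window.

    Positive = progressing dorsiflexion, ~0 = horizontal rocker,
    negative = reversed rocker.
    """
    return angle_at_pct(stance_curve, window[1]) - angle_at_pct(stance_curve, window[0])


# ---------------------------------------------------------------------------
# Vectorized helpers
# ---------------------------------------------------------------------------

def _stack(trials, track, domain):
    return np.stack([t.curves[(track, domain)] for t in trials])


def _vals_at_pct(arr2d: np.ndarray, pct) -> np.ndarray:
    """Interpolated values at per-row percentages of the 0-100 domain."""
    pct = np.broadcast_to(np.asarray(pct, dtype=float), arr2d.shape[:1]).copy()
    pos = np.clip(pct / 100.0 * (N_SAMPLES - 1), 0, N_SAMPLES - 1)
    lo = np.minimum(pos.astype(int), N_SAMPLES - 2)
    w = pos - lo
    rows = np.arange(arr2d.shape[0])
    return arr2d[rows, lo] * (1.0 - w) + arr2d[rows, lo + 1] * w


def _masked_stats(arr2d, mask):
    """min/max and timings (% of domain) over per-row boolean masks."""
    big = np.where(mask, arr2d, -np.inf)
    small = np.where(mask, arr2d, np.inf)
    mx = big.max(axis=1)
    mn = small.min(axis=1)
    tmx = GRID[np.argmax(big, axis=1)]
    tmn = GRID[np.argmin(small, axis=1)]
    return mn, mx, tmn, tmx


def _exceed_pct(arr2d, mean, sd, direction, mask=None):
    out = (arr2d > mean + sd) if direction == "above" else (arr2d < mean - sd)
    if mask is None:
        return 100.0 * out.mean(axis=1)
    return 100.0 * (out & mask).sum(axis=1) / mask.sum(axis=1)


# ---------------------------------------------------------------------------
# Expert battery
# ---------------------------------------------------------------------------

def extract_expert_matrix(
    dataset: Dataset | list[GaitTrial],
    band: NormativeBand,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """The 24 expert features for every trial.

    Continuous features are floats; composite features are
    ``(above, below)`` boolean tuples.  Rows are indexed by trial_id in
    dataset order.
    """
    trials = list(dataset)
    if not trials:
        raise ValidationError("empty dataset")
    toe_off = np.array([t.toe_off_pct for t in trials])
    stance_mask = GRID[None, :] <= toe_off[:, None]
    swing_mask = GRID[None, :] >= toe_off[:, None]

    knee_st = _stack(trials, Track.KNEE_FLEXION, Domain.STANCE)
    knee_sw = _stack(trials, Track.KNEE_FLEXION, Domain.SWING)
    ankle_st = _stack(trials, Track.ANKLE_DORSIFLEXION, Domain.STANCE)
    ankle_sw = _stack(trials, Track.ANKLE_DORSIFLEXION, Domain.SWING)
    ankle_fc = _stack(trials, Track.ANKLE_DORSIFLEXION, Domain.FULL_CYCLE)
    hip_fc = _stack(trials, Track.HIP_FLEXION, Domain.FULL_CYCLE)
    abd_fc = _stack(trials, Track.HIP_ABDUCTION, Domain.FULL_CYCLE)

    cols: dict[str, np.ndarray | list] = {}
    r0, r1 = config.rocker_window
    cols["SRA"] = _vals_at_pct(ankle_st, r1) - _vals_at_pct(ankle_st, r0)
    cols["aMaxStSagA"] = ankle_st.max(axis=1)
    cols["aIc2SagA"] = ankle_sw[:, -1]
    cols["aSagA-pct-GC-900"] = _vals_at_pct(ankle_fc, config.ankle_gc_pct)
    m_sw, s_sw = band.curves(Track.ANKLE_DORSIFLEXION, Domain.SWING)
    cols["aBelow1SDSwSagApct"] = _exceed_pct(ankle_sw, m_sw, s_sw, "below")
    cols["aAbove1SDSwSagApct"] = _exceed_pct(ankle_sw, m_sw, s_sw, "above")

    cols["aIcSagK"] = knee_st[:, 0]
    lo, hi = config.knee_peak_search
    search = (GRID >= lo) & (GRID <= hi)
    _, _, _, tmx = _masked_stats(knee_st, np.broadcast_to(search, knee_st.shape))
    cols["pctaMaxMStSagK"] = tmx
    cols["aMinStSagK"] = knee_st.min(axis=1)
    cols["aMaxSwSagK"] = knee_sw.max(axis=1)
    cols["DeFlKpctSw"] = GRID[np.argmax(knee_sw, axis=1)]

    cols["ARomSagP"] = np.ptp(_stack(trials, Track.PELVIC_TILT, Domain.FULL_CYCLE), axis=1)
    mn, mx, _, _ = _masked_stats(hip_fc, stance_mask)
    cols["aMinStSagH"] = mn
    cols["aRomStSagH"] = mx - mn
    m_h, s_h = band.curves(Track.HIP_FLEXION, Domain.FULL_CYCLE)
    cols["aAbove1SDSagHpct"] = _exceed_pct(hip_fc, m_h, s_h, "above")
    cols["aRomCorP"] = np.ptp(
        _stack(trials, Track.PELVIC_OBLIQUITY, Domain.FULL_CYCLE), axis=1
    )
    m_a, s_a = band.curves(Track.HIP_ABDUCTION, Domain.FULL_CYCLE)
    cols["aBelow1SDSwCorHpct"] = _exceed_pct(abd_fc, m_a, s_a, "below", swing_mask)
    cols["aRomTransP"] = np.ptp(
        _stack(trials, Track.PELVIC_ROTATION, Domain.FULL_CYCLE), axis=1
    )

    for name, (_jm, track, _names) in _COMPOSITES.items():
        fc = _stack(trials, track, Domain.FULL_CYCLE)
        avg = fc.mean(axis=1)
        m, s = band.cycle_mean_mean[track], band.cycle_mean_sd[track]
        above, below = avg > m + s, avg < m - s
        cols[name] = list(zip(above.tolist(), below.tolist()))

    df = pd.DataFrame(cols, index=pd.Index([t.trial_id for t in trials], name="trial_id"))
    return df[EXPERT_FEATURE_ORDER]


def extract_expert_features(
    trial: GaitTrial, band: NormativeBand, config: FeatureConfig = DEFAULT_CONFIG
) -> dict:
    """The 24 expert features of a single trial as a name -> value mapping."""
    row = extract_expert_matrix([trial], band, config).iloc[0]
    return {
        name: (row[name] if isinstance(row[name], tuple) else float(row[name]))
        for name in EXPERT_FEATURE_ORDER
    }


# ---------------------------------------------------------------------------
# Full battery
# ---------------------------------------------------------------------------

_DERIVED_STATS = [
    "min", "max", "rom", "tmin", "tmax", "abovepct", "belowpct",
    "v000", "v050", "v090", "v100", "exc2080",
]


def _battery_layout():
    """(curve keys with domains) and (curve key, window) pairs of the battery.

    Windows on full-cycle curves: the whole cycle plus the stance and
    swing sub-windows; phase curves use their full domain, and the
    stance knee additionally the early-stance search window.
    """
    curve_keys = [(t, Domain.FULL_CYCLE) for t in Track]
    curve_keys += [(t, d) for t in PHASE_TRACKS for d in (Domain.STANCE, Domain.SWING)]
    windows = []
    for t in Track:
        for w in ("cycle", "stance", "swing"):
            windows.append(((t, Domain.FULL_CYCLE), w))
    windows.append(((Track.KNEE_FLEXION, Domain.STANCE), "full"))
    windows.append(((Track.KNEE_FLEXION, Domain.STANCE), "early"))
    windows.append(((Track.KNEE_FLEXION, Domain.SWING), "full"))
    windows.append(((Track.ANKLE_DORSIFLEXION, Domain.STANCE), "full"))
    windows.append(((Track.ANKLE_DORSIFLEXION, Domain.SWING), "full"))
    return curve_keys, windows


def full_battery_names() -> list[str]:
    """Deterministic names of the full battery (default config)."""
    curve_keys, windows = _battery_layout()
    names = []
    for track, domain in curve_keys:
        names += [f"{track.value}.{domain.value}.s{i:02d}" for i in range(N_SAMPLES)]
    for (track, domain), w in windows:
        names += [f"{track.value}.{domain.value}.{w}.{s}" for s in _DERIVED_STATS]
    return names


def extract_full_matrix(
    dataset: Dataset | list[GaitTrial],
    band: NormativeBand,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """The full feature battery for every trial (floats only).

    Timing stats (``tmin``/``tmax``) are % of the curve's own domain;
    point values (``v000``..``v100``) and the ``exc2080`` excursion are
    taken at percentages of the window.
    """
    trials = list(dataset)
    if not trials:
        raise ValidationError("empty dataset")
    n = len(trials)
    toe_off = np.array([t.toe_off_pct for t in trials])
    curve_keys, windows = _battery_layout()
    stacks = {key: _stack(trials, *key) for key in curve_keys}

    def window_bounds(w):
        if w in ("cycle", "full"):
            return np.zeros(n), np.full(n, 100.0)
        if w == "stance":
            return np.zeros(n), toe_off
        if w == "swing":
            return toe_off, np.full(n, 100.0)
        if w == "early":
            lo, hi = config.knee_peak_search
            return np.full(n, lo), np.full(n, hi)
        raise ValueError(w)

    cols = {}
    for (track, domain) in curve_keys:
        arr = stacks[(track, domain)]
        for i in range(N_SAMPLES):
            cols[f"{track.value}.{domain.value}.s{i:02d}"] = arr[:, i]
    for (track, domain), w in windows:
        arr = stacks[(track, domain)]
        t0, t1 = window_bounds(w)
        mask = (GRID[None, :] >= t0[:, None]) & (GRID[None, :] <= t1[:, None])
        mn, mx, tmn, tmx = _masked_stats(arr, mask)
        m, s = band.curves(track, domain)
        prefix = f"{track.value}.{domain.value}.{w}"
        vals = {
            "min": mn, "max": mx, "rom": mx - mn, "tmin": tmn, "tmax": tmx,
            "abovepct": _exceed_pct(arr, m, s, "above", mask),
            "belowpct": _exceed_pct(arr, m, s, "below", mask),
        }
        for tag, frac in (("v000", 0.0), ("v050", 0.5), ("v090", 0.9), ("v100", 1.0)):
            vals[tag] = _vals_at_pct(arr, t0 + frac * (t1 - t0))
        vals["exc2080"] = (
            _vals_at_pct(arr, t0 + 0.8 * (t1 - t0))
            - _vals_at_pct(arr, t0 + 0.2 * (t1 - t0))
        )
        for stat in _DERIVED_STATS:
            cols[f"{prefix}.{stat}"] = vals[stat]

    return pd.DataFrame(
        cols, index=pd.Index([t.trial_id for t in trials], name="trial_id")
    )


def extract_full_features(
    trial: GaitTrial, band: NormativeBand, config: FeatureConfig = DEFAULT_CONFIG
) -> dict[str, float]:
    row = extract_full_matrix([trial], band, config).iloc[0]
    return {k: float(v) for k, v in row.items()}
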