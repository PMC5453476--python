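"""Feature discretization: expert interval/composite schemes and
supervised entropy-based (MDL) discretization.

Interval bins are left-closed, ``bin i = [c_{i-1}, c_i)`` with the last
bin closed; values outside the outer cuts clamp to the first/last bin
with a logged warning (the printed outer bounds are observed data
ranges, so out-of-range values must not fail).  Composite features with
two mutually exclusive boolean constituents map to three states:
1 = above true, 2 = below true, 3 = both false.

``mdl_discretize`` implements recursive binary splitting on class
entropy with the minimum-description-length stopping criterion of
Fayyad & Irani: a cut is accepted only when its information gain
exceeds ``(log2(N-1) + log2(3^k - 2) - (k*Ent(S) - k1*Ent(S1) -
k2*Ent(S2))) / N``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: feature names that have already produced a clamp warning
_clamp_warned: set[str] = set()


class DiscretizationError(ValueError):
    pass


@dataclass(frozen=True)
class IntervalScheme:
    """Strictly increasing cut points defining left-closed bins."""

    feature: str
    cuts: tuple[float, ...]

    def __post_init__(self):
        cuts = tuple(float(c) for c in self.cuts)
        if len(cuts) < 2:
            raise DiscretizationError(f"{self.feature}: need at least 2 cut points")
        interior = np.diff(cuts)
        # a degenerate single-bin scheme (constant feature) may have
        # equal endpoints; multi-bin cuts must strictly increase
        if len(cuts) > 2 and np.any(interior <= 0):
            raise DiscretizationError(f"{self.feature}: cuts must strictly increase")
        if len(cuts) == 2 and cuts[1] < cuts[0]:
            raise DiscretizationError(f"{self.feature}: cuts must not decrease")
        object.__setattr__(self, "cuts", cuts)

    @property
    def n_bins(self) -> int:
        return len(self.cuts) - 1

    def apply(self, value):
        """Bin index (1-based) of a value or array of values."""
        arr = np.asarray(value, dtype=float)
        if np.any(np.isnan(arr)):
            raise DiscretizationError(f"{self.feature}: cannot bin NaN values")
        cuts = np.asarray(self.cuts)
        if np.any(arr < cuts[0]) or np.any(arr > cuts[-1]):
            # warn once per feature to keep large batch runs readable
            if self.feature not in _clamp_warned:
                _clamp_warned.add(self.feature)
                logger.warning(
                    "%s: value(s) outside [%g, %g]; clamping to outer bins "
                    "(further clamps for this feature logged at DEBUG)",
                    self.feature, cuts[0], cuts[-1],
                )
            else:
                logger.debug("%s: clamped out-of-range value(s)", self.feature)
        # left-closed bins; last bin closed on the right
        idx = np.searchsorted(cuts[1:-1], arr, side="right") + 1
        out = np.clip(idx, 1, self.n_bins)
        return int(out) if np.isscalar(value) or arr.ndim == 0 else out

    def to_json(self) -> dict:
        return {"feature": self.feature, "type": "interval", "cuts": list(self.cuts),
                "convention": "left-closed, last bin closed, clamped"}


@dataclass(frozen=True)
class CompositeScheme:
    """Three-state scheme over two mutually exclusive boolean flags."""

    feature: str
    constituents: tuple[str, str]  # (above, below)

    n_bins = 3

    def apply(self, above, below=None):
        """State index: 1 = above, 2 = below, 3 = neither."""
        if below is None:  # allow a single (above, below) tuple
            above, below = above
        above_arr = np.asarray(above, dtype=bool)
        below_arr = np.asarray(below, dtype=bool)
        if np.any(above_arr & below_arr):
            raise DiscretizationError(
                f"{self.feature}: above and below flags cannot co-occur"
            )
        out = np.where(above_arr, 1, np.where(below_arr, 2, 3))
        return int(out) if out.ndim == 0 else out

    def to_json(self) -> dict:
        return {"feature": self.feature, "type": "composite",
                "constituents": list(self.constituents),
                "states": {"1": "above", "2": "below", "3": "neither"}}


def apply_interval(scheme: IntervalScheme, value):
    return scheme.apply(value)


def apply_composite(scheme: CompositeScheme, above, below=None):
    return scheme.apply(above, below)


#: Expert discretization of the 24 features (cut points / constituents
#: as printed in the consensus table).
EXPERT_SCHEMES: dict[str, IntervalScheme | CompositeScheme] = {
    s.feature: s
    for s in (
        IntervalScheme("SRA", (-21, -5.5, 19.4, 31)),
        IntervalScheme("aMaxStSagA", (-40, 0, 20, 38)),
        IntervalScheme("aIc2SagA", (-39, -4.2, 80)),
        IntervalScheme("aSagA-pct-GC-900", (-42, -2, 31)),
        IntervalScheme("aBelow1SDSwSagApct", (0, 50, 100)),
        IntervalScheme("aAbove1SDSwSagApct", (0, 33, 100)),
        IntervalScheme("aIcSagK", (-17, 13.6, 77)),
        IntervalScheme("pctaMaxMStSagK", (0, 11.2, 30)),
        IntervalScheme("aMinStSagK", (-33, -3.8, 7.9, 70)),
        IntervalScheme("aMaxSwSagK", (5, 54.4, 67, 98)),
        IntervalScheme("DeFlKpctSw", (1.5, 35.6, 99)),
        IntervalScheme("ARomSagP", (1, 5.4, 23)),
        CompositeScheme("PS-f2", ("aAbove1SDSagP", "aBelow1SDSagP")),
        IntervalScheme("aMinStSagH", (-32, -4.3, 40)),
        IntervalScheme("aRomStSagH", (8, 38.3, 73)),
        IntervalScheme("aAbove1SDSagHpct", (0, 90, 100)),
        IntervalScheme("aRomCorP", (1, 12.8, 26)),
        CompositeScheme("PC-f2", ("aAbove1SDCorP", "aBelow1SDCorP")),
        IntervalScheme("aBelow1SDSwCorHpct", (0, 50, 100)),
        CompositeScheme("HC-f2", ("aAbove1SDCorHpct", "aBelow1SDCorHpct")),
        IntervalScheme("aRomTransP", (0, 18, 53)),
        CompositeScheme("PT-f2", ("aAbove1SDTransP", "aBelow1SDTransP")),
        CompositeScheme("HT-f1", ("aAbove1SDTransH", "aBelow1SDTransH")),
        CompositeScheme("FT-f1", ("aAbove1SDStTransF", "aBelow1SDStTransF")),
    )
}


# ---------------------------------------------------------------------------
# Supervised MDL discretization
# ---------------------------------------------------------------------------

def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _best_cut(values: np.ndarray, codes: np.ndarray, n_classes: int):
    """Best boundary cut by information gain on a sorted slice.

    Candidates are midpoints between adjacent samples with different
    values and different class labels; ties on gain go to the smallest
    cut value (the natural order of the scan).  Returns
    ``(cut, gain, split_index, stats)`` or ``None``.
    """
    n = len(values)
    diff_val = values[1:] > values[:-1]
    diff_lab = codes[1:] != codes[:-1]
    cand = np.flatnonzero(diff_val & diff_lab)
    if cand.size == 0:
        return None
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), codes] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]
    ent_s = _entropy(total)
    left = cum[cand]                       # counts in S1 for each candidate
    right = total[None, :] - left
    n1 = left.sum(axis=1)
    n2 = n - n1

    def ent_rows(c):
        with np.errstate(divide="ignore", invalid="ignore"):
            tot = c.sum(axis=1, keepdims=True)
            p = np.where(tot > 0, c / np.maximum(tot, 1), 0.0)
            lg = np.where(p > 0, np.log2(np.maximum(p, 1e-300)), 0.0)
        return -(p * lg).sum(axis=1)

    e1, e2 = ent_rows(left), ent_rows(right)
    gains = ent_s - (n1 * e1 + n2 * e2) / n
    best = int(np.argmax(gains))           # first max -> smallest cut value
    i = int(cand[best])
    cut = 0.5 * (values[i] + values[i + 1])
    k = int((total > 0).sum())
    k1 = int((left[best] > 0).sum())
    k2 = int((right[best] > 0).sum())
    stats = (ent_s, e1[best], e2[best], k, k1, k2)
    return cut, float(gains[best]), i + 1, stats


def _mdl_accept(gain, n, stats) -> bool:
    ent_s, e1, e2, k, k1, k2 = stats
    delta = np.log2(3.0 ** k - 2.0) - (k * ent_s - k1 * e1 - k2 * e2)
    return gain > (np.log2(n - 1) + delta) / n


def _recurse(values, codes, n_classes, cuts):
    n = len(values)
    if n < 2:
        return
    found = _best_cut(values, codes, n_classes)
    if found is None:
        return
    cut, gain, split, stats = found
    if not _mdl_accept(gain, n, stats):
        return
    cuts.append(cut)
    _recurse(values[:split], codes[:split], n_classes, cuts)
    _recurse(values[split:], codes[split:], n_classes, cuts)


def mdl_discretize(values, labels, feature: str = "feature") -> IntervalScheme:
    """Supervised discretization of one continuous feature.

    Outer cuts are the observed min/max; when no cut passes the MDL
    criterion (including constant inputs) the result is a single-bin
    scheme.
    """
    vals = np.asarray(values, dtype=float)
    labs = np.asarray(labels)
    if vals.ndim != 1 or vals.shape != labs.shape:
        raise DiscretizationError("values and labels must be equal-length 1-D")
    if len(vals) < 2:
        raise DiscretizationError("mdl_discretize needs at least 2 samples")
    if np.any(np.isnan(vals)):
        raise DiscretizationError("mdl_discretize: NaN values")
    # secondary sort on the label makes the result independent of the
    # input order when duplicate values carry mixed labels
    order = np.lexsort((labs.astype(str), vals))
    vals = vals[order]
    _, codes = np.unique(labs[order], return_inverse=True)
    n_classes = int(codes.max()) + 1
    cuts: list[float] = []
    _recurse(vals, codes, n_classes, cuts)
    lo, hi = float(vals[0]), float(vals[-1])
    return IntervalScheme(feature, tuple([lo] + sorted(cuts) + [hi]))
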