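"""Correlation-based feature subset selection (CFS).

A subset's merit is ``k * r_cf / sqrt(k + k(k-1) * r_ff)`` where
``r_cf`` is the mean feature-class correlation and ``r_ff`` the mean
pairwise feature-feature correlation, both measured as symmetrical
uncertainty on discrete (binned) columns.  Subsets are explored with a
forward best-first search that stops after a fixed number of
consecutive expansions that fail to improve the global best.
"""

from __future__ import annotations

import heapq

import numpy as np
import pandas as pd


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _codes(col) -> tuple[np.ndarray, int]:
    _, inv = np.unique(np.asarray(col), return_inverse=True)
    return inv.astype(np.int64), int(inv.max()) + 1


def _su_codes(cx, nx, hx, cy, ny, hy) -> float:
    if hx == 0.0 or hy == 0.0:
        return 0.0
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).astype(float)
    mi = hx + hy - _entropy_from_counts(joint)
    return float(np.clip(2.0 * mi / (hx + hy), 0.0, 1.0))


def symmetrical_uncertainty(x, y) -> float:
    """SU(x, y) = 2 I(x;y) / (H(x) + H(y)), in [0, 1].

    Zero by convention when either column is constant.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("columns must be 1-D and of equal length")
    cx, nx = _codes(x)
    cy, ny = _codes(y)
    hx = _entropy_from_counts(np.bincount(cx).astype(float))
    hy = _entropy_from_counts(np.bincount(cy).astype(float))
    return _su_codes(cx, nx, hx, cy, ny, hy)


class CfsEvaluator:
    """Merit evaluation over a discrete feature matrix with SU caching."""

    def __init__(self, features: pd.DataFrame, labels):
        self.names = list(features.columns)
        self._y = np.asarray(labels)
        if len(self._y) != len(features):
            raise ValueError("labels length must match the feature matrix")
        self._col: dict[str, tuple[np.ndarray, int, float]] = {}
        for n in self.names:
            c, k = _codes(features[n])
            self._col[n] = (c, k, _entropy_from_counts(np.bincount(c).astype(float)))
        cy, ky = _codes(self._y)
        hy = _entropy_from_counts(np.bincount(cy).astype(float))
        self._su_class = {
            n: _su_codes(*self._col[n], cy, ky, hy) for n in self.names
        }
        self._su_pair: dict[frozenset, float] = {}

    def su_class(self, name: str) -> float:
        return self._su_class[name]

    def su_pair(self, a: str, b: str) -> float:
        if a == b:
            ca, ka, ha = self._col[a]
            return _su_codes(ca, ka, ha, ca, ka, ha)
        key = frozenset((a, b))
        su = self._su_pair.get(key)
        if su is None:
            su = self._su_pair[key] = _su_codes(*self._col[a], *self._col[b])
        return su

    def merit(self, subset) -> float:
        subset = list(subset)
        k = len(subset)
        if k == 0:
            return 0.0
        rcf_sum = sum(self._su_class[f] for f in subset)
        pair_sum = sum(
            self.su_pair(a, b)
            for i, a in enumerate(subset) for b in subset[i + 1:]
        )
        return self._merit_from_sums(k, rcf_sum, pair_sum)

    @staticmethod
    def _merit_from_sums(k: int, rcf_sum: float, pair_sum: float) -> float:
        r_cf = rcf_sum / k
        if k == 1:
            return r_cf
        r_ff = pair_sum / (k * (k - 1) / 2)
        denom = np.sqrt(k + k * (k - 1) * r_ff)
        return float(k * r_cf / denom) if denom > 0 else 0.0


def cfs_merit(subset, feature_matrix: pd.DataFrame, labels) -> float:
    """Merit of a feature subset (empty subset -> 0 by convention)."""
    return CfsEvaluator(feature_matrix, labels).merit(subset)


def best_first_select(
    feature_matrix: pd.DataFrame,
    labels,
    stall_limit: int = 5,
    evaluator: CfsEvaluator | None = None,
) -> list[str]:
    """Forward best-first subset search maximizing the CFS merit.

    Expands the most promising open subset by single-feature additions;
    stops after ``stall_limit`` consecutive expansions that do not
    improve the global best.  Deterministic: merit ties break on the
    lexicographically smallest feature set, and the returned list is
    sorted.
    """
    if feature_matrix is not None and feature_matrix.shape[1] == 0:
        raise ValueError("best_first_select needs at least one feature")
    ev = evaluator or CfsEvaluator(feature_matrix, labels)
    names = sorted(ev.names)

    start: tuple[str, ...] = ()
    best_set, best_merit = start, 0.0
    # heap items: (-merit, subset, rcf_sum, pair_sum); ties pop the
    # lexicographically smallest subset first
    open_heap = [(-0.0, start, 0.0, 0.0)]
    visited = {start}
    stall = 0
    while open_heap:
        _, subset, rcf_sum, pair_sum = heapq.heappop(open_heap)
        improved = False
        members = list(subset)
        for f in names:
            if f in subset:
                continue
            child = tuple(sorted(subset + (f,)))
            if child in visited:
                continue
            visited.add(child)
            child_rcf = rcf_sum + ev.su_class(f)
            child_pairs = pair_sum + sum(ev.su_pair(f, g) for g in members)
            m = ev._merit_from_sums(len(child), child_rcf, child_pairs)
            if m > best_merit or (m == best_merit and best_set and child < best_set):
                if m > best_merit:
                    improved = True
                best_merit, best_set = m, child
            heapq.heappush(open_heap, (-m, child, child_rcf, child_pairs))
        if improved:
            stall = 0
        else:
            stall += 1
        if stall >= stall_limit:
            break
    return sorted(best_set)
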