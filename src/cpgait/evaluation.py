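"""Cross-validated evaluation of the classification approaches.

Implements patient-grouped stratified k-fold construction, macro-
averaged performance metrics, confusion and average-posterior
matrices, and the experiment driver that runs one of the four
expert-knowledge approaches with either classifier:

* approach ``1``  -- expert features, expert discretization;
* approach ``2a`` -- the full feature battery, fed in naively;
* approach ``2b`` -- the full battery with CFS feature selection;
* approach ``3``  -- expert features; learned (MDL) discretization for
  NB, raw continuous features for LR (boolean composites pass through
  unchanged in both).

All training-fold artifacts (MDL cut points, CFS subsets,
standardization constants) are learned on the training portion of each
fold only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import Dataset, JOINT_MOTIONS, NormativeBand
from .features import (
    DEFAULT_CONFIG,
    FeatureConfig,
    expert_feature_names,
    extract_expert_matrix,
    extract_full_matrix,
)
from .discretization import EXPERT_SCHEMES, CompositeScheme, mdl_discretize
from .selection import CfsEvaluator, best_first_select
from . import classifiers as clf

logger = logging.getLogger(__name__)

APPROACHES = ("1", "2a", "2b", "3")
CLASSIFIERS = ("NB", "LR")


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    """Patient-exclusive fold assignment (fold indices 1..k)."""

    k: int
    patient_to_fold: dict[str, int]

    def trial_folds(self, dataset: Dataset) -> np.ndarray:
        return np.array([self.patient_to_fold[t.patient_id] for t in dataset])


def make_folds(dataset: Dataset, k: int = 10, seed: int = 0,
               refine_passes: int = 30) -> FoldAssignment:
    """Greedy stratified grouping of patients into k folds.

    Minimizes the chi-square-weighted deviation between each fold's
    per-joint-motion class counts and an equal share (1/k) of the
    global counts: patients are taken in order of decreasing trial
    count and placed where they increase the total deviation least
    (ties break randomly from ``seed``), followed by local
    move-refinement passes.  Because every trial contributes one count
    per joint motion, fold sizes are balanced implicitly.  All trials
    of a patient share one fold.
    """
    patients = dataset.patients
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients for {k} folds, "
                         f"got {len(patients)}")
    rng = np.random.default_rng(seed)

    # class-count vector per patient over all joint motions
    keys = [(jm, c) for jm in JOINT_MOTIONS for c in JOINT_MOTIONS[jm].classes]
    key_idx = {kc: i for i, kc in enumerate(keys)}
    pvecs, psizes = {}, {}
    for pid, trials in patients.items():
        # last component carries the trial count so that fold sizes stay
        # balanced even for sparsely labeled datasets
        v = np.zeros(len(keys) + 1)
        for t in trials:
            for jm, c in t.labels.items():
                v[key_idx[(jm, c)]] += 1.0
        v[-1] = len(trials)
        pvecs[pid], psizes[pid] = v, len(trials)
    quota = sum(pvecs.values()) / k          # per-fold class-count target
    weight = 1.0 / np.maximum(quota, 1e-9)   # chi-square scaling

    order = sorted(patients, key=lambda p: (-psizes[p], p))
    fold_vec = np.zeros((k, len(keys) + 1))
    fold_count = np.zeros(k, dtype=int)
    assignment: dict[str, int] = {}
    for pid in order:
        p = pvecs[pid]
        # marginal increase of sum_f w*(C_f - Q)^2 when p joins fold f
        scores = np.array([
            float(np.dot(weight * p, 2.0 * fold_vec[f] - 2.0 * quota + p))
            for f in range(k)
        ])
        best = np.flatnonzero(scores <= scores.min() + 1e-9)
        f = int(rng.choice(best))
        assignment[pid] = f
        fold_vec[f] += p
        fold_count[f] += 1

    for _ in range(refine_passes):
        moved = False
        for pid in order:
            f0 = assignment[pid]
            if fold_count[f0] <= 1:
                continue  # never empty a fold
            p = pvecs[pid]
            deltas = np.array([
                float(np.dot(weight * p, 2.0 * (fold_vec[f] - (fold_vec[f0] - p))))
                for f in range(k)
            ])
            deltas[f0] = 0.0
            f = int(np.argmin(deltas))
            if deltas[f] < -1e-9:
                assignment[pid] = f
                fold_vec[f0] -= p
                fold_vec[f] += p
                fold_count[f0] -= 1
                fold_count[f] += 1
                moved = True
        if not moved:
            break
    return FoldAssignment(
        k=k, patient_to_fold={p: f + 1 for p, f in assignment.items()}
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion_matrix(y_true, y_pred, classes) -> pd.DataFrame:
    """Counts with true classes as rows and predicted classes as columns."""
    classes = list(classes)
    idx = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in idx or p not in idx:
            raise ValueError(f"label {t if t not in idx else p!r} missing from class list")
        m[idx[t], idx[p]] += 1
    return pd.DataFrame(m, index=classes, columns=classes)


def normalize_confusion(cm: pd.DataFrame) -> pd.DataFrame:
    counts = cm.to_numpy(dtype=float)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(row_sums > 0, counts / row_sums, np.nan)
    return pd.DataFrame(out, index=cm.index, columns=cm.columns)


def macro_metrics(y_true, y_pred, classes) -> tuple[float, float, float]:
    """(macro accuracy %, macro f-score %, percent correct).

    Macro accuracy is the unweighted mean of per-class recall; the
    macro f-score the unweighted mean of per-class F1 (0 when
    undefined); percent-correct is the plain fraction of correctly
    classified trials.
    """
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences must have equal length")
    cm = confusion_matrix(y_true, y_pred, classes).to_numpy(dtype=float)
    tp = np.diag(cm)
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    present = support > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(present, tp / np.maximum(support, 1), np.nan)
        precision = np.where(predicted > 0, tp / np.maximum(predicted, 1), 0.0)
        f1 = np.where(
            (precision + recall > 0) & present,
            2 * precision * recall / np.maximum(precision + recall, 1e-300),
            np.where(present, 0.0, np.nan),
        )
    macro_acc = 100.0 * float(np.nanmean(recall))
    macro_f1 = 100.0 * float(np.nanmean(f1))
    pct = 100.0 * float(tp.sum() / cm.sum()) if cm.sum() else float("nan")
    return macro_acc, macro_f1, pct


def avg_posterior_matrix(y_true, posteriors, classes) -> pd.DataFrame:
    """Row i = mean posterior vector over trials with true class i."""
    classes = list(classes)
    P = np.asarray(posteriors, dtype=float)
    if P.shape != (len(list(y_true)), len(classes)):
        raise ValueError("posterior matrix shape does not match labels/classes")
    out = np.full((len(classes), len(classes)), np.nan)
    y = np.asarray(list(y_true))
    for i, c in enumerate(classes):
        rows = P[y == c]
        if len(rows) == 0:
            warnings.warn(f"no trials with true class {c}; row set to NaN")
            continue
        out[i] = rows.mean(axis=0)
    return pd.DataFrame(out, index=classes, columns=classes)


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    k: int = 10
    seed: int = 0
    alpha: float = 1.0            # NB smoothing pseudo-count
    lam: float = 1.0              # LR regularization strength (used when lam_grid is None)
    #: candidate LR regularization strengths, chosen per training fold by
    #: inner patient-grouped cross-validation (set to None to fix lam)
    lam_grid: tuple[float, ...] | None = (0.01, 0.1, 1.0, 10.0)
    inner_k: int = 3              # inner folds for the lam grid
    lr_tol: float = 1e-6
    lr_max_iter: int = 500
    stall_limit: int = 5          # CFS best-first stall limit
    features: FeatureConfig = field(default_factory=lambda: DEFAULT_CONFIG)
    folds: FoldAssignment | None = None
    #: learn the CFS subset per training fold (leak-free, default) or
    #: once on the full dataset
    selection_per_fold: bool = True


@dataclass
class JointMotionResult:
    joint_motion: str
    classes: tuple[str, ...]
    macro_accuracy: float
    macro_f1: float
    percent_correct: float
    confusion: pd.DataFrame
    confusion_normalized: pd.DataFrame
    avg_posterior: pd.DataFrame
    n_features_per_fold: list[int] | None = None
    #: CFS-selected feature names per fold (approach 2b only)
    selected_features_per_fold: dict[int, list[str]] | None = None

    @property
    def n_features_mean(self) -> float | None:
        if not self.n_features_per_fold:
            return None
        return float(np.mean(self.n_features_per_fold))


@dataclass
class EvaluationReport:
    approach: str
    classifier: str
    per_joint_motion: dict[str, JointMotionResult]
    config: ExperimentConfig

    @property
    def overall_macro_accuracy(self) -> float:
        return float(np.mean(
            [r.macro_accuracy for r in self.per_joint_motion.values()]
        ))

    @property
    def overall_macro_f1(self) -> float:
        return float(np.mean([r.macro_f1 for r in self.per_joint_motion.values()]))

    @property
    def overall_percent_correct(self) -> float:
        return float(np.mean(
            [r.percent_correct for r in self.per_joint_motion.values()]
        ))

    def summary(self) -> pd.DataFrame:
        rows = []
        for jm, r in self.per_joint_motion.items():
            rows.append({
                "joint_motion": jm,
                "macro_accuracy": r.macro_accuracy,
                "macro_f1": r.macro_f1,
                "percent_correct": r.percent_correct,
                "n_features": r.n_features_mean,
            })
        rows.append({
            "joint_motion": "overall",
            "macro_accuracy": self.overall_macro_accuracy,
            "macro_f1": self.overall_macro_f1,
            "percent_correct": self.overall_percent_correct,
            "n_features": None,
        })
        return pd.DataFrame(rows).set_index("joint_motion")

    def to_text(self) -> str:
        name = f"{self.classifier}{self.approach}"
        df = self.summary()
        lines = [f"{name:>8}  macro-acc  macro-f1  pct-correct"]
        for jm, row in df.iterrows():
            lines.append(
                f"{jm:>8}  {row.macro_accuracy:9.1f}  {row.macro_f1:8.1f}"
                f"  {row.percent_correct:11.1f}"
            )
        return "\n".join(lines)


def _composite_states(col) -> np.ndarray:
    """3-state codes from a column of (above, below) tuples."""
    above = np.array([t[0] for t in col], dtype=bool)
    below = np.array([t[1] for t in col], dtype=bool)
    return CompositeScheme("tmp", ("a", "b")).apply(above, below)


def _expert_bins(expert_df: pd.DataFrame, jm: str) -> tuple[np.ndarray, list[int]]:
    """Expert-scheme bin indices for a joint motion's features."""
    cols, n_bins = [], []
    for name in expert_feature_names(jm):
        scheme = EXPERT_SCHEMES[name]
        if isinstance(scheme, CompositeScheme):
            cols.append(_composite_states(expert_df[name]))
            n_bins.append(3)
        else:
            cols.append(scheme.apply(expert_df[name].to_numpy(dtype=float)))
            n_bins.append(scheme.n_bins)
    return np.column_stack(cols), n_bins


def _split_expert(expert_df: pd.DataFrame, jm: str):
    """Continuous columns (values) and composite columns (3-state codes)."""
    cont_names = [n for n in expert_feature_names(jm)
                  if not isinstance(EXPERT_SCHEMES[n], CompositeScheme)]
    comp_names = [n for n in expert_feature_names(jm)
                  if isinstance(EXPERT_SCHEMES[n], CompositeScheme)]
    cont = (expert_df[cont_names].to_numpy(dtype=float)
            if cont_names else np.empty((len(expert_df), 0)))
    comp = (np.column_stack([_composite_states(expert_df[n]) for n in comp_names])
            if comp_names else np.empty((len(expert_df), 0), dtype=int))
    return cont_names, cont, comp_names, comp


def _mdl_bin_fold(values_train, labels_train, values_all, name, cache, cache_key):
    """MDL scheme learned on the training fold, applied to all trials."""
    if cache is not None and cache_key in cache:
        scheme = cache[cache_key]
    else:
        scheme = mdl_discretize(values_train, labels_train, feature=name)
        if cache is not None:
            cache[cache_key] = scheme
    return scheme


def _onehot_blocks(codes: np.ndarray, n_bins: list[int]) -> np.ndarray:
    enc = clf.Encoding.onehot(n_bins)
    return enc.transform(codes) if codes.shape[1] else np.empty((codes.shape[0], 0))


def _stratified_patient_split(pids, labels, k, seed) -> dict[str, int]:
    """Patient-grouped k-way split balancing one label column.

    Same marginal-quota greedy as :func:`make_folds`, applied to a
    single joint motion's labels; used for the inner folds of the LR
    regularization grid so that small classes are spread across them.
    """
    classes = sorted(set(labels.tolist()))
    cidx = {c: i for i, c in enumerate(classes)}
    pvec: dict[str, np.ndarray] = {}
    for p, c in zip(pids, labels):
        v = pvec.setdefault(p, np.zeros(len(classes) + 1))
        v[cidx[c]] += 1.0
        v[-1] += 1.0
    quota = sum(pvec.values()) / k
    weight = 1.0 / np.maximum(quota, 1e-9)
    rng = np.random.default_rng(seed)
    order = sorted(pvec, key=lambda p: (-pvec[p][-1], p))
    fold_vec = np.zeros((k, len(classes) + 1))
    out: dict[str, int] = {}
    for p in order:
        v = pvec[p]
        scores = np.array([
            float(np.dot(weight * v, 2.0 * fold_vec[f] - 2.0 * quota + v))
            for f in range(k)
        ])
        f = int(rng.choice(np.flatnonzero(scores <= scores.min() + 1e-9)))
        out[p] = f
        fold_vec[f] += v
    return out


def _lr_fit_cell(X, y, tr, tr_classes, config, pids, encoding):
    """LR fit with the regularization strength chosen on inner folds.

    The inner split is patient-grouped and deterministic (patients of
    the training fold round-robin over ``inner_k`` folds); the score is
    macro accuracy pooled over the inner test folds.  Ties prefer the
    stronger regularization.  Only training-fold data is touched.
    """
    lam = config.lam
    grid = config.lam_grid
    if grid and len(grid) > 1:
        tr_idx = np.flatnonzero(tr)
        tr_pids = pids[tr_idx]
        fold_of_pid = _stratified_patient_split(
            tr_pids, y[tr_idx], config.inner_k, config.seed
        )
        ifold = np.array([fold_of_pid[p] for p in tr_pids])
        scored = []
        for lam_c in grid:
            y_true, y_pred = [], []
            for f in range(config.inner_k):
                itr, ite = tr_idx[ifold != f], tr_idx[ifold == f]
                cls = tuple(c for c in tr_classes if c in set(y[itr]))
                if len(ite) == 0 or len(cls) < 2:
                    continue
                m = clf.lr_fit(X[itr], y[itr], classes=cls, lam=lam_c,
                               tol=config.lr_tol, max_iter=config.lr_max_iter,
                               encoding=encoding)
                post = clf.lr_posterior_matrix(m, X[ite])
                y_pred += [cls[i] for i in post.argmax(axis=1)]
                y_true += y[ite].tolist()
            if y_true:
                cls_all = sorted(set(y_true) | set(y_pred))
                scored.append((macro_metrics(y_true, y_pred, cls_all)[0], lam_c))
            else:
                scored.append((-1.0, lam_c))
        lam = max(scored)[1]
    model = clf.lr_fit(X[tr], y[tr], classes=tr_classes, lam=lam,
                       tol=config.lr_tol, max_iter=config.lr_max_iter,
                       encoding=encoding)
    return model


def run_experiment(
    dataset: Dataset,
    band: NormativeBand,
    approach: str,
    classifier: str,
    config: ExperimentConfig | None = None,
    mdl_cache: dict | None = None,
) -> EvaluationReport:
    """Cross-validated evaluation of one approach x classifier cell.

    Returns macro metrics, confusion and average-posterior matrices
    per joint motion.  Pass the same ``config.folds`` to every cell so
    all of them share one fold assignment; ``mdl_cache`` may be shared
    between approaches 2a/2b and 3 on the same dataset and folds to
    avoid re-learning identical discretizations.
    """
    approach, classifier = str(approach), str(classifier)
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}; expected one of {APPROACHES}")
    if classifier not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier!r}")
    config = config or ExperimentConfig()
    folds = config.folds or make_folds(dataset, config.k, config.seed)
    trial_fold = folds.trial_folds(dataset)

    expert_df = extract_expert_matrix(dataset, band, config.features)
    full_df = (extract_full_matrix(dataset, band, config.features)
               if approach in ("2a", "2b") else None)

    results: dict[str, JointMotionResult] = {}
    logger.debug("mdl cache: %s", "shared" if mdl_cache is not None else "local")
    for jm in JOINT_MOTIONS:
        labeled = np.array([jm in t.labels for t in dataset])
        if not labeled.any():
            continue
        y_all = np.array([t.labels.get(jm, "") for t in dataset])
        classes = tuple(c for c in JOINT_MOTIONS[jm].classes
                        if c in set(y_all[labeled]))
        li = np.flatnonzero(labeled)
        y = y_all[li]
        pids = np.array([t.patient_id for t in dataset], dtype=object)[li]
        fold_of = trial_fold[li]

        y_pred = np.empty(len(li), dtype=object)
        P = np.zeros((len(li), len(classes)))
        n_feat_folds: list[int] = []
        sel_folds: dict[int, list[str]] = {}
        global_selected = None
        if approach == "2b" and not config.selection_per_fold:
            # single whole-dataset selection (leaky by construction;
            # exposed for comparison with reports that selected once)
            X_all = full_df.iloc[li].to_numpy(dtype=float)
            kept, cols = [], {}
            for j, name in enumerate(full_df.columns):
                scheme = mdl_discretize(X_all[:, j], y, feature=name)
                if scheme.n_bins >= 2:
                    kept.append(name)
                    cols[name] = scheme.apply(X_all[:, j])
            if kept:
                global_selected = best_first_select(
                    pd.DataFrame(cols), y, stall_limit=config.stall_limit,
                )
            else:
                global_selected = []
        for f in sorted(set(fold_of.tolist())):
            tr = fold_of != f
            te = ~tr
            tr_classes = tuple(c for c in classes if c in set(y[tr]))
            pred, post, selected = _fit_predict_fold(
                approach, classifier, config, jm, expert_df, full_df,
                li, tr, te, y, tr_classes, mdl_cache, fold_id=f, pids=pids,
                global_selected=global_selected,
            )
            y_pred[te] = pred
            # embed the fold's posterior into the full class list
            col_idx = [classes.index(c) for c in tr_classes]
            P[np.ix_(np.flatnonzero(te), col_idx)] = post
            if selected is not None:
                n_feat_folds.append(len(selected))
                sel_folds[f] = list(selected)

        macro_acc, macro_f1, pct = macro_metrics(y, y_pred, classes)
        cm = confusion_matrix(y, y_pred, classes)
        results[jm] = JointMotionResult(
            joint_motion=jm, classes=classes,
            macro_accuracy=macro_acc, macro_f1=macro_f1, percent_correct=pct,
            confusion=cm, confusion_normalized=normalize_confusion(cm),
            avg_posterior=avg_posterior_matrix(y, P, classes),
            n_features_per_fold=n_feat_folds or None,
            selected_features_per_fold=sel_folds or None,
        )
    return EvaluationReport(
        approach=approach, classifier=classifier,
        per_joint_motion=results, config=replace(config, folds=folds),
    )


def _fit_predict_fold(approach, classifier, config, jm, expert_df, full_df,
                      li, tr, te, y, tr_classes, mdl_cache, fold_id, pids,
                      global_selected=None):
    """Train on the fold's training portion, predict its test portion.

    Returns (predicted labels, posterior matrix over tr_classes,
    selected feature names for approach 2b or None).
    """
    n_feat = None
    if approach == "1":
        bins, n_bins = _expert_bins(expert_df.iloc[li], jm)
        Xtr, Xte = bins[tr], bins[te]
        if classifier == "NB":
            model = clf.nb_fit(Xtr, y[tr], classes=tr_classes,
                               n_bins=n_bins, alpha=config.alpha)
            post = clf.nb_posterior_matrix(model, Xte)
        else:
            enc = clf.Encoding.onehot(n_bins)
            model = _lr_fit_cell(bins, y, tr, tr_classes, config, pids, enc)
            post = clf.lr_posterior_matrix(model, Xte)

    elif approach == "3":
        cont_names, cont, comp_names, comp = _split_expert(expert_df.iloc[li], jm)
        if classifier == "NB":
            blocks, n_bins = [], []
            for j, name in enumerate(cont_names):
                scheme = _mdl_bin_fold(
                    cont[tr, j], y[tr], cont[:, j], name, mdl_cache,
                    ("expert", jm, fold_id, name),
                )
                blocks.append(scheme.apply(cont[:, j]))
                n_bins.append(scheme.n_bins)
            for j in range(comp.shape[1]):
                blocks.append(comp[:, j])
                n_bins.append(3)
            bins = np.column_stack(blocks)
            model = clf.nb_fit(bins[tr], y[tr], classes=tr_classes,
                               n_bins=n_bins, alpha=config.alpha)
            post = clf.nb_posterior_matrix(model, bins[te])
        else:
            # raw continuous features (standardized on the training fold)
            # next to one-hot composite states
            std = clf.Encoding.standardize_fit(cont[tr]) if cont.shape[1] else None
            design = np.hstack(
                ([std.transform(cont)] if std is not None else [])
                + ([_onehot_blocks(comp, [3] * comp.shape[1])] if comp.shape[1] else [])
            )
            ident = clf.Encoding(kind="standardize",
                                 mean=np.zeros(design.shape[1]),
                                 scale=np.ones(design.shape[1]))
            model = _lr_fit_cell(design, y, tr, tr_classes, config, pids, ident)
            post = clf.lr_posterior_matrix(model, design[te])

    else:  # 2a / 2b on the full battery
        X = full_df.iloc[li].to_numpy(dtype=float)
        names = list(full_df.columns)
        if classifier == "NB" or approach == "2b":
            # MDL-discretize every feature on the training fold; features
            # for which no cut passes the criterion carry no information
            # and are dropped
            kept, bin_cols, n_bins = [], [], []
            for j, name in enumerate(names):
                scheme = _mdl_bin_fold(
                    X[tr, j], y[tr], X[:, j], name, mdl_cache,
                    ("full", jm, fold_id, name),
                )
                if scheme.n_bins < 2:
                    continue
                kept.append(name)
                bin_cols.append(scheme.apply(X[:, j]))
                n_bins.append(scheme.n_bins)
            bins = (np.column_stack(bin_cols) if bin_cols
                    else np.ones((X.shape[0], 0), dtype=int))
        if approach == "2b":
            if global_selected is not None:
                selected = [n for n in global_selected if n in kept]
            elif not kept:
                selected = []
            else:
                bdf = pd.DataFrame(bins[tr], columns=kept)
                ev = CfsEvaluator(bdf, y[tr])
                selected = best_first_select(
                    bdf, y[tr], stall_limit=config.stall_limit, evaluator=ev,
                )
            n_feat = selected
            sel_idx = [kept.index(s) for s in selected]
            if classifier == "NB":
                use_bins = bins[:, sel_idx] if sel_idx else np.ones(
                    (X.shape[0], 0), dtype=int)
                use_nb = [n_bins[i] for i in sel_idx]
                model = clf.nb_fit(use_bins[tr], y[tr], classes=tr_classes,
                                   n_bins=use_nb, alpha=config.alpha)
                post = clf.nb_posterior_matrix(model, use_bins[te])
            else:
                cols = [names.index(s) for s in selected]
                Xsel = X[:, cols] if cols else np.zeros((X.shape[0], 1))
                enc = clf.Encoding.standardize_fit(Xsel[tr])
                model = _lr_fit_cell(Xsel, y, tr, tr_classes, config, pids, enc)
                post = clf.lr_posterior_matrix(model, Xsel[te])
        elif classifier == "NB":  # 2a
            model = clf.nb_fit(bins[tr], y[tr], classes=tr_classes,
                               n_bins=n_bins, alpha=config.alpha)
            post = clf.nb_posterior_matrix(model, bins[te])
        else:  # 2a, LR
            enc = clf.Encoding.standardize_fit(X[tr])
            model = _lr_fit_cell(X, y, tr, tr_classes, config, pids, enc)
            post = clf.lr_posterior_matrix(model, X[te])

    pred = np.array([tr_classes[i] for i in np.argmax(post, axis=1)], dtype=object)
    return pred, post, n_feat


def run_cells(
    dataset: Dataset,
    band: NormativeBand,
    approaches=APPROACHES,
    classifiers=CLASSIFIERS,
    config: ExperimentConfig | None = None,
) -> dict[str, EvaluationReport]:
    """All requested approach x classifier cells on shared folds.

    Returns a mapping like ``{"NB1": report, "LR2b": report, ...}``.
    """
    config = config or ExperimentConfig()
    if config.folds is None:
        config = replace(config, folds=make_folds(dataset, config.k, config.seed))
    cache: dict = {}
    out = {}
    for a in approaches:
        for c in classifiers:
            out[f"{c}{a}"] = run_experiment(
                dataset, band, a, c, config, mdl_cache=cache,
            )
    return out


def cells_summary(reports: dict[str, EvaluationReport]) -> pd.DataFrame:
    """Overall macro metrics per cell (one row per approach x classifier)."""
    rows = []
    for name, rep in reports.items():
        rows.append({
            "cell": name,
            "macro_accuracy": rep.overall_macro_accuracy,
            "macro_f1": rep.overall_macro_f1,
            "percent_correct": rep.overall_percent_correct,
        })
    return pd.DataFrame(rows).set_index("cell")
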