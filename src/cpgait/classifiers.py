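"""Probabilistic classifiers: categorical Naive Bayes and multinomial
logistic regression.

Both emit full posterior vectors over a joint motion's pattern classes
(soft assignment) next to the maximum-a-posteriori label (hard
assignment).

Naive Bayes assumes the discrete features are conditionally
independent given the class: ``p(c | f) ~ p(c) * prod_i p(f_i | c)``,
with the conditional probability tables estimated by counting and
optionally smoothed with a pseudo-count ``alpha``.  With ``alpha = 0``
(pure maximum likelihood) a feature bin never seen for any class makes
every class likelihood zero; that degenerate case falls back to the
class prior.

Logistic regression maximizes the softmax likelihood (the multinomial
generalization of the sigmoid model; the binary case reduces exactly
to it) with an L2 penalty ``lam`` on the non-intercept weights,
minimized with a quasi-Newton method (L-BFGS) from a zero start, which
makes the fit deterministic; the objective is convex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

logger = logging.getLogger(__name__)


class ClassifierError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Naive Bayes
# ---------------------------------------------------------------------------

@dataclass
class NBModel:
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    n_bins: tuple[int, ...]
    priors: np.ndarray                      # (n_classes,)
    cpts: list[np.ndarray]                  # per feature: (n_classes, n_bins)
    alpha: float

    def to_json(self) -> dict:
        return {
            "classes": list(self.classes),
            "features": list(self.feature_names),
            "n_bins": list(self.n_bins),
            "priors": self.priors.tolist(),
            "cpts": [c.tolist() for c in self.cpts],
            "alpha": self.alpha,
        }


def nb_fit(X, labels, classes=None, n_bins=None, alpha: float = 1.0,
           feature_names=None) -> NBModel:
    """Fit the class priors and CPTs from 1-based bin indices by counting.

    ``CPT[c, b] = (count(f = b, c) + alpha) / (count(c) + alpha * B)``
    with ``B`` the feature's bin count.  Every declared class must be
    present in the training data.
    """
    X = np.asarray(X, dtype=int)
    if X.ndim != 2:
        raise ClassifierError("X must be a 2-D bin-index matrix")
    labels = np.asarray(labels)
    n, p = X.shape
    if classes is None:
        classes = tuple(sorted(set(labels.tolist())))
    classes = tuple(classes)
    missing = [c for c in classes if c not in set(labels.tolist())]
    if missing:
        raise ClassifierError(f"class(es) absent from training data: {missing}")
    unknown = set(labels.tolist()) - set(classes)
    if unknown:
        raise ClassifierError(f"labels outside the declared class list: {unknown}")
    if np.any(X < 1):
        raise ClassifierError("bin indices must be 1-based")
    if n_bins is None:
        n_bins = tuple(int(b) for b in X.max(axis=0))
    n_bins = tuple(int(b) for b in n_bins)
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(p))

    y = np.array([classes.index(l) for l in labels.tolist()])
    class_counts = np.bincount(y, minlength=len(classes)).astype(float)
    priors = class_counts / n
    cpts = []
    for j, B in enumerate(n_bins):
        if np.any(X[:, j] > B):
            raise ClassifierError(
                f"feature {feature_names[j]!r}: bin index exceeds its bin count {B}"
            )
        counts = np.zeros((len(classes), B))
        np.add.at(counts, (y, X[:, j] - 1), 1.0)
        cpt = (counts + alpha) / (class_counts[:, None] + alpha * B)
        cpts.append(cpt)
    return NBModel(
        classes=classes, feature_names=tuple(feature_names), n_bins=n_bins,
        priors=priors, cpts=cpts, alpha=float(alpha),
    )


def nb_log_posterior_matrix(model: NBModel, X) -> np.ndarray:
    """Normalized log posteriors, one row per instance."""
    X = np.atleast_2d(np.asarray(X, dtype=int))
    n = X.shape[0]
    with np.errstate(divide="ignore"):
        log_prior = np.log(model.priors)
        scores = np.tile(log_prior, (n, 1))
        for j, cpt in enumerate(model.cpts):
            idx = np.clip(X[:, j] - 1, 0, cpt.shape[1] - 1)
            if np.any((X[:, j] < 1) | (X[:, j] > cpt.shape[1])):
                raise ClassifierError(
                    f"feature {model.feature_names[j]!r}: bin index out of range"
                )
            scores += np.log(cpt[:, idx]).T
    # alpha = 0 can zero out every class; fall back to the prior there
    dead = ~np.isfinite(scores).any(axis=1)
    if np.any(dead):
        logger.warning(
            "%d instance(s) with zero likelihood for every class; "
            "falling back to the class prior", int(dead.sum()),
        )
        scores[dead] = log_prior
    return scores - logsumexp(scores, axis=1, keepdims=True)


def nb_posterior(model: NBModel, x) -> np.ndarray:
    """Posterior probability vector for one instance of bin indices."""
    return np.exp(nb_log_posterior_matrix(model, np.atleast_2d(x))[0])


def nb_posterior_matrix(model: NBModel, X) -> np.ndarray:
    return np.exp(nb_log_posterior_matrix(model, X))


def nb_map(model: NBModel, x) -> str:
    """MAP class; exact ties resolve to the first declared class."""
    post = nb_posterior(model, x)
    return model.classes[int(np.argmax(post))]


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

@dataclass
class Encoding:
    """Deterministic design-matrix descriptor fitted on training data.

    ``kind='onehot'`` expands 1-based bin indices into indicator
    columns per (feature, bin); ``kind='standardize'`` centers/scales
    continuous columns with the training mean/SD (constant columns get
    unit scale, contributing nothing).
    """

    kind: str
    n_bins: tuple[int, ...] = ()
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None

    @classmethod
    def onehot(cls, n_bins) -> "Encoding":
        return cls(kind="onehot", n_bins=tuple(int(b) for b in n_bins))

    @classmethod
    def standardize_fit(cls, X) -> "Encoding":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(kind="standardize", mean=mean, scale=scale)

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.kind == "standardize":
            if X.shape[1] != self.mean.shape[0]:
                raise ClassifierError("encoding mismatch: wrong number of columns")
            return (X - self.mean) / self.scale
        if self.kind == "onehot":
            Xi = X.astype(int)
            if Xi.shape[1] != len(self.n_bins):
                raise ClassifierError("encoding mismatch: wrong number of columns")
            blocks = []
            for j, B in enumerate(self.n_bins):
                if np.any((Xi[:, j] < 1) | (Xi[:, j] > B)):
                    raise ClassifierError(
                        f"encoding mismatch: bin index out of range for feature {j}"
                    )
                block = np.zeros((Xi.shape[0], B))
                block[np.arange(Xi.shape[0]), Xi[:, j] - 1] = 1.0
                blocks.append(block)
            return np.hstack(blocks)
        raise ClassifierError(f"unknown encoding kind {self.kind!r}")


@dataclass
class LRModel:
    classes: tuple[str, ...]
    theta: np.ndarray           # (n_classes, 1 + n_encoded), first column intercept
    lam: float
    encoding: Encoding
    converged: bool = True
    n_iter: int = 0

    def to_json(self) -> dict:
        return {
            "classes": list(self.classes),
            "theta": self.theta.tolist(),
            "lambda": self.lam,
            "encoding": self.encoding.kind,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def lr_objective_grad(theta_flat, Xb, Y, lam):
    """Penalized cross-entropy and its gradient.

    ``J = -sum log softmax + lam * sum(theta_non_intercept^2)`` over a
    design matrix with a leading all-ones column.
    """
    n, d = Xb.shape
    K = Y.shape[1]
    theta = theta_flat.reshape(K, d)
    scores = Xb @ theta.T
    log_p = scores - logsumexp(scores, axis=1, keepdims=True)
    J = -float((Y * log_p).sum())
    P = np.exp(log_p)
    G = (P - Y).T @ Xb
    pen = theta.copy()
    pen[:, 0] = 0.0
    J += lam * float((pen ** 2).sum())
    G += 2.0 * lam * pen
    return J, G.ravel()


def lr_fit(X, labels, classes=None, lam: float = 1.0, tol: float = 1e-6,
           max_iter: int = 500, encoding: Encoding | None = None) -> LRModel:
    """Fit multinomial logistic regression on an encoded design matrix.

    ``X`` is raw input; it is transformed by ``encoding`` (default:
    standardization fitted on X).  Deterministic: zero initialization,
    quasi-Newton (L-BFGS) minimization until the projected gradient
    norm drops below ``tol`` or ``max_iter`` iterations.
    """
    labels = np.asarray(labels)
    if classes is None:
        classes = tuple(sorted(set(labels.tolist())))
    classes = tuple(classes)
    if len(classes) < 2:
        raise ClassifierError("logistic regression needs at least 2 classes")
    missing = [c for c in classes if c not in set(labels.tolist())]
    if missing:
        raise ClassifierError(f"class(es) absent from training data: {missing}")
    if encoding is None:
        encoding = Encoding.standardize_fit(X)
    Xe = encoding.transform(X)
    if not np.all(np.isfinite(Xe)):
        raise ClassifierError("design matrix contains non-finite values")
    n = Xe.shape[0]
    Xb = np.hstack([np.ones((n, 1)), Xe])
    Y = np.zeros((n, len(classes)))
    Y[np.arange(n), [classes.index(l) for l in labels.tolist()]] = 1.0

    x0 = np.zeros(len(classes) * Xb.shape[1])
    res = minimize(
        lr_objective_grad, x0, args=(Xb, Y, lam), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12},
    )
    if not res.success:
        logger.warning("logistic regression did not fully converge: %s", res.message)
    return LRModel(
        classes=classes, theta=res.x.reshape(len(classes), Xb.shape[1]),
        lam=float(lam), encoding=encoding, converged=bool(res.success),
        n_iter=int(res.nit),
    )


def lr_posterior_matrix(model: LRModel, X) -> np.ndarray:
    Xe = model.encoding.transform(X)
    Xb = np.hstack([np.ones((Xe.shape[0], 1)), Xe])
    return softmax(Xb @ model.theta.T, axis=1)


def lr_posterior(model: LRModel, x) -> np.ndarray:
    return lr_posterior_matrix(model, np.atleast_2d(np.asarray(x)))[0]


def lr_map(model: LRModel, x) -> str:
    return model.classes[int(np.argmax(lr_posterior(model, x)))]
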