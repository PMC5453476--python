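"""Naive Bayes and logistic regression against hand counts, brute-force
enumeration, finite differences and scikit-learn."""

import itertools

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import CategoricalNB

from cpgait.classifiers import (
    ClassifierError,
    Encoding,
    lr_fit,
    lr_map,
    lr_objective_grad,
    lr_posterior,
    lr_posterior_matrix,
    nb_fit,
    nb_map,
    nb_posterior,
    nb_posterior_matrix,
)


class TestNbFit:
    # 6 trials: class A x3 all f1=1; class B x3 with f1=(1,2,2)
    X = np.array([[1], [1], [1], [1], [2], [2]])
    y = np.array(["A", "A", "A", "B", "B", "B"])

    def test_ml_counting(self):
        m = nb_fit(self.X, self.y, alpha=0.0, n_bins=[2])
        assert m.priors == pytest.approx([0.5, 0.5])
        assert m.cpts[0][0, 0] == pytest.approx(1.0)       # p(f1=1 | A)
        assert m.cpts[0][1, 0] == pytest.approx(1 / 3)     # p(f1=1 | B)

    def test_laplace_smoothing(self):
        m = nb_fit(self.X, self.y, alpha=1.0, n_bins=[2])
        assert m.cpts[0][0, 0] == pytest.approx(4 / 5)

    def test_cpt_rows_normalized(self):
        m = nb_fit(self.X, self.y, alpha=1.0, n_bins=[2])
        for cpt in m.cpts:
            assert np.allclose(cpt.sum(axis=1), 1.0)

    def test_absent_class_rejected(self):
        with pytest.raises(ClassifierError, match="absent"):
            nb_fit(self.X, self.y, classes=("A", "B", "C"))


class TestNbPosterior:
    def test_uniform_cpts_return_priors(self):
        rng = np.random.default_rng(0)
        X = rng.integers(1, 3, size=(30, 2))
        y = rng.choice(["A", "B", "C"], 30)
        m = nb_fit(X, y, alpha=1.0)
        for cpt in m.cpts:
            cpt[:] = 1.0 / cpt.shape[1]
        post = nb_posterior(m, [1, 2])
        assert post == pytest.approx(m.priors)

    def test_hand_example(self):
        m = nb_fit(TestNbFit.X, TestNbFit.y, alpha=0.0, n_bins=[2])
        post = nb_posterior(m, [1])
        assert post[0] == pytest.approx(0.75)  # (1*.5)/(1*.5 + 1/3*.5)

    def test_sums_to_one(self):
        rng = np.random.default_rng(1)
        X = rng.integers(1, 4, size=(50, 3))
        y = rng.choice(["A", "B"], 50)
        m = nb_fit(X, y, alpha=1.0)
        P = nb_posterior_matrix(m, X)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_map_tie_goes_to_first_declared_class(self):
        X = np.array([[1], [2]])
        y = np.array(["A", "B"])
        m = nb_fit(X, y, alpha=1.0, n_bins=[2])
        # symmetric training data: observing nothing informative yields a tie
        m.cpts[0][:] = 0.5
        assert nb_map(m, [1]) == "A"

    def test_zero_likelihood_falls_back_to_prior(self, caplog):
        X = np.array([[1], [1], [1], [1]])
        y = np.array(["A", "A", "A", "B"])
        m = nb_fit(X, y, alpha=0.0, n_bins=[2])
        with caplog.at_level("WARNING"):
            post = nb_posterior(m, [2])  # bin never seen for any class
        assert post == pytest.approx([0.75, 0.25])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_joint_enumeration_oracle(self, seed):
        """Exact agreement with brute-force joint-table enumeration."""
        rng = np.random.default_rng(seed)
        n_feat = int(rng.integers(1, 5))
        bins = [int(b) for b in rng.integers(2, 4, n_feat)]
        classes = ["c1", "c2", "c3"]
        X = np.column_stack([rng.integers(1, b + 1, 60) for b in bins])
        y = rng.choice(classes, 60)
        m = nb_fit(X, y, classes=classes, n_bins=bins, alpha=1.0)
        for combo in itertools.product(*[range(1, b + 1) for b in bins]):
            # oracle: p(c) * prod p(f|c) over the explicit joint table
            joint = np.array([
                m.priors[ci] * np.prod([
                    m.cpts[j][ci, combo[j] - 1] for j in range(n_feat)
                ])
                for ci in range(len(classes))
            ])
            expected = np.log(joint / joint.sum())
            got = np.log(nb_posterior(m, list(combo)))
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_matches_sklearn_categorical_nb(self):
        rng = np.random.default_rng(9)
        X = np.column_stack([rng.integers(1, 4, 80), rng.integers(1, 3, 80)])
        y = rng.choice(["A", "B", "C"], 80)
        m = nb_fit(X, y, alpha=1.0, n_bins=[3, 2])
        sk = CategoricalNB(alpha=1.0)
        sk.fit(X - 1, y)
        np.testing.assert_allclose(
            nb_posterior_matrix(m, X), sk.predict_proba(X - 1), atol=1e-9
        )

    def test_permutation_equivariant_under_class_relabeling(self):
        rng = np.random.default_rng(2)
        X = rng.integers(1, 3, size=(40, 2))
        y = rng.choice(["A", "B", "C"], 40)
        m1 = nb_fit(X, y, classes=("A", "B", "C"), alpha=1.0, n_bins=[2, 2])
        m2 = nb_fit(X, y, classes=("C", "A", "B"), alpha=1.0, n_bins=[2, 2])
        p1 = nb_posterior(m1, [1, 2])
        p2 = nb_posterior(m2, [1, 2])
        assert p1[0] == pytest.approx(p2[1]) and p1[2] == pytest.approx(p2[0])


class TestLogisticRegression:
    def _toy(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        y = np.array(["neg"] * (n // 2) + ["pos"] * (n // 2))
        x = np.where(y == "pos", 2.0, -2.0)[:, None] + rng.normal(0, 0.3, (n, 1))
        return x, y

    def test_separable_toy_perfect_training_accuracy(self):
        x, y = self._toy()
        m = lr_fit(x, y, lam=0.0)
        pred = [lr_map(m, xi) for xi in x]
        assert (np.array(pred) == y).mean() == 1.0

    def test_huge_lambda_recovers_class_frequencies(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (90, 2))
        y = np.array(["a"] * 60 + ["b"] * 30)
        m = lr_fit(x, y, lam=1e7)
        assert np.abs(m.theta[:, 1:]).max() < 1e-3
        post = lr_posterior_matrix(m, x).mean(axis=0)
        assert post == pytest.approx([2 / 3, 1 / 3], abs=1e-3)

    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(3)
        n, d, K = 25, 3, 3
        Xb = np.hstack([np.ones((n, 1)), rng.normal(0, 1, (n, d))])
        Y = np.eye(K)[rng.integers(0, K, n)]
        theta = rng.normal(0, 0.5, K * (d + 1))
        _, grad = lr_objective_grad(theta, Xb, Y, lam=0.7)
        eps = 1e-6
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (lr_objective_grad(tp, Xb, Y, 0.7)[0]
                  - lr_objective_grad(tm, Xb, Y, 0.7)[0]) / (2 * eps)
            assert abs(fd - grad[i]) / max(abs(fd), 1.0) < 1e-5

    def test_zero_weights_give_uniform_posterior(self):
        x, y = self._toy()
        m = lr_fit(x, y, lam=1.0)
        m.theta[:] = 0.0
        assert lr_posterior(m, x[0]) == pytest.approx([0.5, 0.5])

    def test_binary_score_zero_is_half(self):
        # with weights making the two class scores equal, sigmoid(0) = 1/2
        x, y = self._toy()
        m = lr_fit(x, y, lam=1.0)
        m.theta[:] = np.array([[0.3, 1.2], [0.3, 1.2]])
        assert lr_posterior(m, x[0])[0] == pytest.approx(0.5)

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (40, 3))
        y = rng.choice(["a", "b", "c"], 40)
        m = lr_fit(x, y, lam=0.5)
        m.theta[:] = rng.normal(0, 2, m.theta.shape)
        P = lr_posterior_matrix(m, x)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_objective_convex_same_minimum_from_random_starts(self):
        from scipy.optimize import minimize
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, (50, 2))
        y = rng.choice(["a", "b", "c"], 50)
        Xb = np.hstack([np.ones((50, 1)), x])
        Y = np.eye(3)[[list("abc").index(c) for c in y]]
        vals = []
        for s in range(3):
            x0 = np.random.default_rng(s).normal(0, 3, 9)
            res = minimize(lr_objective_grad, x0, args=(Xb, Y, 1.0), jac=True,
                           method="L-BFGS-B", options={"gtol": 1e-9})
            vals.append(res.fun)
        assert max(vals) - min(vals) < 1e-5

    def test_matches_sklearn_multinomial(self):
        # 3 classes so scikit-learn uses the same full softmax
        # parameterization; its penalty 1/(2C) matches lam via C = 1/(2*lam)
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, (150, 3))
        logits = x @ rng.normal(0, 1, (3, 3)) + rng.normal(0, 0.5, (150, 3))
        y = np.array(["u", "v", "w"])[np.argmax(logits, axis=1)]
        lam = 0.5
        ident = Encoding(kind="standardize", mean=np.zeros(3), scale=np.ones(3))
        m = lr_fit(x, y, lam=lam, encoding=ident, tol=1e-10)
        sk = LogisticRegression(C=1.0 / (2 * lam), tol=1e-10, max_iter=5000)
        sk.fit(x, y)
        np.testing.assert_allclose(
            lr_posterior_matrix(m, x), sk.predict_proba(x), atol=1e-3
        )

    def test_single_class_rejected(self):
        with pytest.raises(ClassifierError):
            lr_fit(np.zeros((5, 1)), np.array(["a"] * 5))

    def test_encoding_mismatch_rejected(self):
        x, y = self._toy()
        m = lr_fit(x, y, lam=1.0)
        with pytest.raises(ClassifierError):
            lr_posterior_matrix(m, np.zeros((3, 4)))
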