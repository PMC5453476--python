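"""Fold construction, metrics and the experiment driver."""

import numpy as np
import pandas as pd
import pytest

from cpgait.core import Dataset, JOINT_MOTIONS
from cpgait.evaluation import (
    ExperimentConfig,
    avg_posterior_matrix,
    confusion_matrix,
    macro_metrics,
    make_folds,
    run_cells,
    run_experiment,
)
from cpgait.synthetic import GeneratorConfig, generate_cp_dataset, noise_free

from conftest import make_trial


def _tiny_config():
    return ExperimentConfig(k=3, seed=5, lam_grid=None)


class TestMakeFolds:
    def test_one_patient_per_fold_when_k_equals_patients(self):
        ds = Dataset([
            make_trial(lambda t, d: np.zeros(51), trial_id=f"t{i}",
                       patient_id=f"p{i}")
            for i in range(10)
        ])
        folds = make_folds(ds, k=10, seed=0)
        assert sorted(folds.patient_to_fold.values()) == list(range(1, 11))

    def test_patient_exclusive(self, small_dataset):
        folds = make_folds(small_dataset, k=5, seed=1)
        trial_folds = folds.trial_folds(small_dataset)
        for pid, trials in small_dataset.patients.items():
            fs = {folds.patient_to_fold[pid]}
            assert {trial_folds[i] for i, t in enumerate(small_dataset)
                    if t.patient_id == pid} == fs

    def test_too_few_patients(self, small_dataset):
        with pytest.raises(ValueError):
            make_folds(small_dataset, k=100)

    def test_stratification_within_10_points(self):
        # balanced class priors: every per-fold class proportion stays
        # within 10 percentage points of the global proportion
        prior = {jm: {c: 1.0 for c in JOINT_MOTIONS[jm].classes}
                 for jm in JOINT_MOTIONS}
        ds = generate_cp_dataset(GeneratorConfig(n_patients=250, seed=3,
                                                 class_prior=prior))
        folds = make_folds(ds, k=10, seed=3)
        tf = folds.trial_folds(ds)
        for jm in JOINT_MOTIONS:
            labels = np.array([t.labels[jm] for t in ds])
            for cls in JOINT_MOTIONS[jm].classes:
                global_prop = (labels == cls).mean()
                for f in range(1, 11):
                    sel = tf == f
                    assert abs((labels[sel] == cls).mean() - global_prop) <= 0.10


class TestMetrics:
    def test_perfect_prediction(self):
        y = ["a", "b", "a", "c"]
        acc, f1, pct = macro_metrics(y, y, ["a", "b", "c"])
        assert (acc, f1, pct) == (100.0, 100.0, 100.0)

    def test_hand_computed_three_class_example(self):
        # confusion counts [[8,2,0],[1,9,0],[0,5,5]]
        y_true = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        y_pred = (["a"] * 8 + ["b"] * 2 + ["a"] * 1 + ["b"] * 9
                  + ["b"] * 5 + ["c"] * 5)
        acc, f1, pct = macro_metrics(y_true, y_pred, ["a", "b", "c"])
        recalls = [0.8, 0.9, 0.5]
        precisions = [8 / 9, 9 / 16, 1.0]
        f1s = [2 * p * r / (p + r) for p, r in zip(precisions, recalls)]
        assert acc == pytest.approx(100 * np.mean(recalls))
        assert f1 == pytest.approx(100 * np.mean(f1s))
        assert pct == pytest.approx(100 * 22 / 30)

    def test_degenerate_single_class_predictor(self):
        y_true = ["a", "b"] * 10
        y_pred = ["a"] * 20
        acc, _, _ = macro_metrics(y_true, y_pred, ["a", "b"])
        assert acc == pytest.approx(50.0)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            macro_metrics(["a", "x"], ["a", "a"], ["a", "b"])

    def test_confusion_layout(self):
        cm = confusion_matrix(["a", "a", "b"], ["b", "a", "b"], ["a", "b"])
        assert cm.loc["a", "b"] == 1 and cm.loc["b", "b"] == 1


class TestAvgPosterior:
    def test_one_hot_posteriors_identity(self):
        y = ["a", "b", "c"]
        P = np.eye(3)
        out = avg_posterior_matrix(y, P, ["a", "b", "c"])
        assert np.allclose(out.to_numpy(), np.eye(3))

    def test_uniform_posteriors(self):
        y = ["a", "a", "b"]
        P = np.full((3, 2), 0.5)
        out = avg_posterior_matrix(y, P, ["a", "b"])
        assert np.allclose(out.to_numpy(), 0.5)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        P = rng.dirichlet(np.ones(3), size=20)
        y = rng.choice(["a", "b", "c"], 20)
        out = avg_posterior_matrix(y, P, ["a", "b", "c"])
        sums = out.sum(axis=1).to_numpy()
        assert np.allclose(sums[~np.isnan(out.to_numpy()).any(axis=1)], 1.0)

    def test_empty_class_row_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            out = avg_posterior_matrix(["a"], [[0.4, 0.6]], ["a", "b"])
        assert np.isnan(out.loc["b"]).all()


class TestRunExperiment:
    def test_report_shape_and_overall_row(self, band, small_dataset):
        rep = run_experiment(small_dataset, band, "1", "NB", _tiny_config())
        assert set(rep.per_joint_motion) == set(JOINT_MOTIONS)
        summary = rep.summary()
        assert len(summary) == 12
        assert summary.loc["overall", "macro_accuracy"] == pytest.approx(
            np.mean([r.macro_accuracy for r in rep.per_joint_motion.values()])
        )

    def test_single_class_prior_trivially_perfect(self, band):
        # all-normal one-hot priors: one class per joint motion, NB scores 100
        prior = {
            jm: {c: (100.0 if c.endswith("0") else 0.0)
                 for c in JOINT_MOTIONS[jm].classes}
            for jm in JOINT_MOTIONS
        }
        ds = generate_cp_dataset(noise_free(GeneratorConfig(
            n_patients=6, seed=8, class_prior=prior)))
        rep = run_experiment(ds, band, "1", "NB", _tiny_config())
        assert rep.overall_macro_accuracy == pytest.approx(100.0)

    def test_noise_free_multiclass_perfect(self, band):
        # noise-free patterns are separable by construction; prevalences
        # below ~3% are zeroed so that every class is carried by enough
        # patients for each training fold to see it at this small scale
        from cpgait.core import CLASS_FREQUENCIES
        prior = {
            jm: {c: (f if f >= 3.0 else 0.0)
                 for c, f in CLASS_FREQUENCIES[jm].items()}
            for jm in JOINT_MOTIONS
        }
        ds = generate_cp_dataset(noise_free(GeneratorConfig(
            n_patients=60, seed=8, class_prior=prior)))
        rep = run_experiment(ds, band, "1", "NB", _tiny_config())
        assert rep.overall_macro_accuracy == pytest.approx(100.0)

    def test_posterior_rows_sum_to_one(self, band, small_dataset):
        rep = run_experiment(small_dataset, band, "1", "NB", _tiny_config())
        for r in rep.per_joint_motion.values():
            sums = r.avg_posterior.sum(axis=1).to_numpy()
            valid = ~np.isnan(r.avg_posterior.to_numpy()).any(axis=1)
            assert np.allclose(sums[valid], 1.0, atol=1e-9)

    def test_folds_shared_across_cells(self, band, small_dataset):
        reports = run_cells(small_dataset, band, approaches=("1",),
                            classifiers=("NB", "LR"), config=_tiny_config())
        f_nb = reports["NB1"].config.folds.patient_to_fold
        f_lr = reports["LR1"].config.folds.patient_to_fold
        assert f_nb == f_lr

    def test_rerun_identical(self, band, small_dataset):
        r1 = run_experiment(small_dataset, band, "1", "NB", _tiny_config())
        r2 = run_experiment(small_dataset, band, "1", "NB", _tiny_config())
        assert r1.summary().equals(r2.summary())

    def test_approach_3_reports_selected_nothing_but_runs(self, band, small_dataset):
        rep = run_experiment(small_dataset, band, "3", "NB", _tiny_config())
        # composite-only joint motions pass through unchanged: HT and FPA
        # behave exactly as in approach 1
        rep1 = run_experiment(small_dataset, band, "1", "NB", _tiny_config())
        for jm in ("HT", "FPA"):
            assert rep.per_joint_motion[jm].confusion.equals(
                rep1.per_joint_motion[jm].confusion
            )

    def test_unknown_approach_rejected(self, band, small_dataset):
        with pytest.raises(ValueError):
            run_experiment(small_dataset, band, "4", "NB", _tiny_config())


@pytest.fixture(scope="module")
def tiny():
    return generate_cp_dataset(GeneratorConfig(n_patients=12, seed=17))


class TestApproach2Small:
    """2a/2b on a reduced dataset exercise the full-battery path."""

    def test_2b_selects_features_and_reports_counts(self, tiny, band):
        rep = run_experiment(tiny, band, "2b", "NB", _tiny_config())
        counts = [r.n_features_mean for r in rep.per_joint_motion.values()]
        assert all(c is not None and c >= 1 for c in counts)

    def test_2b_global_selection_mode(self, tiny, band):
        import dataclasses
        cfg = dataclasses.replace(_tiny_config(), selection_per_fold=False)
        rep = run_experiment(tiny, band, "2b", "NB", cfg)
        # one shared subset: every fold reports the same selected names
        for r in rep.per_joint_motion.values():
            subsets = {tuple(v) for v in r.selected_features_per_fold.values()}
            assert len(subsets) <= 2  # identical up to fold-wise informativeness

    def test_2a_runs_both_classifiers(self, tiny, band):
        cache = {}
        for c in ("NB", "LR"):
            rep = run_experiment(tiny, band, "2a", c, _tiny_config(),
                                 mdl_cache=cache)
            assert 0 <= rep.overall_macro_accuracy <= 100
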