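"""Metrics, the one-class SVM contract, the CV harness and the paired test."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import f1_score, recall_score

import smellbench as sb
from smellbench.datatypes import DescriptorMatrix, FeatureTable
from smellbench.predict import (
    DEFAULT_BINARY_GRID,
    DEFAULT_OCSVM_GRID,
    repeated_stratified_folds,
)


def labels_from(y: np.ndarray, names=None) -> DescriptorMatrix:
    y = np.atleast_2d(np.asarray(y, dtype=int))
    if y.shape[0] == 1:
        y = y.T
    names = names or [f"d{i}" for i in range(y.shape[1])]
    return DescriptorMatrix(pd.DataFrame(y, index=[f"m{i}" for i in range(len(y))],
                                         columns=names))


class TestF1AndRecall:
    @pytest.mark.parametrize("tp,fp,fn,expected", [
        (2, 0, 0, (1.0, 1.0)),        # perfect prediction
        (1, 1, 1, (0.5, 0.5)),        # 2*0.5*0.5/(0.5+0.5)
        (0, 0, 3, (0.0, 0.0)),        # 0/0 convention
        (0, 5, 0, (0.0, 0.0)),
    ])
    def test_examples(self, tp, fp, fn, expected):
        assert sb.f1_and_recall(tp, fp, fn) == pytest.approx(expected)

    def test_agrees_with_sklearn_on_random_predictions(self, rng):
        for _ in range(20):
            truth = rng.integers(0, 2, size=50)
            pred = rng.integers(0, 2, size=50)
            tp = int(np.sum((pred == 1) & (truth == 1)))
            fp = int(np.sum((pred == 1) & (truth == 0)))
            fn = int(np.sum((pred == 0) & (truth == 1)))
            f1, rec = sb.f1_and_recall(tp, fp, fn)
            assert f1 == pytest.approx(f1_score(truth, pred, zero_division=0))
            assert rec == pytest.approx(recall_score(truth, pred, zero_division=0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sb.f1_and_recall(-1, 0, 0)


class TestOneClassSVM:
    @pytest.mark.parametrize("nu", [0.1, 0.3])
    def test_nu_property_bounds_outliers_and_support_vectors(self, nu, rng):
        x = rng.normal(size=(200, 2))
        model = sb.train_one_class(x, sb.OCSVMSpec(nu=nu))
        assert model.training_outlier_fraction(x) <= nu + 0.05
        assert model.support_fraction >= nu - 0.05

    def test_far_outlier_scored_out_of_class(self, rng):
        x = rng.normal(size=(150, 2))
        model = sb.train_one_class(x, sb.OCSVMSpec(nu=0.1))
        far = np.array([[100.0, 100.0]])
        assert sb.predict_descriptor(model, far)[0] == 1

    def test_duplicating_training_rows_keeps_outlier_fraction(self, rng):
        x = rng.normal(size=(120, 3))
        spec = sb.OCSVMSpec(nu=0.2)
        frac = sb.train_one_class(x, spec).training_outlier_fraction(x)
        doubled = np.vstack([x, x])
        frac2 = sb.train_one_class(doubled, spec).training_outlier_fraction(doubled)
        assert abs(frac - frac2) <= 0.05

    def test_training_rows_flagged_at_most_near_nu(self, rng):
        x = rng.normal(size=(200, 2))
        model = sb.train_one_class(x, sb.OCSVMSpec(nu=0.1))
        assert sb.predict_descriptor(model, x).mean() <= 0.15

    def test_validation(self, rng):
        with pytest.raises(ValueError):
            sb.train_one_class(rng.normal(size=(1, 2)))
        with pytest.raises(ValueError):
            sb.OCSVMSpec(nu=0.0)
        model = sb.train_one_class(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError, match="features"):
            model.decision_scores(rng.normal(size=(4, 2)))


class TestStratifiedFolds:
    def test_folds_partition_and_spread_positives(self, rng):
        y = np.zeros(100, dtype=int)
        y[:7] = 1  # fewer positives than folds
        folds = list(repeated_stratified_folds(y, k=10, repeats=3, seed=5))
        assert len(folds) == 30
        for rep in range(3):
            block = folds[rep * 10:(rep + 1) * 10]
            vals = np.concatenate([v for _, v in block])
            assert sorted(vals) == list(range(100))  # exact partition per repeat
            pos_per_fold = [int(y[v].sum()) for _, v in block]
            assert max(pos_per_fold) - min(pos_per_fold) <= 1

    def test_deterministic_in_seed(self):
        y = np.array([0, 1] * 20)
        a = list(repeated_stratified_folds(y, 4, 2, seed=9))
        b = list(repeated_stratified_folds(y, 4, 2, seed=9))
        for (ta, va), (tb, vb) in zip(a, b):
            np.testing.assert_array_equal(va, vb)
            np.testing.assert_array_equal(ta, tb)

    def test_k_validation(self):
        with pytest.raises(ValueError):
            list(repeated_stratified_folds(np.zeros(5, int), k=6, repeats=1, seed=0))


class TestEvaluateRepeatedCV:
    def test_separable_synthetic_data_scores_high_f1(self, rng):
        # positives sit 8 sd away from the majority cloud
        n = 240
        y = np.zeros(n, dtype=int)
        y[:60] = 1
        x = rng.normal(size=(n, 2))
        x[y == 1] += 8.0
        # a tight, smooth frontier (small nu, small gamma) suits cleanly
        # separable data: nu also lower-bounds the training outlier rate,
        # hence the held-out false positives
        result = sb.evaluate_repeated_cv(x, labels_from(y), "ocsvm",
                                         sb.OCSVMSpec(nu=0.01, gamma=0.01),
                                         k=5, repeats=2, seed=3)
        assert result.mean_f1("d0") >= 0.95

    def test_permuted_labels_destroy_the_signal(self, rng):
        n = 120
        y = np.zeros(n, dtype=int)
        y[:30] = 1
        x = rng.normal(size=(n, 2))
        x[y == 1] += 8.0
        permuted = labels_from(rng.permutation(y))
        result = sb.evaluate_repeated_cv(x, permuted, "ocsvm",
                                         sb.OCSVMSpec(nu=0.1), k=5, repeats=2, seed=3)
        assert result.mean_f1("d0") < 0.6

    def test_one_result_per_descriptor_and_zero_positive_exclusion(self, rng):
        x = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, size=(40, 5))
        y[:, 2] = 0  # never positive
        result = sb.evaluate_repeated_cv(x, labels_from(y), "ocsvm",
                                         k=4, repeats=1, seed=1)
        assert result.labels == ["d0", "d1", "d3", "d4"]
        assert result.excluded == ["d2"]
        for lab in result.labels:
            assert len(result.fold_f1[lab]) == 4

    def test_fold_metrics_match_brute_force_confusion_recount(self, rng):
        x = rng.normal(size=(50, 3))
        y = (rng.uniform(size=(50, 3)) < 0.3).astype(int)
        result = sb.evaluate_repeated_cv(x, labels_from(y), "ocsvm",
                                         k=5, repeats=2, seed=8)
        for lab in result.labels:
            for (tp, fp, fn, tn), f1, rec in zip(result.fold_counts[lab],
                                                 result.fold_f1[lab],
                                                 result.fold_recall[lab]):
                ef1, erec = sb.f1_and_recall(tp, fp, fn)
                assert f1 == ef1 and rec == erec

    def test_same_seed_reproduces_metrics_exactly(self, rng):
        x = rng.normal(size=(40, 3))
        y = (rng.uniform(size=(40, 2)) < 0.4).astype(int)
        r1 = sb.evaluate_repeated_cv(x, labels_from(y), "ocsvm", k=4, repeats=2, seed=13)
        r2 = sb.evaluate_repeated_cv(x, labels_from(y), "ocsvm", k=4, repeats=2, seed=13)
        for lab in r1.labels:
            np.testing.assert_array_equal(r1.fold_f1[lab], r2.fold_f1[lab])

    def test_binary_svm_handles_single_class_training_folds(self, rng):
        x = rng.normal(size=(30, 2))
        y = np.zeros(30, dtype=int)
        y[0] = 1  # one positive: most training folds see both, some folds don't
        result = sb.evaluate_repeated_cv(x, labels_from(y), "binary_svm",
                                         k=3, repeats=1, seed=2)
        assert set(result.labels) == {"d0"}

    def test_misaligned_rows_rejected(self, rng):
        x = FeatureTable(pd.DataFrame(rng.normal(size=(10, 2)),
                                      index=[f"x{i}" for i in range(10)]),
                         provenance="synthetic")
        with pytest.raises(ValueError, match="aligned"):
            sb.evaluate_repeated_cv(x, labels_from(np.ones(10, int)), k=2)


class TestHyperparameterSearch:
    def test_single_spec_grid_returns_it(self, rng):
        x = rng.normal(size=(30, 2))
        y = (rng.uniform(size=30) < 0.3).astype(int)
        spec = sb.OCSVMSpec(nu=0.2)
        best = sb.search_hyperparameters(x, labels_from(y), [spec], k=3, repeats=1, seed=1)
        assert best["d0"] == spec

    def test_ties_prefer_smaller_nu(self, rng):
        # labels with no positives in features' reach: every spec scores 0
        x = rng.normal(size=(30, 2))
        y = np.zeros(30, dtype=int)
        y[0] = 1
        grid = [sb.OCSVMSpec(nu=0.5, gamma=1.0), sb.OCSVMSpec(nu=0.01, gamma=1.0)]
        best = sb.search_hyperparameters(x, labels_from(y), grid, k=3, repeats=1, seed=4)
        chosen = best["d0"]
        r = {s: sb.evaluate_repeated_cv(x, labels_from(y), "ocsvm", s,
                                        k=3, repeats=1, seed=4).mean_f1("d0")
             for s in grid}
        if r[grid[0]] == r[grid[1]]:
            assert chosen.nu == 0.01

    def test_default_grids_are_well_formed(self):
        assert len(DEFAULT_OCSVM_GRID) == 24
        assert len(DEFAULT_BINARY_GRID) == 4
        with pytest.raises(ValueError, match="non-empty"):
            sb.search_hyperparameters(np.zeros((4, 1)), labels_from(np.ones(4, int)), [])


class TestCompareFeatureSets:
    @staticmethod
    def result_from_f1(values: dict[str, float]) -> sb.EvaluationResult:
        return sb.EvaluationResult(
            fold_f1={k: np.array([v]) for k, v in values.items()},
            fold_recall={k: np.array([v]) for k, v in values.items()},
            fold_counts={k: [(0, 0, 0, 0)] for k in values},
            k=1, repeats=1, seed=0, model_kind="ocsvm")

    def test_closed_form_example(self):
        a = self.result_from_f1({f"d{i}": v for i, v in
                                 enumerate([0.2, 0.2, 0.2, 0.0])})
        b = self.result_from_f1({f"d{i}": 0.1 for i in range(4)})
        cmp = sb.compare_feature_sets(a, b)  # d = (0.1, 0.1, 0.1, -0.1)
        assert cmp.t_statistic == pytest.approx(1.0, abs=1e-12)
        assert cmp.p_value == pytest.approx(0.391002218700,  abs=1e-6)
        assert cmp.n_pairs == 4

    def test_self_comparison_flags_exact_equality(self):
        a = self.result_from_f1({"d0": 0.3, "d1": 0.6})
        cmp = sb.compare_feature_sets(a, a)
        assert cmp.exactly_equal and cmp.p_value == 1.0 and not np.isnan(cmp.t_statistic)

    def test_matches_scipy_ttest_rel_to_1e10(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            fa = rng.uniform(size=n)
            fb = np.clip(fa + rng.normal(0, 0.1, size=n), 0, 1)
            names = [f"d{i}" for i in range(n)]
            a = self.result_from_f1(dict(zip(names, fa)))
            b = self.result_from_f1(dict(zip(names, fb)))
            cmp = sb.compare_feature_sets(a, b)
            t_ref, p_ref = stats.ttest_rel(fa, fb)
            assert cmp.t_statistic == pytest.approx(t_ref, abs=1e-10)
            assert cmp.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_mismatched_descriptor_sets_rejected(self):
        a = self.result_from_f1({"d0": 0.1, "d1": 0.2})
        b = self.result_from_f1({"d0": 0.1, "d2": 0.2})
        with pytest.raises(ValueError):
            sb.compare_feature_sets(a, b)


def test_mean_f1_monotone_in_signal_strength(vocab20):
    """Stronger planted feature-label coupling never hurts mean F1."""
    macro = {}
    for s in (0.0, 1.0, 3.0):
        truth = sb.default_cohort_truth(vocab20, signal_strength=s, seed=77)
        tables, labels = sb.generate_cohort(120, vocab20, truth, seed=77)
        scores, _, _ = sb.preprocess_table(tables["enose"], cutoff=0.95)
        res = sb.evaluate_repeated_cv(scores, labels, "ocsvm", sb.OCSVMSpec(nu=0.2),
                                      k=5, repeats=1, seed=77)
        macro[s] = res.macro_mean_f1()
    assert macro[1.0] >= macro[0.0] - 0.02
    assert macro[3.0] >= macro[1.0] - 0.02
    assert macro[3.0] > macro[0.0]
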