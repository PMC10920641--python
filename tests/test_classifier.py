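"""Nested CV machinery: folds, in-fold preprocessing, SVM, metrics, stability."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dyadsync.classifier import (
    C_GRID,
    CVScheme,
    InFoldPreprocSpec,
    InFoldPreprocessor,
    LinearModel,
    ModelRecord,
    class_weights,
    classification_metrics,
    compute_cvr,
    leakage_audit,
    make_stratified_folds,
    permutation_test,
    run_nested_cv,
    sign_consistency,
    train_weighted_linear_svm,
)

SMALL_GRID = (0.0625, 0.5, 4.0)


class TestStratifiedFolds:
    def test_balanced_labels_split_evenly(self):
        y = np.array([0] * 50 + [1] * 50)
        f = make_stratified_folds(y, 10, seed=3)
        for i in range(10):
            assert np.sum((f == i) & (y == 0)) == 5
            assert np.sum((f == i) & (y == 1)) == 5

    def test_56_38_split_proportions(self):
        y = np.array([1] * 56 + [0] * 38)
        f = make_stratified_folds(y, 10, seed=0)
        for i in range(10):
            size = np.sum(f == i)
            assert size in (9, 10)
            assert np.sum((f == i) & (y == 1)) in (5, 6)
            assert np.sum((f == i) & (y == 0)) in (3, 4)

    def test_deterministic_under_seed(self):
        y = np.array([0, 1] * 20)
        assert (make_stratified_folds(y, 5, 7) == make_stratified_folds(y, 5, 7)).all()

    def test_class_smaller_than_k_raises(self):
        with pytest.raises(ValueError):
            make_stratified_folds(np.array([0] * 20 + [1] * 3), 5, 0)


class TestInFoldPreprocessor:
    def test_training_columns_scaled_to_unit_interval(self, rng):
        X = rng.normal(10, 5, (40, 6))
        pre = InFoldPreprocessor(
            InFoldPreprocSpec(age_residualize=False)
        ).fit(X, rng.uniform(5, 25, 40))
        out = pre.transform(X, np.zeros(40))
        assert out.min() >= 0 and out.max() <= 1

    def test_test_rows_clipped_to_training_extrema(self, rng):
        X = rng.uniform(0, 1, (30, 3))
        pre = InFoldPreprocessor(
            InFoldPreprocSpec(age_residualize=False)
        ).fit(X, np.zeros(30))
        out = pre.transform(np.array([[5.0, -3.0, 0.5]]), np.zeros(1))
        assert out[0, 0] == 1.0 and out[0, 1] == 0.0

    def test_constant_column_pruned_everywhere(self, rng):
        X = rng.normal(size=(30, 4))
        X[:, 2] = 7.0
        pre = InFoldPreprocessor().fit(X, rng.uniform(5, 25, 30))
        assert pre.keep_.tolist() == [True, True, False, True]
        assert pre.transform(X, np.zeros(30)).shape[1] == 3

    def test_infinite_training_column_pruned(self, rng):
        X = rng.normal(size=(20, 3))
        X[4, 1] = np.inf
        pre = InFoldPreprocessor().fit(X, rng.uniform(5, 25, 20))
        assert pre.keep_.tolist() == [True, False, True]

    def test_age_residualization_removes_age_dependence(self, rng):
        n = 80
        age = rng.uniform(6, 25, n)
        X = np.column_stack([
            2.0 * age + rng.normal(0, 1, n),
            rng.normal(size=n),
        ])
        pre = InFoldPreprocessor(InFoldPreprocSpec()).fit(X, age)
        out = pre.transform(X, age)
        assert abs(stats.pearsonr(out[:, 0], age).statistic) < 0.05

    def test_age_independent_features_nearly_unchanged(self, rng):
        n = 60
        age = rng.uniform(6, 25, n)
        X = rng.normal(size=(n, 3))
        pre = InFoldPreprocessor(
            InFoldPreprocSpec(scale01=False, prune=False)
        ).fit(X, age)
        # fitted age slopes are statistically indistinguishable from zero
        assert np.allclose(pre.age_coef_[1], 0.0, atol=0.1)
        out = pre.transform(X, age)
        for j in range(3):
            assert stats.pearsonr(out[:, j], X[:, j]).statistic > 0.98

    def test_all_columns_pruned_raises(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError):
            InFoldPreprocessor().fit(X, np.zeros(10))


class TestLinearSVM:
    def test_separable_data_signs_correct(self):
        X = np.array([[-1.0], [-1.2], [-0.8], [1.0], [1.1], [0.9]])
        y = np.array([0, 0, 0, 1, 1, 1])
        m = train_weighted_linear_svm(X, y, C=1.0)
        assert ((m.decision(X) > 0).astype(int) == y).all()

    def test_duplicated_dataset_same_decision_function(self, rng):
        X = np.vstack([rng.normal(-1, 0.3, (15, 3)), rng.normal(1, 0.3, (15, 3))])
        y = np.array([0] * 15 + [1] * 15)
        m1 = train_weighted_linear_svm(X, y, C=1.0)
        m2 = train_weighted_linear_svm(
            np.vstack([X, X]), np.concatenate([y, y]), C=1.0
        )
        assert np.allclose(m1.weights, m2.weights, atol=1e-6)
        assert m1.bias == pytest.approx(m2.bias, abs=1e-6)

    def test_minority_upweighting_improves_minority_recall(self, rng):
        # imbalanced overlapping classes: 8 positives vs 60 negatives
        X = np.concatenate([rng.normal(0.8, 1, 8), rng.normal(-0.8, 1, 60)])[:, None]
        y = np.array([1] * 8 + [0] * 60)
        plain = train_weighted_linear_svm(X, y, C=1.0)
        weighted = train_weighted_linear_svm(X, y, C=1.0, weights={0: 1.0, 1: 10.0})
        def recall(m):
            return np.mean((m.decision(X[y == 1]) > 0))
        assert recall(weighted) >= recall(plain)

    def test_inverse_prevalence_weights(self):
        y = np.array([1] * 56 + [0] * 38)
        w = class_weights(y)
        assert w[1] == pytest.approx(94 / 112)
        assert w[0] == pytest.approx(94 / 76)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            train_weighted_linear_svm(np.ones((5, 2)), np.ones(5), C=1.0)


class TestClassificationMetrics:
    def test_perfect_classifier(self):
        m = classification_metrics(tn=10, tp=10, fn=0, fp=0)
        assert m.bac == 1.0 and m.nnd == 1.0 and m.accuracy == 1.0

    def test_all_one_class_predictor_is_chance(self):
        m = classification_metrics(tn=0, tp=20, fn=0, fp=15)
        assert m.bac == 0.5
        assert math.isinf(m.nnd)

    def test_bac_identity(self):
        m = classification_metrics(tn=19, tp=43, fn=13, fp=19)
        assert m.bac == (m.sensitivity + m.specificity) / 2

    def test_missing_true_class_raises(self):
        with pytest.raises(ValueError):
            classification_metrics(tn=5, tp=0, fn=0, fp=3)


class TestNestedCV:
    def test_strong_signal_recovers_high_bac(self, gaussian_table):
        table = gaussian_table(n1=30, n0=30, d=4.0, seed=1)
        res = run_nested_cv(
            table, CVScheme(5, 1, 5, seed=0), SMALL_GRID
        )
        assert res.metrics.bac >= 0.95

    def test_deterministic_under_seed(self, gaussian_table):
        table = gaussian_table(n1=20, n0=20, d=1.0, seed=2)
        a = run_nested_cv(table, CVScheme(4, 1, 4, seed=9), SMALL_GRID)
        b = run_nested_cv(table, CVScheme(4, 1, 4, seed=9), SMALL_GRID)
        pd.testing.assert_frame_equal(a.scores, b.scores)
        pd.testing.assert_frame_equal(a.selected_C, b.selected_C)

    def test_each_dyad_scored_perms_times_inner_folds(self, gaussian_table):
        table = gaussian_table(n1=20, n0=20, d=0.5, seed=3)
        res = run_nested_cv(table, CVScheme(4, 2, 5, seed=0), SMALL_GRID)
        assert (res.scores.n_scores == 2 * 5).all()

    def test_leakage_audit_passes(self, gaussian_table):
        table = gaussian_table(n1=15, n0=15, d=1.0, seed=4)
        res = run_nested_cv(table, CVScheme(3, 2, 3, seed=1), SMALL_GRID)
        assert leakage_audit(res)

    def test_pooled_bac_equals_metric_identity(self, gaussian_table):
        table = gaussian_table(n1=18, n0=14, d=1.0, seed=5)
        res = run_nested_cv(table, CVScheme(3, 1, 3, seed=2), SMALL_GRID)
        m = res.metrics
        assert m.bac == pytest.approx((m.sensitivity + m.specificity) / 2, abs=1e-15)

    def test_mean_pooling_option(self, gaussian_table):
        table = gaussian_table(n1=15, n0=15, d=2.0, seed=6)
        res = run_nested_cv(
            table, CVScheme(3, 1, 3, seed=0), SMALL_GRID, pooling="mean"
        )
        assert (res.scores.predicted == (res.scores.score_mean > 0)).all()

    def test_ndd_style_label_grouping(self, gaussian_table):
        table = gaussian_table(n1=20, n0=20, d=2.0, seed=7)
        table.loc[table.index[:10], "label"] = "ADHD"  # still class-1 signal
        res = run_nested_cv(
            table, CVScheme(3, 1, 3, seed=0), SMALL_GRID,
            positive_label=("ASD", "ADHD"),
        )
        counts = res.metrics
        assert counts.tn + counts.tp + counts.fn + counts.fp == len(table)


class TestPermutationTest:
    def test_strong_signal_beats_every_permutation(self, gaussian_table):
        table = gaussian_table(n1=12, n0=12, d=3.0, p=10, seed=8)
        out = permutation_test(
            table, CVScheme(3, 1, 3, seed=0), SMALL_GRID, B=9, seed=0
        )
        assert out["p"] == pytest.approx(1 / 10)
        assert out["observed_bac"] > max(out["permuted_bac"])

    def test_p_never_zero_and_bounded(self, gaussian_table):
        table = gaussian_table(n1=10, n0=10, d=0.0, p=5, seed=9)
        out = permutation_test(
            table, CVScheme(2, 1, 2, seed=0), (1.0,), B=5, seed=1
        )
        assert 0 < out["p"] <= 1


def _record(perm, fold, ifold, w):
    w = np.asarray(w, dtype=float)
    mask = ~np.isnan(w)
    return ModelRecord(
        perm, fold, ifold, 1.0,
        LinearModel(w[mask], 0.0, 1.0, ()), mask, frozenset(),
    )


class TestFeatureStability:
    def test_cvr_matches_spreadsheet_recomputation(self):
        # 2 outer folds x 3 inner weights for one feature
        store = [
            _record(0, 0, 0, [1.0]), _record(0, 0, 1, [2.0]), _record(0, 0, 2, [3.0]),
            _record(0, 1, 0, [2.0]), _record(0, 1, 1, [2.0]), _record(0, 1, 2, [5.0]),
        ]
        fold0 = np.median([1, 2, 3]) / (np.std([1, 2, 3], ddof=1) / math.sqrt(3))
        fold1 = np.median([2, 2, 5]) / (np.std([2, 2, 5], ddof=1) / math.sqrt(3))
        expected = (fold0 + fold1) / 2
        cvr = compute_cvr(store, ["f"])
        assert cvr.loc["f", "cvr"] == pytest.approx(expected)
        assert cvr.loc["f", "n_folds"] == 2
        assert cvr.loc["f", "n_models"] == 6

    def test_cvr_antisymmetric_under_sign_flip(self):
        store = [_record(0, 0, i, [w]) for i, w in enumerate([0.5, 1.0, 2.0])]
        flipped = [_record(0, 0, i, [-w]) for i, w in enumerate([0.5, 1.0, 2.0])]
        assert compute_cvr(store, ["f"]).loc["f", "cvr"] == pytest.approx(
            -compute_cvr(flipped, ["f"]).loc["f", "cvr"]
        )

    def test_cvr_zero_se_flagged_and_capped(self):
        store = [_record(0, 0, i, [1.5]) for i in range(3)]
        cvr = compute_cvr(store, ["f"], se_cap=100.0)
        assert cvr.loc["f", "zero_se_folds"] == 1
        assert cvr.loc["f", "cvr"] == 100.0

    def test_cvr_skips_folds_where_feature_pruned(self):
        store = [
            _record(0, 0, 0, [1.0, np.nan]), _record(0, 0, 1, [2.0, np.nan]),
            _record(0, 1, 0, [1.0, 0.3]), _record(0, 1, 1, [2.0, 0.5]),
        ]
        cvr = compute_cvr(store, ["f", "g"])
        assert cvr.loc["f", "n_folds"] == 2
        assert cvr.loc["g", "n_folds"] == 1
        assert cvr.loc["g", "n_models"] == 2

    def test_all_positive_signs_closed_form(self):
        store = [_record(0, 0, i, [0.1 + i]) for i in range(100)]
        cons = sign_consistency(store, ["f"])
        # two-sided binomial: p = 2 * 0.5^100
        assert cons.loc["f", "neg_log10_p"] == pytest.approx(29.8, abs=0.05)

    def test_half_positive_signs_is_null(self):
        store = [_record(0, 0, i, [1.0 if i % 2 else -1.0]) for i in range(40)]
        cons = sign_consistency(store, ["f"])
        assert cons.loc["f", "p"] == pytest.approx(1.0)
        assert cons.loc["f", "neg_log10_p"] == pytest.approx(0.0)

    def test_score_threshold_matches_alpha(self):
        # -log10(p) >= 1.3 is the p <= 0.05 line
        store = [_record(0, 0, i, [1.0]) for i in range(30)] + [
            _record(0, 1, i, [-1.0]) for i in range(10)
        ]
        cons = sign_consistency(store, ["f"])
        assert (cons.loc["f", "neg_log10_p"] >= 1.3) == (cons.loc["f", "p"] <= 0.05)

    def test_fdr_flags_follow_benjamini_hochberg(self):
        from statsmodels.stats.multitest import multipletests

        store = (
            [_record(0, 0, i, [1.0, 1.0 if i < 11 else -1.0]) for i in range(20)]
        )
        cons = sign_consistency(store, ["f", "g"])
        expected = multipletests(cons["p"].to_numpy(), 0.05, "fdr_bh")[0]
        assert cons["fdr_significant"].tolist() == expected.tolist()
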