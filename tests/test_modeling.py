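"""Learners, feature selection, CV protocol, metric panel, model comparison."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import lesionmap as lm
from lesionmap.modeling import (
    DegenerateFitError,
    NoSelectionError,
    PairingError,
    SingleClassError,
    feature_columns,
    stratified_partition,
)

from conftest import random_feature_table

FAST_SVM = lm.ModelSpec("svm_rbf", "p4", "fscore_rank").desk_scale()


class TestFScoreRank:
    def test_feature_identical_in_both_classes_ranks_last(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.repeat([0.0, 3.0], 10), np.ones(20)])
        X[:, 0] += rng.normal(0, 0.1, 20)
        y = np.repeat([0, 1], 10)
        order, scores = lm.fscore_rank(X, y)
        assert scores[1] == 0.0
        assert order[-1] == 1

    def test_hand_computed_six_sample_table(self):
        # class 0 rows: (1,5),(2,4),(3,6); class 1 rows: (7,1),(8,2),(9,3)
        # feature 0: means 2 / 8 / overall 5, vars 1+1 -> F = (9+9)/2 = 9
        # feature 1: means 5 / 2 / overall 3.5, vars 1+1 -> F = (2.25+2.25)/2 = 2.25
        X = np.array([[1, 5], [2, 4], [3, 6], [7, 1], [8, 2], [9, 3]], float)
        y = np.array([0, 0, 0, 1, 1, 1])
        order, scores = lm.fscore_rank(X, y)
        assert scores == pytest.approx([9.0, 2.25])
        assert list(order) == [0, 1]

    def test_separating_feature_beats_noise(self):
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 25)
            X = np.column_stack([y + rng.normal(0, 0.05, 50), rng.normal(0, 1, 50)])
            order, _ = lm.fscore_rank(X, y)
            wins += order[0] == 0
        assert wins >= 49  # >= 98% of replicates

    def test_zero_within_class_variance_flagged_and_ranked_first(self):
        X = np.column_stack([np.repeat([0.0, 1.0], 5), np.random.default_rng(1).normal(size=10)])
        y = np.repeat([0, 1], 5)
        with pytest.warns(UserWarning, match="zero"):
            order, _ = lm.fscore_rank(X, y)
        assert order[0] == 0

    def test_requires_two_samples_per_class(self):
        with pytest.raises(DegenerateFitError):
            lm.fscore_rank(np.ones((3, 2)), np.array([0, 1, 1]))


class TestFeatureCurve:
    def test_single_candidate_gives_length_one_curve(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 1))
        y = (X[:, 0] > 0).astype(int)
        curve = lm.select_feature_count(np.array([0]), X, y, FAST_SVM, seed=0)
        assert len(curve.val_f1) == 1
        assert curve.selected_count == 1

    def test_selected_count_is_argmax_of_validation_curve(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 8))
        y = (X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.5, 60) > 0).astype(int)
        order, _ = lm.fscore_rank(X, y)
        curve = lm.select_feature_count(order, X, y, FAST_SVM, seed=1)
        k = curve.selected_count
        assert curve.val_f1[k - 1] == curve.val_f1.max()
        assert curve.val_f1[k - 1] >= curve.val_f1[-1]
        # smallest k on ties
        assert not np.any(curve.val_f1[: k - 1] == curve.val_f1[k - 1])

    def test_planted_signal_recovery(self):
        # 5 informative features (2 SD class shift) among 50, n=200: the
        # chosen count stays near the true support and the planted features
        # rank in the top 10
        spec = lm.ModelSpec("svm_rbf", "p4", "fscore_rank")
        ok_count, ok_rank = 0, 0
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(300 + seed)
            y = rng.integers(0, 2, 200)
            X = rng.normal(size=(200, 50))
            X[:, :5] += 2.0 * y[:, None]
            order, _ = lm.fscore_rank(X, y)
            ok_rank += set(range(5)) <= set(order[:10])
            curve = lm.select_feature_count(
                order, X, y, spec, seed=seed, compute_train=False
            )
            ok_count += 3 <= curve.selected_count <= 10
        assert ok_count / reps >= 0.80
        assert ok_rank / reps >= 0.80


class TestFitPredict:
    def test_linearly_separable_toy_both_learners(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        for learner in ("logreg", "svm_rbf"):
            spec = lm.ModelSpec(learner, "p3").desk_scale()
            fit = lm.fit_predict(spec, X, y, X, seed=0)
            assert np.array_equal(fit.labels, y)

    def test_unregularized_logreg_symmetry_probability_half(self):
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array([0, 1, 0, 1])
        fit = lm.fit_predict(lm.ModelSpec("logreg", "p3"), X, y, np.array([[0.0]]))
        assert fit.scores[0] == pytest.approx(0.5, abs=1e-6)

    def test_single_class_training_raises(self):
        X = np.zeros((4, 2))
        with pytest.raises(DegenerateFitError):
            lm.fit_predict(lm.ModelSpec("logreg", "p3"), X, np.zeros(4, int), X)

    def test_strong_planted_regional_effects_reach_high_auc(self):
        # standardized beta 2.0 on 5 regions, n=300 -> held-out SVM-p4 AUC
        aucs = []
        for seed in range(10):
            table = random_feature_table(
                300, 45, seed=seed, effect_betas={r: 2.0 for r in range(1, 6)}
            )
            cols = feature_columns(table, "p4")
            X = table[cols].to_numpy(float)
            y = table["mrs_binary"].to_numpy(int)
            fit = lm.fit_predict(FAST_SVM, X[:200], y[:200], X[200:], seed=seed)
            aucs.append(lm.mann_whitney_auc(y[200:], fit.scores))
        assert np.mean(aucs) >= 0.85

    def test_held_out_predictions_independent_of_other_test_rows(self):
        # no-leakage: scoring a subset of the held-out fold gives the same
        # scores as scoring the full fold
        table = random_feature_table(80, 10, seed=4)
        cols = feature_columns(table, "p4")
        X = table[cols].to_numpy(float)
        y = table["mrs_binary"].to_numpy(int)
        spec = lm.ModelSpec("logreg", "p4", "lasso").desk_scale()
        full = lm.fit_predict(spec, X[:60], y[:60], X[60:], seed=1)
        part = lm.fit_predict(spec, X[:60], y[:60], X[60:65], seed=1)
        assert np.allclose(full.scores[:5], part.scores)

    def test_invalid_learner_selector_pairings_rejected(self):
        with pytest.raises(ValueError):
            lm.ModelSpec("svm_rbf", "p4", "lasso")
        with pytest.raises(ValueError):
            lm.ModelSpec("logreg", "p4", "fscore_rank")


class TestMetrics:
    def test_four_sample_worked_example(self):
        panel = lm.classification_metrics(
            np.array([1, 1, 0, 0]), np.array([0.9, 0.4, 0.6, 0.1]), threshold=0.5
        )
        assert panel.auc == pytest.approx(0.75)  # 3 of 4 positive-negative pairs
        assert panel.sensitivity == pytest.approx(0.5)
        assert panel.specificity == pytest.approx(0.5)
        assert panel.ppv == pytest.approx(0.5)
        assert panel.npv == pytest.approx(0.5)
        assert panel.accuracy == pytest.approx(0.5)

    def test_perfect_and_antiperfect_scores(self):
        y = np.array([0, 0, 1, 1])
        perfect = lm.classification_metrics(y, np.array([0.1, 0.2, 0.8, 0.9]), 0.5)
        assert all(v == 1.0 for v in perfect.as_dict().values())
        anti = lm.classification_metrics(y, np.array([0.9, 0.8, 0.2, 0.1]), 0.5)
        assert anti.auc == 0.0

    def test_auc_matches_sklearn_and_survives_monotone_transforms(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            y = rng.integers(0, 2, 40)
            if y.min() == y.max():
                continue
            s = rng.normal(size=40)
            auc = lm.mann_whitney_auc(y, s)
            assert auc == pytest.approx(roc_auc_score(y, s))
            for f in (lambda x: 3 * x + 1, np.exp, np.arctan):
                assert lm.mann_whitney_auc(y, f(s)) == pytest.approx(auc)

    def test_ties_counted_half(self):
        y = np.array([0, 1])
        s = np.array([0.5, 0.5])
        assert lm.mann_whitney_auc(y, s) == 0.5

    def test_zero_denominator_reported_as_nan(self):
        panel = lm.classification_metrics(
            np.array([0, 0, 1]), np.array([0.1, 0.2, 0.3]), threshold=0.9
        )
        assert np.isnan(panel.ppv)  # no positive predictions
        assert panel.specificity == 1.0

    def test_single_class_truth_raises(self):
        with pytest.raises(SingleClassError):
            lm.classification_metrics(np.ones(4), np.arange(4.0), 0.5)


class TestRepeatedCV:
    def test_partition_invariants(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(40, 120))
            y = rng.integers(0, 2, n)
            if np.bincount(y).min() < 10:
                continue
            assignment = stratified_partition(y, 10, int(rng.integers(2**31)))
            assert np.array_equal(np.sort(np.unique(assignment)), np.arange(10))
            global_rate = y.mean()
            for f in range(10):
                fold_y = y[assignment == f]
                expect = global_rate * len(fold_y)
                assert abs(fold_y.sum() - expect) <= 1.0

    def test_leave_one_out_degenerate(self):
        table = random_feature_table(12, 3, seed=5)
        cv = lm.repeated_cv(
            lm.ModelSpec("logreg", "p3"), table, folds=12, repeats=1, seed=0
        )
        assert cv.repeats == 1 and cv.n_fold_fits == 12

    def test_rerun_bit_identical(self):
        table = random_feature_table(60, 5, seed=6)
        spec = lm.ModelSpec("logreg", "p4", "lasso").desk_scale()
        a = lm.repeated_cv(spec, table, folds=5, repeats=3, seed=21)
        b = lm.repeated_cv(spec, table, folds=5, repeats=3, seed=21)
        assert a.per_repeat().equals(b.per_repeat())
        assert np.array_equal(a.selection_counts, b.selection_counts)

    def test_class_too_small_to_stratify_names_minimum(self):
        table = random_feature_table(20, 3, seed=7)
        table["mrs_binary"] = [1] * 4 + [0] * 16
        with pytest.raises(ValueError, match="4"):
            lm.repeated_cv(lm.ModelSpec("logreg", "p3"), table, folds=10, repeats=1)

    def test_sd_zero_with_single_repeat(self):
        table = random_feature_table(50, 3, seed=8)
        cv = lm.repeated_cv(lm.ModelSpec("logreg", "p3"), table, folds=5, repeats=1)
        assert (cv.summary()["sd"].fillna(0) == 0).all()


class TestCompareModels:
    def _cv_pair(self):
        table = random_feature_table(60, 4, seed=9)
        spec = lm.ModelSpec("logreg", "p3")
        a = lm.repeated_cv(spec, table, folds=5, repeats=8, seed=3)
        return table, spec, a

    def test_identical_results_give_p_one(self):
        _, _, a = self._cv_pair()
        p = lm.compare_models(a, a)
        assert p["p_auc"] == 1.0 and p["p_accuracy"] == 1.0

    def test_constant_auc_shift_strongly_significant(self):
        table = random_feature_table(150, 4, seed=10)
        spec = lm.ModelSpec("logreg", "p3")
        a = lm.repeated_cv(spec, table, folds=10, repeats=100, seed=3)
        shifted = [
            lm.MetricPanel(**{**p.as_dict(), "auc": p.auc + 0.05}) for p in a.panels
        ]
        b = lm.CVResult(
            spec=a.spec, panels=shifted, feature_names=a.feature_names,
            selection_counts=a.selection_counts, n_fold_fits=a.n_fold_fits,
            folds=a.folds, repeats=a.repeats, seed=a.seed, n_samples=a.n_samples,
        )
        assert lm.compare_models(b, a)["p_auc"] < 0.001

    def test_unpaired_results_rejected(self):
        table, spec, a = self._cv_pair()
        b = lm.repeated_cv(spec, table, folds=5, repeats=4, seed=3)
        with pytest.raises(PairingError):
            lm.compare_models(a, b)
        c = lm.repeated_cv(spec, table, folds=5, repeats=8, seed=4)
        with pytest.raises(PairingError):
            lm.compare_models(a, c)


class TestRegionImportance:
    def test_no_selection_model_rejected(self):
        table = random_feature_table(50, 3, seed=11)
        cv = lm.repeated_cv(lm.ModelSpec("logreg", "p3"), table, folds=5, repeats=1)
        with pytest.raises(NoSelectionError):
            lm.region_importance(cv)

    def test_frequencies_valid_and_sorted(self):
        table = random_feature_table(
            80, 8, seed=12, effect_betas={1: 2.0, 2: 2.0}
        )
        spec = lm.ModelSpec("logreg", "p4", "lasso").desk_scale()
        cv = lm.repeated_cv(spec, table, folds=5, repeats=2, seed=5)
        imp = lm.region_importance(cv)
        f = imp["selection_frequency"]
        assert ((f >= 0) & (f <= 1)).all()
        assert (f.diff().dropna() <= 1e-12).all()
        assert set(imp.loc[imp.is_covariate, "feature"]) == {"age", "nihss", "volume_ml"}
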