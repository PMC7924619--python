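"""Confusion metrics, curves, thresholds, CV orchestration, AUC t-test."""

import math

import numpy as np
import pytest
from scipy import stats

from pupfuse.encoders import FeatureMatrix, encode_dataset
from pupfuse.evaluation import (ConfusionCounts, compare_auc_ttest,
                                confusion_at_threshold, fused_cv, kfold_cv,
                                metrics, pr_points, roc_points,
                                threshold_at_specificity)
from pupfuse.models import ModelScores, ModelSpec


def as_scores(vals, labels):
    return ModelScores(np.asarray(vals, float), labels=np.asarray(labels, int))


class TestConfusion:
    def test_threshold_zero_all_positive(self):
        c = confusion_at_threshold(as_scores([0.1, 0.9, 0.4], [0, 1, 0]), 0.0)
        assert (c.FN, c.TN) == (0, 0) and c.TP + c.FP == 3

    def test_threshold_above_max_all_negative(self):
        c = confusion_at_threshold(as_scores([0.1, 0.9, 0.4], [0, 1, 0]), 0.95)
        assert (c.TP, c.FP) == (0, 0)

    def test_hand_enumeration(self):
        c = confusion_at_threshold(
            as_scores([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]), 0.75)
        assert (c.TP, c.FP, c.TN, c.FN) == (1, 1, 1, 1)

    def test_tie_at_threshold_predicted_positive(self):
        c = confusion_at_threshold(as_scores([0.5], [1]), 0.5)
        assert c.TP == 1


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(TP=50, FP=0, TN=50, FN=0))
        assert (m.sens, m.spec, m.acc, m.precision, m.mcc) == (1, 1, 1, 1, 1)

    def test_uninformative_counts(self):
        m = metrics(ConfusionCounts(TP=25, FP=25, TN=25, FN=25))
        assert m.mcc == 0 and m.acc == 0.5

    def test_direct_formula_oracle(self):
        m = metrics(ConfusionCounts(TP=50, FP=5, TN=45, FN=10))
        assert m.mcc == pytest.approx(2200 / math.sqrt(9075000))
        assert m.mcc == pytest.approx(0.7303, abs=1e-4)
        assert m.sens == pytest.approx(50 / 60)
        assert m.spec == pytest.approx(45 / 50)
        assert m.acc == pytest.approx(95 / 110)
        assert m.precision == pytest.approx(50 / 55)

    def test_recall_is_sensitivity(self):
        m = metrics(ConfusionCounts(TP=3, FP=2, TN=4, FN=1))
        assert m.recall == m.sens

    def test_zero_denominator_is_nan_not_zero(self):
        m = metrics(ConfusionCounts(TP=0, FP=0, TN=5, FN=5))
        assert math.isnan(m.precision)
        assert m.mcc == 0.0  # zero-factor convention

    def test_mcc_symmetric_under_class_swap(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(0, 40, size=4)
            a = metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn))).mcc
            b = metrics(ConfusionCounts(int(tn), int(fn), int(tp), int(fp))).mcc
            assert a == pytest.approx(b)

    def test_fuzzed_against_direct_arithmetic(self, rng):
        for _ in range(100):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 50, size=4))
            m = metrics(ConfusionCounts(tp, fp, tn, fn))
            if tp + fn:
                assert m.sens == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert m.spec == pytest.approx(tn / (tn + fp))
            if tp + fp + tn + fn:
                assert m.acc == pytest.approx((tp + tn) / (tp + fp + tn + fn))


class TestCurves:
    def test_perfect_ranking(self):
        s = as_scores([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc_points(s).auc == 1.0
        assert pr_points(s).auc == pytest.approx(1.0)

    def test_random_scores_auc_half(self, rng):
        n = 2000
        labels = np.array([1, 0] * (n // 2))
        s = as_scores(rng.uniform(size=n), labels)
        assert roc_points(s).auc == pytest.approx(0.5, abs=0.03)

    def test_auc_equals_mann_whitney(self, rng):
        """Trapezoid ROC AUC == U/(n+ * n-) on fuzzed score sets."""
        for _ in range(200):
            n_pos, n_neg = (int(x) for x in rng.integers(3, 30, size=2))
            labels = np.array([1] * n_pos + [0] * n_neg)
            scores = np.round(rng.uniform(size=n_pos + n_neg), 2)  # force ties
            auc = roc_points(as_scores(scores, labels)).auc
            u = stats.mannwhitneyu(scores[:n_pos], scores[n_pos:]).statistic
            assert auc == pytest.approx(u / (n_pos * n_neg))

    def test_auc_invariant_under_monotone_transform(self, rng):
        labels = (rng.uniform(size=300) < 0.4).astype(int)
        labels[:2] = [0, 1]
        scores = rng.uniform(size=300)
        base = roc_points(as_scores(scores, labels)).auc
        squashed = 1 / (1 + np.exp(-5 * (scores - 0.5)))
        assert roc_points(as_scores(squashed, labels)).auc == pytest.approx(base)

    def test_roc_anchored(self, rng):
        s = as_scores(rng.uniform(size=50), np.array([1, 0] * 25))
        pts = roc_points(s)
        assert pts.x[0] == 0 and pts.y[0] == 0
        assert pts.x[-1] == 1 and pts.y[-1] == 1
        assert np.all(np.diff(pts.x) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points(as_scores([0.5, 0.6], [1, 1]))


class TestThresholdAtSpecificity:
    def test_target_zero_minimal_threshold(self):
        s = as_scores([0.1, 0.5, 0.9], [0, 1, 1])
        t = threshold_at_specificity(s, 0.0)
        assert t == 0.1  # everything predicted positive

    def test_separable_target_one(self):
        s = as_scores([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        t = threshold_at_specificity(s, 1.0)
        c = confusion_at_threshold(s, t)
        assert metrics(c).spec == 1.0 and c.TP == 2

    def test_fuzzed_minimality_against_scan_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 60))
            labels = (rng.uniform(size=n) < 0.5).astype(int)
            labels[:2] = [0, 1]
            scores = np.round(rng.uniform(size=n), 2)
            s = as_scores(scores, labels)
            target = float(rng.choice([0.5, 0.8, 0.9, 1.0]))
            t = threshold_at_specificity(s, target)
            neg = scores[labels == 0]

            def spec_at(th):
                return np.mean(neg < th)

            assert spec_at(t) >= target
            lower = [c for c in np.unique(scores) if c < t]
            if lower:
                assert spec_at(lower[-1]) < target


class TestKFoldCV:
    SPEC = ModelSpec("RF", {"tree_count": 60}, seed=0)

    def test_stratification_and_determinism(self, small_planted_dataset):
        matrix = encode_dataset(small_planted_dataset, "Binary")
        rep1 = kfold_cv(matrix, self.SPEC, folds=5, seed=3)
        rep2 = kfold_cv(matrix, self.SPEC, folds=5, seed=3)
        assert np.array_equal(rep1.fold_assignment, rep2.fold_assignment)
        assert np.array_equal(rep1.oof_scores.scores, rep2.oof_scores.scores)
        y = matrix.labels
        for fold in range(5):
            m = rep1.fold_assignment == fold
            assert abs(m.sum() - len(y) / 5) <= 1
            assert abs((y[m] == 1).sum() - (y[m] == 0).sum()) <= 1

    def test_planted_signal_auc_high(self, small_planted_dataset):
        matrix = encode_dataset(small_planted_dataset, "Binary")
        rep = kfold_cv(matrix, self.SPEC, folds=5, seed=0)
        assert rep.pooled_auc > 0.8

    def test_pure_noise_auc_near_half(self, noise_dataset):
        matrix = encode_dataset(noise_dataset, "CKSAAP")
        rep = kfold_cv(matrix, self.SPEC, folds=5, seed=1)
        assert rep.pooled_auc == pytest.approx(0.5, abs=0.12)

    def test_class_too_small_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        matrix = FeatureMatrix("Binary", X, ["a", "b", "c"], y)
        with pytest.raises(ValueError):
            kfold_cv(matrix, self.SPEC, folds=5, seed=0)


class TestFusedCV:
    def test_fused_dominates_singles_on_planted_signal(self, small_planted_dataset):
        mats = {e: encode_dataset(small_planted_dataset, e, allow_pseudo=True)
                for e in ("Binary", "CKSAAP", "TPC")}
        rep = fused_cv(mats, ModelSpec("RF", {"tree_count": 60}, 0),
                       folds=5, seed=2)
        for enc, single in rep.per_encoding.items():
            assert rep.fused.pooled_auc >= single.pooled_auc - 1e-12
        assert sum(rep.weights.weights.values()) == pytest.approx(1.0)


class TestCompareAUCTTest:
    def test_identical_vectors(self):
        t, p = compare_auc_ttest([0.8, 0.8, 0.8], [0.8, 0.8, 0.8])
        assert t == 0.0 and p == 1.0

    def test_constant_shift_detected(self, rng):
        a = 0.7 + rng.normal(scale=0.005, size=10)
        t, p = compare_auc_ttest(a + 0.2, a)
        assert p < 0.01 and t > 0

    def test_matches_welch_closed_form(self):
        a = np.array([0.9, 0.85, 0.8, 0.95])
        b = np.array([0.7, 0.75, 0.65])
        t, p = compare_auc_ttest(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_oracle = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), df)
        assert t == pytest.approx(t_oracle)
        assert p == pytest.approx(p_oracle)

    def test_zero_variance_different_means_rejected(self):
        with pytest.raises(ValueError):
            compare_auc_ttest([0.8, 0.8], [0.9, 0.9])
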