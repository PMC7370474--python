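import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from pheoihd.metrics import (
    ConfusionMatrix,
    auc,
    auc_from_scores,
    confusion,
    f1_from_precision_recall,
    metric_ci,
    metric_set,
    roc_curve,
)


def pairwise_auc(scores, truth, positive_label=0):
    """O(n^2) Mann-Whitney oracle: P(pos outscores neg), ties counting 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(truth) == positive_label]
    neg = scores[np.asarray(truth) != positive_label]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_all_positive_identity(self):
        cm = confusion([0, 0, 0], [0, 0, 0], positive_label=0)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (3, 0, 0, 0)

    def test_reference_matrix_reconstruction(self):
        # 114 test patients with the published marginals: TP 85, FP 2, FN 15, TN 12
        truth = np.r_[np.zeros(85), np.zeros(15), np.ones(2), np.ones(12)].astype(int)
        pred = np.r_[np.zeros(85), np.ones(15), np.zeros(2), np.ones(12)].astype(int)
        cm = confusion(truth, pred, positive_label=0)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (85, 2, 15, 12)
        assert cm.total == 114

    def test_swapping_positive_label_transposes(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 30)
        pred = rng.integers(0, 2, 30)
        a = confusion(truth, pred, positive_label=0)
        b = confusion(truth, pred, positive_label=1)
        assert (a.tp, a.fp, a.fn, a.tn) == (b.tn, b.fn, b.fp, b.tp)

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0], positive_label=0)
        with pytest.raises(ValueError):
            confusion([0, 2], [0, 1], positive_label=0)

    def test_convention_documented(self):
        cm = confusion([0, 1], [0, 1], positive_label=0)
        assert "normal" in cm.positive_class_meaning


class TestMetricSet:
    def test_reference_accuracy(self):
        ms = metric_set(ConfusionMatrix(85, 2, 15, 12))
        assert round(ms.accuracy, 4) == 0.8509
        assert ms.as_dict()["accuracy"] == 0.8509

    def test_f1_from_published_precision_recall(self):
        assert round(f1_from_precision_recall(0.954, 0.8557), 4) == 0.9022

    def test_zero_denominator_flagged_not_silent(self):
        ms = metric_set(ConfusionMatrix(0, 3, 0, 5))
        assert math.isnan(ms.tpr)
        assert "tpr" in ms.undefined
        assert ms.accuracy == pytest.approx(5 / 8)

    def test_accuracy_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(0, 10, 4)
            if counts.sum() == 0:
                continue
            cm = ConfusionMatrix(*counts)
            assert metric_set(cm).accuracy == pytest.approx(
                (cm.tp + cm.tn) / cm.total)


class TestROC:
    def test_perfect_separation_passes_corner(self):
        curve = roc_curve([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1], positive_label=0)
        assert any(f == 0.0 and t == 1.0 for f, t in zip(curve.fpr, curve.tpr))
        assert auc(curve) == pytest.approx(1.0)

    def test_all_tied_scores_trace_diagonal(self):
        curve = roc_curve([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1], positive_label=0)
        assert curve.fpr.tolist() == [0.0, 1.0]
        assert curve.tpr.tolist() == [0.0, 1.0]
        assert auc(curve) == pytest.approx(0.5)

    def test_hand_set_against_threshold_enumeration(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6])
        truth = np.array([0, 0, 1, 0])  # positive = 0
        curve = roc_curve(scores, truth, positive_label=0)
        # brute force every threshold: predicted positive iff score >= t
        expected = {(0.0, 0.0)}
        for t in scores:
            pred_pos = scores >= t
            tpr = (pred_pos & (truth == 0)).sum() / 3
            fpr = (pred_pos & (truth == 1)).sum() / 1
            expected.add((float(fpr), float(tpr)))
        assert set(zip(curve.fpr, curve.tpr)) == expected

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [0, 0], positive_label=0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_trapezoid_equals_pairwise_oracle(self, data):
        n = data.draw(st.integers(2, 12))
        truth = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)
                          .filter(lambda t: 0 < sum(t) < len(t)))
        scores = data.draw(st.lists(
            st.floats(0, 1, allow_nan=False, width=16), min_size=n, max_size=n))
        assert auc_from_scores(scores, truth, 0) == pytest.approx(
            pairwise_auc(scores, truth, 0), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        truth = rng.integers(0, 2, 40)
        base = auc_from_scores(scores, truth, 0)
        for f in (np.exp, np.tanh, lambda s: 3 * s + 1):
            assert auc_from_scores(f(scores), truth, 0) == pytest.approx(base)

    def test_matches_sklearn_on_random_data(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            truth = rng.integers(0, 2, 50)
            if len(np.unique(truth)) < 2:
                continue
            scores = rng.random(50).round(1)  # force ties
            ours = auc_from_scores(scores, truth, positive_label=1)
            theirs = roc_auc_score(truth, scores)
            assert ours == pytest.approx(theirs, abs=1e-12)


class TestMetricCI:
    def test_constant_correct_predictions(self):
        truth = np.r_[np.zeros(30), np.ones(30)].astype(int)
        scores = 1.0 - truth  # score for positive class 0
        lo, hi = metric_ci(scores, truth, metric="accuracy", replicates=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_interval_nesting(self):
        rng = np.random.default_rng(4)
        truth = rng.integers(0, 2, 100)
        scores = rng.random(100) + 0.3 * (truth == 0)
        lo95, hi95 = metric_ci(scores, truth, level=0.95, replicates=500, seed=5)
        lo99, hi99 = metric_ci(scores, truth, level=0.99, replicates=500, seed=5)
        assert lo99 <= lo95 <= hi95 <= hi99

    def test_contains_point_estimate(self):
        rng = np.random.default_rng(6)
        truth = rng.integers(0, 2, 150)
        scores = rng.random(150) + 0.5 * (truth == 0)
        point = auc_from_scores(scores, truth, 0)
        lo, hi = metric_ci(scores, truth, replicates=1000, seed=7)
        assert lo <= point <= hi

    def test_degenerate_resamples_rejected(self):
        truth = np.array([0, 0, 0, 0, 1])
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.1])
        with pytest.raises(RuntimeError, match="single-class"):
            metric_ci(scores, truth, replicates=200, seed=8)

    def test_replicate_floor_enforced(self):
        with pytest.raises(ValueError):
            metric_ci([0.1, 0.9], [0, 1], replicates=50)

    def test_coverage_of_true_auc(self):
        # scores ~ N(1,1) for positives vs N(0,1): true AUC = Phi(1/sqrt(2))
        from scipy.stats import norm

        true_auc = norm.cdf(1 / math.sqrt(2))
        rng = np.random.default_rng(9)
        covered = 0
        n_sets = 200
        for i in range(n_sets):
            truth = (rng.random(200) < 0.5).astype(int)
            scores = rng.normal(0, 1, 200) + (truth == 0)
            lo, hi = metric_ci(scores, truth, metric="auc", level=0.95,
                               replicates=300, seed=i)
            covered += lo <= true_auc <= hi
        assert 0.90 <= covered / n_sets <= 0.99
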