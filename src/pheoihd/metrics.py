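"""Model assessment: confusion matrix, the study's metric formulas, ROC/AUC,
and a bootstrap interval estimate.

The study's sign convention is unusual and is preserved as the default:
patients *without* hemodynamic instability (y = 0, "normal patients") are the
positive class, so sensitivity (TPR) describes recognition of event-free
cases and specificity (TNR) recognition of the ill. The convention is carried
inside the ConfusionMatrix so it cannot silently invert.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "POSITIVE_CONVENTION",
    "ConfusionMatrix",
    "MetricSet",
    "confusion",
    "metric_set",
    "f1_from_precision_recall",
    "ROCCurve",
    "roc_curve",
    "auc",
    "auc_from_scores",
    "metric_ci",
]

POSITIVE_CONVENTION = "positive = y 0 (patients without IHD, 'normal patients')"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int
    positive_label: int = 0
    positive_class_meaning: str = POSITIVE_CONVENTION

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total < 1:
            raise ValueError("confusion matrix must tally at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(truth, predicted, positive_label: int = 0) -> ConfusionMatrix:
    """Tally binary (truth, predicted) pairs into a confusion matrix."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape or truth.size < 1:
        raise ValueError("truth and predicted must be equal-length, nonempty")
    labels = set(np.unique(truth)) | set(np.unique(predicted))
    if not labels <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(labels)}")
    pos_t = truth == positive_label
    pos_p = predicted == positive_label
    return ConfusionMatrix(
        tp=int((pos_t & pos_p).sum()), fp=int((~pos_t & pos_p).sum()),
        fn=int((pos_t & ~pos_p).sum()), tn=int((~pos_t & ~pos_p).sum()),
        positive_label=positive_label,
        positive_class_meaning=POSITIVE_CONVENTION if positive_label == 0
        else "positive = y 1 (patients with IHD)")


@dataclass(frozen=True)
class MetricSet:
    """accuracy, TPR (sensitivity/recall), TNR (specificity), PPV (precision),
    FPR and f1; a zero denominator leaves the metric NaN and lists its name in
    ``undefined`` instead of silently reporting 0."""

    accuracy: float
    tpr: float
    tnr: float
    ppv: float
    fpr: float
    f1: float
    undefined: frozenset = field(default_factory=frozenset)

    def as_dict(self, ndigits: int | None = 4) -> dict[str, float]:
        vals = {"accuracy": self.accuracy, "tpr": self.tpr, "tnr": self.tnr,
                "ppv": self.ppv, "fpr": self.fpr, "f1": self.f1}
        if ndigits is not None:
            vals = {k: (round(v, ndigits) if not math.isnan(v) else v)
                    for k, v in vals.items()}
        return vals


def _ratio(num: float, den: float, name: str, undefined: set) -> float:
    if den == 0:
        undefined.add(name)
        return math.nan
    return num / den


def metric_set(cm: ConfusionMatrix) -> MetricSet:
    """The study's formula set, computed exactly as printed:
    accuracy = correct/total, TPR = TP/(TP+FN), TNR = TN/(FP+TN),
    PPV = TP/(TP+FP), FPR = FP/(FP+TN), f1 = 2*recall*precision/(recall+precision).
    """
    undefined: set = set()
    accuracy = (cm.tp + cm.tn) / cm.total
    tpr = _ratio(cm.tp, cm.tp + cm.fn, "tpr", undefined)
    tnr = _ratio(cm.tn, cm.fp + cm.tn, "tnr", undefined)
    ppv = _ratio(cm.tp, cm.tp + cm.fp, "ppv", undefined)
    fpr = _ratio(cm.fp, cm.fp + cm.tn, "fpr", undefined)
    if math.isnan(tpr) or math.isnan(ppv) or (tpr + ppv) == 0:
        undefined.add("f1")
        f1 = math.nan
    else:
        f1 = f1_from_precision_recall(ppv, tpr)
    return MetricSet(accuracy, tpr, tnr, ppv, fpr, f1, frozenset(undefined))


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean 2*recall*precision/(recall+precision)."""
    if precision < 0 or recall < 0 or (precision + recall) == 0:
        raise ValueError("precision and recall must be nonnegative, not both zero")
    return 2.0 * recall * precision / (recall + precision)


# ---------------------------------------------------------------------------
# ROC

@dataclass(frozen=True)
class ROCCurve:
    """Threshold sweep from (0,0) to (1,1); tied scores collapse into a single
    step, so ties trace diagonal segments."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self):
        if (np.diff(self.fpr) < -1e-12).any() or (np.diff(self.tpr) < -1e-12).any():
            raise ValueError("ROC coordinates must be nondecreasing")
        for arr, name in ((self.fpr, "FPR"), (self.tpr, "TPR")):
            if not (arr[0] == 0.0 and arr[-1] == 1.0):
                raise ValueError(f"{name} must start at 0 and end at 1")


def roc_curve(scores, truth, positive_label: int = 0) -> ROCCurve:
    """ROC from scores interpreted as confidence for the positive class.

    A threshold is placed at every distinct score; predicted positive means
    score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    pos = truth == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s, p = scores[order], pos[order]
    distinct = np.flatnonzero(np.r_[np.diff(s) != 0, True])  # last index of each tie group
    tp_cum = np.cumsum(p)[distinct]
    fp_cum = np.cumsum(~p)[distinct]
    fpr = np.r_[0.0, fp_cum / n_neg]
    tpr = np.r_[0.0, tp_cum / n_pos]
    thresholds = np.r_[np.inf, s[distinct]]
    return ROCCurve(fpr, tpr, thresholds)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC; equals the Mann-Whitney probability
    that a random positive outscores a random negative (ties counting 1/2)."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def auc_from_scores(scores, truth, positive_label: int = 0) -> float:
    return auc(roc_curve(scores, truth, positive_label))


# ---------------------------------------------------------------------------
# bootstrap interval

_METRIC_NAMES = ("auc", "accuracy", "tpr", "tnr", "ppv", "fpr", "f1")


def _point_metric(scores: np.ndarray, truth: np.ndarray, metric: str,
                  positive_label: int, threshold: float) -> float:
    if metric == "auc":
        return auc_from_scores(scores, truth, positive_label)
    predicted = np.where(scores >= threshold, positive_label, 1 - positive_label)
    ms = metric_set(confusion(truth, predicted, positive_label))
    return getattr(ms, metric) if metric != "accuracy" else ms.accuracy


def metric_ci(scores, truth, metric: str = "auc", level: float = 0.95,
              replicates: int = 2000, seed: int = 0, positive_label: int = 0,
              threshold: float = 0.5) -> tuple[float, float]:
    """Percentile bootstrap interval over test-set rows.

    Resamples with a single-class draw are skipped (and an error raised if
    more than 20% of replicates degenerate). Threshold-based metrics classify
    positive when score >= ``threshold``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if replicates < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    if metric not in _METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRIC_NAMES}")
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    n = len(truth)
    rng = np.random.default_rng(seed)
    values, skipped = [], 0
    for _ in range(replicates):
        idx = rng.integers(0, n, size=n)
        t = truth[idx]
        if len(np.unique(t)) < 2:
            skipped += 1
            continue
        v = _point_metric(scores[idx], t, metric, positive_label, threshold)
        if not math.isnan(v):
            values.append(v)
    if skipped > 0.2 * replicates:
        raise RuntimeError(
            f"{skipped}/{replicates} bootstrap resamples were single-class; "
            "the test set is too small or too imbalanced for a row bootstrap")
    alpha = 1.0 - level
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
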