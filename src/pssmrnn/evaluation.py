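"""Classification metrics: sensitivity, specificity, accuracy, MCC,
ROC/AUC.

All threshold metrics derive from confusion counts with the tie rule
"probability >= threshold predicts positive".  Degenerate denominators
follow the usual conventions: sensitivity/specificity are 0 when their
class is absent, and MCC is 0 whenever any factor of its denominator is
zero.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionCounts", "MetricSet", "EvalReport",
    "confusion_counts", "metrics", "roc_auc", "evaluate",
]


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclasses.dataclass
class MetricSet:
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float


@dataclasses.dataclass
class EvalReport:
    """Full evaluation of one model on one split."""

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: float
    roc: np.ndarray          # (n_points, 2) of (FPR, TPR), (0,0) -> (1,1)
    threshold: float
    support_positive: int
    support_negative: int

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roc"] = self.roc.tolist()
        return d


def confusion_counts(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Confusion counts at a decision threshold (ties predict positive)."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels differ in length")
    if p.size == 0:
        raise ValueError("cannot evaluate an empty prediction vector")
    pred = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, and
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total == 0:
        raise ValueError("confusion counts are all zero")
    sens = tp / (tp + fn) if tp + fn > 0 else 0.0
    spec = tn / (tn + fp) if tn + fp > 0 else 0.0
    acc = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return MetricSet(sens, spec, acc, mcc)


def roc_auc(probabilities: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC curve over all distinct score thresholds and its trapezoidal
    area.

    The trapezoidal AUC equals the Mann-Whitney U statistic normalised
    by n_pos * n_neg, with tied scores counting one half.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes to be present")
    fpr, tpr, _ = roc_curve(y, p, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def evaluate(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> EvalReport:
    """Confusion metrics at the threshold plus ROC/AUC, as one report."""
    counts = confusion_counts(probabilities, labels, threshold)
    ms = metrics(counts)
    roc, auc = roc_auc(probabilities, labels)
    y = np.asarray(labels)
    return EvalReport(
        sensitivity=ms.sensitivity,
        specificity=ms.specificity,
        accuracy=ms.accuracy,
        mcc=ms.mcc,
        auc=auc,
        roc=roc,
        threshold=threshold,
        support_positive=int((y == 1).sum()),
        support_negative=int((y == 0).sum()),
    )
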