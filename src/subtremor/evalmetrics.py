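"""Confusion-matrix metrics and ROC/AUC evaluation.

Scalar metrics are all recomputable from the confusion matrix: accuracy,
sensitivity (recall of the positive class), precision, specificity, F1,
false positive rate, and negative predictive value.  Ratios with a zero
denominator are reported as NaN with an explicit flag, never silently 0.
The three-class problem is evaluated one-vs-all: each class in turn is the
positive class, the confusion collapsed to 2x2.  ROC curves sweep the
softmax probability of the positive class; AUC is trapezoidal and equals
the Mann-Whitney probability that a random positive outscores a random
negative (ties counted half).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "ROCCurve",
    "confusion",
    "binary_metrics",
    "one_vs_all_metrics",
    "roc_auc",
]


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    def collapse(self, positive) -> "ConfusionMatrix":
        """One-vs-all 2x2 collapse with `positive` as the first class."""
        i = self.classes.index(positive)
        tp = self.counts[i, i]
        fn = self.counts[i].sum() - tp
        fp = self.counts[:, i].sum() - tp
        tn = self.total - tp - fn - fp
        return ConfusionMatrix(np.array([[tp, fn], [fp, tn]]),
                               [positive, f"not-{positive}"])


@dataclass
class MetricSet:
    accuracy: float
    sensitivity: float
    precision: float
    specificity: float
    f1: float
    fpr: float
    npv: float
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "precision": self.precision, "specificity": self.specificity,
            "f1": self.f1, "fpr": self.fpr, "npv": self.npv,
            "undefined": list(self.undefined),
        }


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def confusion(y_true, y_pred, classes=None) -> ConfusionMatrix:
    """Build the count matrix; trace equals the number correct."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if classes is None:
        classes = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    classes = list(classes)
    unknown = (set(y_true.tolist()) | set(y_pred.tolist())) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class list: {sorted(unknown)}")
    counts = _sk_confusion(y_true, y_pred, labels=classes)
    return ConfusionMatrix(counts, classes)


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def binary_metrics(cm: ConfusionMatrix, positive=None) -> MetricSet:
    """Full scalar metric suite from a 2x2 (or collapsible) confusion.

    accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN),
    precision = TP/(TP+FP), specificity = TN/(TN+FP),
    F1 = 2 P R/(P+R), FPR = FP/(FP+TN), NPV = TN/(TN+FN).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if cm.counts.shape != (2, 2):
        if positive is None:
            raise ValueError("positive class required to collapse a multi-class matrix")
        cm = cm.collapse(positive)
    elif positive is not None and cm.classes[0] != positive:
        # swap so the requested class is positive
        c = cm.counts
        cm = ConfusionMatrix(np.array([[c[1, 1], c[1, 0]], [c[0, 1], c[0, 0]]]),
                             [cm.classes[1], cm.classes[0]])
    (tp, fn), (fp, tn) = cm.counts
    undefined: list[str] = []
    sens = _ratio(tp, tp + fn, "sensitivity", undefined)
    prec = _ratio(tp, tp + fp, "precision", undefined)
    spec = _ratio(tn, tn + fp, "specificity", undefined)
    fpr = _ratio(fp, fp + tn, "fpr", undefined)
    npv = _ratio(tn, tn + fn, "npv", undefined)
    if np.isnan(prec) or np.isnan(sens) or (prec + sens) == 0:
        undefined.append("f1")
        f1 = float("nan")
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricSet(
        accuracy=(tp + tn) / cm.total, sensitivity=sens, precision=prec,
        specificity=spec, f1=f1, fpr=fpr, npv=npv, undefined=undefined,
    )


def one_vs_all_metrics(cm: ConfusionMatrix) -> dict:
    """Per-class metric sets from a multi-class confusion (class vs rest)."""
    if cm.counts.shape[0] < 3:
        raise ValueError("one-vs-all collapse expects a multi-class matrix")
    return {cls: binary_metrics(cm.collapse(cls)) for cls in cm.classes}


def roc_auc(scores, labels, positive=1) -> ROCCurve:
    """ROC curve and AUC from positive-class scores.

    Threshold sweep over the unique scores (ties stepped simultaneously);
    AUC by trapezoidal integration.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    if pos.all() or (~pos).all():
        raise ValueError("ROC needs at least one positive and one negative label")
    fpr, tpr, thr = _sk_roc_curve(pos.astype(int), scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)
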