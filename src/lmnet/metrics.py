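"""Confusion-matrix construction and classification metrics.

Multi-class accuracy is trace/total; per-class precision, recall and F1
come from the one-vs-rest TP/TN/FP/FN view of the confusion matrix, and
the summary report carries both macro (unweighted class mean) and
support-weighted averages.  Classes with a zero denominator score 0 and
raise a warning rather than an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "ClassCounts", "MetricsReport",
           "confusion_matrix", "scores"]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray                       # (K, K), rows true, cols predicted
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        if not self.class_names:
            self.class_names = [str(i) for i in range(self.counts.shape[0])]

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def class_counts(self, k: int) -> "ClassCounts":
        """One-vs-rest TP/TN/FP/FN for class ``k``."""
        tp = int(self.counts[k, k])
        fn = int(self.counts[k].sum() - tp)
        fp = int(self.counts[:, k].sum() - tp)
        tn = self.total - tp - fn - fp
        return ClassCounts(tp, tn, fp, fn)


@dataclass(frozen=True)
class ClassCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    accuracy: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_f1: float
    confusion: ConfusionMatrix

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "per_class": {
                name: {"precision": float(p), "recall": float(r), "f1": float(f)}
                for name, p, r, f in zip(self.confusion.class_names,
                                         self.per_class_precision,
                                         self.per_class_recall,
                                         self.per_class_f1)
            },
            "confusion_matrix": self.confusion.counts.tolist(),
        }


def confusion_matrix(y_true, y_pred, num_classes: int,
                     class_names: list[str] | None = None) -> ConfusionMatrix:
    """counts[i, j] = number of samples with true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(f"{name} contains labels outside [0, {num_classes})")
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts, class_names or [])


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    bad = den == 0
    if bad.any():
        warnings.warn(f"{what} undefined for classes {np.flatnonzero(bad).tolist()}; "
                      "reported as 0", stacklevel=3)
    np.divide(num, den, out=out, where=~bad)
    return out


def scores(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class precision/recall/F1 and macro/weighted averages."""
    c = cm.counts.astype(np.float64)
    total = c.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(c)
    precision = _safe_div(diag, c.sum(axis=0), "precision")
    recall = _safe_div(diag, c.sum(axis=1), "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "F1")
    support = c.sum(axis=1)
    return MetricsReport(
        accuracy=float(diag.sum() / total),
        per_class_precision=precision,
        per_class_recall=recall,
        per_class_f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        weighted_f1=float((f1 * support).sum() / total),
        confusion=cm,
    )
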