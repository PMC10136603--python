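"""Confusion matrices and multiclass accuracy/precision/recall/F1.

Metrics follow the one-vs-rest reduction per class with MACRO (unweighted)
averaging: per-class precision TP/(TP+FP) is the column-normalized
diagonal, recall TP/(TP+FN) the row-normalized diagonal, F1 their harmonic
mean, and accuracy the trace over the total.  Confusion matrices are laid
out rows = actual, columns = predicted.  Subject-level summaries are the
arithmetic mean and population standard deviation (divisor n) of the
per-subject accuracies, with optional subject exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics",
           "subject_average"]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K), rows = actual, cols = predicted
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = self.counts.shape[0]
        if self.counts.ndim != 2 or self.counts.shape[1] != k:
            raise ValueError(f"confusion matrix must be square, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be nonnegative")
        if not self.class_names:
            self.class_names = tuple(str(i) for i in range(k))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.counts, index=list(self.class_names), columns=list(self.class_names)
        ).to_csv(path)


@dataclass
class MetricsReport:
    accuracy: float
    precision: np.ndarray  # per class
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n: int

    def rounded(self, decimals: int = 2) -> dict:
        """Two-decimal presentation of the macro metrics, as reported."""
        return {
            "accuracy": round(self.accuracy, decimals),
            "precision": round(self.macro_precision, decimals),
            "recall": round(self.macro_recall, decimals),
            "f1": round(self.macro_f1, decimals),
        }

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {
                "precision": self.precision.tolist(),
                "recall": self.recall.tolist(),
                "f1": self.f1.tolist(),
            },
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "n": self.n,
        }


def confusion(true_labels, predicted_labels, n_classes: int,
              class_names: tuple[str, ...] = ()) -> ConfusionMatrix:
    """Count matrix: counts[a][p] = #{i : true = a, pred = p}."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("true and predicted label arrays differ in length")
    for name, arr in (("true", t), ("predicted", p)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} labels fall outside [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts, class_names)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest macro metrics from a confusion matrix.

    A class never predicted (or never actually present) contributes
    precision (recall) 0 with a logged warning rather than NaN.
    """
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, tp / col, 0.0)
        recall = np.where(row > 0, tp / row, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    if (col == 0).any() or (row == 0).any():
        logger.warning(
            "classes with zero predicted or actual count: metrics set to 0"
        )
    return MetricsReport(
        accuracy=float(tp.sum() / total),
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        n=int(total),
    )


def subject_average(accuracies, exclude=()) -> tuple[float, float]:
    """Mean and population SD of per-subject accuracies.

    ``accuracies`` is a sequence or a {subject_id: accuracy} mapping;
    ``exclude`` lists subject ids (mapping) or 0-based indices (sequence)
    to drop before averaging.
    """
    if isinstance(accuracies, dict):
        vals = [v for k, v in accuracies.items() if k not in set(exclude)]
    else:
        vals = [v for i, v in enumerate(accuracies) if i not in set(exclude)]
    if not vals:
        raise ValueError("no subjects left after exclusion")
    arr = np.asarray(vals, dtype=np.float64)
    return float(arr.mean()), float(arr.std())
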