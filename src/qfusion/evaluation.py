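"""Confusion matrices and multi-class classification metrics.

Metrics are computed one-vs-rest from the confusion matrix (rows = true
class, columns = predicted class): per-class precision TP/(TP+FP), recall
TP/(TP+FN), F1 as their harmonic mean; accuracy = trace/total; macro
aggregates are unweighted means, weighted aggregates are support-weighted.
Support-weighted recall is identically equal to accuracy (each class
contributes support * TP/support = TP), a useful internal consistency check.

A class with zero predicted (or true) samples gets precision (recall) 0 with
a warning.  Percentages are reported at two decimals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    label_map: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValidationError("confusion matrix counts must be non-negative")
        if not self.label_map:
            self.label_map = [f"class_{k}" for k in range(self.counts.shape[0])]

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps(
            {"counts": self.counts.tolist(), "label_map": self.label_map}, indent=1))


@dataclass
class MetricsReport:
    """Per-class and aggregate metrics, all in percent at two decimals."""

    per_class: pd.DataFrame  # columns: class, precision, recall, f1, support
    accuracy: float
    error_rate: float
    macro_f1: float
    weighted_f1: float
    weighted_precision: float
    weighted_recall: float

    def to_csv(self, path: Path) -> None:
        self.per_class.to_csv(path, index=False)

    def aggregates(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("accuracy", "error_rate", "macro_f1", "weighted_f1",
                 "weighted_precision", "weighted_recall")}


def confusion_matrix(true_labels, predicted_labels, n_classes: int,
                     label_map: list[str] | None = None) -> ConfusionMatrix:
    """Count matrix with ``counts[i, j] = #{n : true=i, pred=j}``."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape or t.ndim != 1:
        raise ValidationError("label vectors must be 1-D and of equal length")
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValidationError(f"labels must lie in [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts, label_map or [])


def _round2(x: float) -> float:
    return float(np.round(x, 2))


def raw_metrics(cm: ConfusionMatrix) -> dict[str, np.ndarray | float]:
    """Unrounded metrics on the 0-1 scale (per-class arrays + aggregates)."""
    C = cm.counts.astype(np.float64)
    total = C.sum()
    if total == 0:
        raise ValidationError("confusion matrix holds no samples")
    tp = np.diag(C)
    support = C.sum(axis=1)  # true counts per class
    predicted = C.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, tp / np.where(predicted > 0, predicted, 1), 0.0)
        recall = np.where(support > 0, tp / np.where(support > 0, support, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    if (predicted == 0).any() or (support == 0).any():
        warnings.warn("class with no predicted or true samples: metric set to 0",
                      RuntimeWarning, stacklevel=3)

    accuracy = tp.sum() / total
    w = support / total
    return {"precision": precision, "recall": recall, "f1": f1,
            "support": support, "accuracy": float(accuracy),
            "macro_f1": float(f1.mean()),
            "weighted_f1": float((w * f1).sum()),
            "weighted_precision": float((w * precision).sum()),
            "weighted_recall": float((w * recall).sum())}


def metrics_from_cm(cm: ConfusionMatrix) -> MetricsReport:
    """Derive the full metrics report (percent, two decimals) from a matrix."""
    raw = raw_metrics(cm)
    precision, recall, f1 = raw["precision"], raw["recall"], raw["f1"]
    support, accuracy = raw["support"], raw["accuracy"]
    per_class = pd.DataFrame({
        "class": cm.label_map,
        "precision": np.round(100 * precision, 2),
        "recall": np.round(100 * recall, 2),
        "f1": np.round(100 * f1, 2),
        "support": support.astype(int),
    })
    return MetricsReport(
        per_class=per_class,
        accuracy=_round2(100 * accuracy),
        error_rate=_round2(100 * (1 - accuracy)),
        macro_f1=_round2(100 * raw["macro_f1"]),
        weighted_f1=_round2(100 * raw["weighted_f1"]),
        weighted_precision=_round2(100 * raw["weighted_precision"]),
        weighted_recall=_round2(100 * raw["weighted_recall"]),
    )


def macro_f1_score(true_labels, predicted_labels, n_classes: int) -> float:
    """Unweighted mean per-class F1 on the 0-1 scale (used for early stopping)."""
    cm = confusion_matrix(true_labels, predicted_labels, n_classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return raw_metrics(cm)["macro_f1"]


def accuracy_from_counts(correct: int, total: int) -> float:
    """``100 * correct / total`` at two decimals."""
    if total <= 0:
        raise ValidationError("total must be positive")
    if not 0 <= correct <= total:
        raise ValidationError("correct must lie in [0, total]")
    return _round2(100.0 * correct / total)
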