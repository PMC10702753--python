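"""Confusion-matrix evaluation and compression-ratio accounting.

Per-class precision, recall and F1 use the one-vs-rest TP/FP/FN reading of
a C x C confusion matrix (rows = true class, columns = predicted class);
overall accuracy is the multiclass reduction trace/total.  Compression
ratio is uncompressed size over compressed size, i.e. B**2 / M per block.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "confusion_matrix",
    "per_class_metrics",
    "overall_accuracy",
    "macro_average",
    "f1_score",
    "compression_ratio",
    "measurements_for_cr",
    "round_half_up",
    "export_class_report",
    "export_sweep_report",
]


@dataclass
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{c} classes"
            )
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float


def confusion_matrix(y_true, y_pred, classes) -> ConfusionMatrix:
    """Count true-vs-predicted label pairs over an ordered class set."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"label lists differ in length: {len(y_true)} vs {len(y_pred)}"
        )
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label pair ({t!r}, {p!r}) outside class set")
        counts[index[t], index[p]] += 1
    if not y_true:
        warnings.warn("empty label lists: all-zero confusion matrix",
                      stacklevel=2)
    return ConfusionMatrix(counts, classes)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; returning 0", stacklevel=3)
        return 0.0
    return num / den


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 if either is 0)."""
    if precision == 0 or recall == 0:
        return 0.0
    # reciprocal form avoids underflow of the product for tiny inputs
    return 2.0 / (1.0 / precision + 1.0 / recall)


def per_class_metrics(cm: ConfusionMatrix, cls: str) -> ClassMetrics:
    """One-vs-rest precision, recall and F1 for one class."""
    if cls not in cm.classes:
        raise ValueError(f"{cls!r} not in {cm.classes}")
    i = cm.classes.index(cls)
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[:, i].sum()) - tp
    fn = int(cm.counts[i, :].sum()) - tp
    p = _safe_div(tp, tp + fp, f"precision[{cls}]")
    r = _safe_div(tp, tp + fn, f"recall[{cls}]")
    return ClassMetrics(p, r, f1_score(p, r))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified items: trace / total."""
    if cm.total == 0:
        raise ValueError("cannot compute accuracy of an empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def macro_average(per_class: list[ClassMetrics]) -> tuple[float, float, float]:
    """Unweighted arithmetic mean of per-class precision, recall, F1."""
    if not per_class:
        raise ValueError("no per-class metrics to average")
    p = float(np.mean([m.precision for m in per_class]))
    r = float(np.mean([m.recall for m in per_class]))
    f = float(np.mean([m.f1 for m in per_class]))
    return p, r, f


def compression_ratio(config) -> float:
    """CR = uncompressed size / compressed size = B**2 / M per block."""
    b, m = config.block_size, config.measurements
    if m < 1:
        raise ValueError(f"measurements must be >= 1, got {m}")
    if m > b * b:
        raise ValueError(f"measurements {m} exceed block capacity {b * b}")
    return (b * b) / m


def measurements_for_cr(block_size: int, cr: float) -> int:
    """Invert CR = B**2 / M; CR must divide B**2 evenly."""
    ell = block_size * block_size
    m = ell / cr
    if abs(m - round(m)) > 1e-9 or not 1 <= round(m) <= ell:
        raise ValueError(
            f"compression ratio {cr} does not map to an integer measurement "
            f"count for block size {block_size}"
        )
    return int(round(m))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding as used in report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def export_class_report(cm: ConfusionMatrix, path) -> None:
    """Per-class precision/recall/F1 table as CSV (2-decimal, half-up)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class", "precision", "recall", "f1_score"])
        for cls in cm.classes:
            m = per_class_metrics(cm, cls)
            writer.writerow(
                [cls] + [round_half_up(v) for v in (m.precision, m.recall, m.f1)]
            )


def export_sweep_report(rows: list[dict], path) -> None:
    """Per-CR performance table as CSV.

    ``rows`` carry keys: method, cr, precision, recall, f1, accuracy, loss
    (metric values as percentages).
    """
    cols = ["method", "cr", "precision", "recall", "f1_score",
            "test_accuracy", "test_loss"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for row in rows:
            writer.writerow([
                row["method"],
                row["cr"],
                round_half_up(row["precision"]),
                round_half_up(row["recall"]),
                round_half_up(row["f1"]),
                round_half_up(row["accuracy"]),
                round_half_up(row["loss"]),
            ])
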