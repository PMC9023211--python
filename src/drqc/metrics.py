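"""Confusion matrix and per-class classification metrics.

The report follows the per-class layout common in the medical-imaging
literature: for each class, a one-vs-rest accuracy (in percent) alongside
precision, recall and F1 as unit fractions, plus the overall accuracy.
One-vs-rest accuracy counts both true positives and true negatives for the
class against all others, which is why a distinct accuracy per class exists
at all.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["confusion", "ClassMetrics", "MetricsReport", "report", "format_report"]

log = logging.getLogger(__name__)


def confusion(y_true: Sequence[int], y_pred: Sequence[int], n_classes: int) -> np.ndarray:
    """K x K count matrix; rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=np.int64).reshape(-1)
    y_pred = np.asarray(y_pred, dtype=np.int64).reshape(-1)
    if y_true.size == 0:
        raise ValueError("empty label sequences")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred differ in length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.min() < 0 or y.max() >= n_classes:
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        log.warning("%s undefined (0/0); reporting 0", what)
        return 0.0
    return num / den


@dataclass(frozen=True)
class ClassMetrics:
    accuracy_pct: float  # one-vs-rest, percent
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class MetricsReport:
    per_class: tuple[ClassMetrics, ...]
    overall_accuracy_pct: float
    confusion_matrix: np.ndarray

    def to_dict(self) -> dict:
        return {
            "overall_accuracy_pct": self.overall_accuracy_pct,
            "per_class": [
                {
                    "accuracy_pct": m.accuracy_pct,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                }
                for m in self.per_class
            ],
            "confusion_matrix": self.confusion_matrix.tolist(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def report(cm: np.ndarray) -> MetricsReport:
    """Per-class accuracy/precision/recall/F1 and overall accuracy from counts.

    For class c: TP = cm[c][c], FP = column sum - TP, FN = row sum - TP,
    TN = everything else; accuracy_c = (TP + TN) / total (one-vs-rest),
    precision = TP / (TP + FP), recall = TP / (TP + FN), F1 the harmonic
    mean.  Degenerate 0/0 cells yield 0 with a logged warning.
    """
    cm = np.asarray(cm, dtype=np.int64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ValueError("confusion matrix must be square and non-empty")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    total = int(cm.sum())
    if total == 0:
        raise ValueError("confusion matrix holds no samples")
    per = []
    for c in range(cm.shape[0]):
        tp = int(cm[c, c])
        fp = int(cm[:, c].sum()) - tp
        fn = int(cm[c, :].sum()) - tp
        tn = total - tp - fp - fn
        precision = _safe_div(tp, tp + fp, f"class {c} precision")
        recall = _safe_div(tp, tp + fn, f"class {c} recall")
        f1 = _safe_div(2 * precision * recall, precision + recall, f"class {c} F1")
        per.append(
            ClassMetrics(100.0 * (tp + tn) / total, precision, recall, f1)
        )
    overall = 100.0 * np.trace(cm) / total
    return MetricsReport(tuple(per), overall, cm)


def format_report(rep: MetricsReport, class_names: Sequence[str] | None = None) -> str:
    """Aligned text table: Classes / Acc. / Precision / Recall / F1 score."""
    k = len(rep.per_class)
    names = list(class_names) if class_names else [f"class {c}" for c in range(k)]
    width = max(len(n) for n in names + ["Classes"])
    lines = [
        f"{'Classes':<{width}}  {'Acc. (%)':>9}  {'Precision':>9}  {'Recall':>7}  {'F1 score':>8}"
    ]
    for name, m in zip(names, rep.per_class):
        lines.append(
            f"{name:<{width}}  {m.accuracy_pct:>9.2f}  {m.precision:>9.4f}"
            f"  {m.recall:>7.4f}  {m.f1:>8.4f}"
        )
    lines.append(f"Overall accuracy: {rep.overall_accuracy_pct:.2f}%")
    return "\n".join(lines)
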