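"""Binary classification metrics: confusion counts, accuracy/recall/
precision/F1, and the ROC curve.

The positive class is the patient group (label 1) throughout, so recall is
the fraction of patients correctly detected — the clinically critical number.
Zero-denominator cases (e.g. no positive predictions) return 0 with a
warning rather than NaN.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn import metrics as skm

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts",
           "metrics_from_counts", "roc_curve", "evaluate_predictions"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    recall: float
    precision: float
    f1: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None
    counts: ConfusionCounts | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "auc": self.auc,
        }
        if self.counts is not None:
            payload["counts"] = {"TP": self.counts.tp, "TN": self.counts.tn,
                                 "FP": self.counts.fp, "FN": self.counts.fn}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def roc_to_tsv(self, path: str | Path) -> None:
        lines = ["FPR\tTPR"] + [f"{fpr:.6g}\t{tpr:.6g}" for fpr, tpr in self.roc_points]
        Path(path).write_text("\n".join(lines) + "\n")


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty input to confusion_counts")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary (0/1)")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _safe_ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); returning 0", stacklevel=3)
        return 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    """Accuracy = (TN+TP)/total, recall = TP/(TP+FN), precision = TP/(TP+FP),
    F1 = harmonic mean of precision and recall."""
    if c.total == 0:
        raise ValueError("no samples in confusion counts")
    accuracy = (c.tn + c.tp) / c.total
    recall = _safe_ratio(c.tp, c.tp + c.fn, "recall")
    precision = _safe_ratio(c.tp, c.tp + c.fp, "precision")
    if precision + recall == 0:
        warnings.warn("F1 undefined (precision + recall = 0); returning 0", stacklevel=2)
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(accuracy=accuracy, recall=recall, precision=precision,
                         f1=f1, counts=c)


def roc_curve(y_true, scores) -> tuple[list[tuple[float, float]], float]:
    """Threshold sweep over the class-1 scores; AUC by the trapezoid rule.

    Invariant to strictly monotone transformations of the scores.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC requires both classes in y_true")
    fpr, tpr, _ = skm.roc_curve(y_true, scores, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    return [(float(f), float(t)) for f, t in zip(fpr, tpr)], auc


def evaluate_predictions(y_true, y_pred, scores=None) -> MetricsReport:
    """Full report from hard predictions plus (optionally) class-1 scores."""
    report = metrics_from_counts(confusion_counts(y_true, y_pred))
    if scores is not None and len(np.unique(np.asarray(y_true))) == 2:
        report.roc_points, report.auc = roc_curve(y_true, scores)
    return report
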