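"""Confusion-matrix metric suite for binary nodule classification.

Malignant is the positive class (label 1), benign the negative (label 0):
TP/TN count correctly predicted malignant/benign cases.  Five metrics are
derived: accuracy, precision, sensitivity (recall on malignant), specificity
(recall on benign) and F1 (harmonic mean of precision and sensitivity).

A metric whose denominator is zero is reported as NaN ("undefined"), never
silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "f1")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_array(self) -> np.ndarray:
        """[[TN, FP], [FN, TP]] — rows true class, columns predicted."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


def confusion_matrix(predictions, labels) -> ConfusionMatrix:
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    bad = set(np.unique(predictions)) | set(np.unique(labels))
    if not bad <= {0, 1}:
        raise ValueError(f"labels/predictions must be binary 0/1, saw {sorted(bad)}")
    return ConfusionMatrix(
        tp=int(np.sum((predictions == 1) & (labels == 1))),
        tn=int(np.sum((predictions == 0) & (labels == 0))),
        fp=int(np.sum((predictions == 1) & (labels == 0))),
        fn=int(np.sum((predictions == 0) & (labels == 1))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """The five metrics from one confusion matrix (NaN when undefined)."""
    accuracy = _ratio(cm.tp + cm.tn, cm.total)
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn)  # recall on malignant
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    if math.isnan(precision) or math.isnan(sensitivity) \
            or precision + sensitivity == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    return {"accuracy": accuracy, "precision": precision,
            "sensitivity": sensitivity, "specificity": specificity, "f1": f1}


def evaluate(predictions, labels) -> tuple[ConfusionMatrix, dict[str, float]]:
    """Confusion matrix plus the five metrics for one prediction set."""
    cm = confusion_matrix(predictions, labels)
    return cm, compute_metrics(cm)
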