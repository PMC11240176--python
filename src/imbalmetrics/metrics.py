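"""Confusion matrices and single-threshold classification metrics.

The predicted-positive convention is score >= threshold, so a threshold at
the maximum observed score still predicts a non-empty positive set (the
same convention standard curve constructors use).

Precision is reported as ``None`` (an explicit undefined marker) when no
instance is predicted positive; it is never silently coerced to 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .synthetic import LabeledScores

__all__ = [
    "ConfusionMatrix",
    "PointMetrics",
    "confusion_at_threshold",
    "point_metrics",
    "threshold_metrics",
    "ppv_from_roc",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PointMetrics:
    """Operating-point metrics; ``precision`` is None when TP+FP = 0."""

    precision: Optional[float]
    tpr: float
    fpr: float
    specificity: float
    accuracy: float


def confusion_at_threshold(data: LabeledScores, threshold: float) -> ConfusionMatrix:
    """Counts at one operating point (predicted positive iff score >= threshold)."""
    data.require_both_classes()
    predicted = data.scores >= threshold
    actual = data.labels == 1
    tp = int(np.sum(predicted & actual))
    fp = int(np.sum(predicted & ~actual))
    fn = int(np.sum(~predicted & actual))
    tn = int(np.sum(~predicted & ~actual))
    return ConfusionMatrix(tp, fp, fn, tn)


def point_metrics(cm: ConfusionMatrix) -> PointMetrics:
    if cm.n_pos < 1 or cm.n_neg < 1:
        raise ValueError("need at least one positive and one negative instance")
    predicted_pos = cm.tp + cm.fp
    precision = cm.tp / predicted_pos if predicted_pos > 0 else None
    return PointMetrics(
        precision=precision,
        tpr=cm.tp / cm.n_pos,
        fpr=cm.fp / cm.n_neg,
        specificity=cm.tn / cm.n_neg,
        accuracy=(cm.tp + cm.tn) / cm.total,
    )


def threshold_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """F1, G-mean and MCC at one operating point.

    F1 = 2·precision·recall/(precision+recall), 0 when undefined (no true
    positives among predictions or no predictions at all).  G-mean =
    sqrt(TPR·(1−FPR)).  MCC has the usual 0 convention when any marginal
    of the contingency table is empty.
    """
    pm = point_metrics(cm)
    if pm.precision is None or (pm.precision + pm.tpr) == 0:
        f1 = 0.0
    else:
        f1 = 2 * pm.precision * pm.tpr / (pm.precision + pm.tpr)
    g_mean = math.sqrt(pm.tpr * (1.0 - pm.fpr))
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)
    return {"f1": f1, "g_mean": g_mean, "mcc": mcc}


def ppv_from_roc(tpr: float, fpr: float, prevalence: float) -> Optional[float]:
    """Precision from ROC coordinates and prevalence.

    PPV = TPR·π / (TPR·π + FPR·(1−π)); returns None when TPR = FPR = 0
    (no predicted positives).  This identity makes precision a re-weighting
    of the ROC operating point by the class composition: no information is
    lost by plotting in ROC space.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    if not (0.0 <= tpr <= 1.0 and 0.0 <= fpr <= 1.0):
        raise ValueError("tpr and fpr must be in [0, 1]")
    numerator = tpr * prevalence
    denominator = tpr * prevalence + fpr * (1.0 - prevalence)
    if denominator == 0.0:
        return None
    return numerator / denominator
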