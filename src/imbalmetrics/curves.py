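"""ROC and PR curve construction and AUC estimators.

Curves are built from cumulative true/false-positive counts at the unique
observed score values, sorted descending, so tied instances always move
between operating points together.  ROC-AUC is the trapezoidal area (which
equals the tie-corrected Mann-Whitney U statistic); PR-AUC is average
precision, the recall-weighted step sum — trapezoidal interpolation is
deliberately not used in PR space, where linear interpolation between
operating points is invalid because precision's denominator changes along
the curve.

The partial ROC-AUC restricts the trapezoidal area to FPR in [0, fpr_max]
(linearly interpolating TPR at the boundary) and, when requested, applies
the McClish standardization

    0.5 * (1 + (pAUC - A_min) / (A_max - A_min)),

with A_min = fpr_max^2 / 2 (the chance diagonal's partial area) and
A_max = fpr_max (a perfect classifier), so chance maps to 0.5 and
perfection to 1 regardless of fpr_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .synthetic import LabeledScores

__all__ = [
    "Curve",
    "AUCResult",
    "cumulative_counts",
    "roc_curve",
    "pr_curve",
    "roc_auc",
    "pr_auc",
    "partial_roc_auc",
    "partial_auc_from_curve",
    "mann_whitney_auc",
    "analytic_binormal_auc",
]


@dataclass(frozen=True)
class Curve:
    """An ordered sequence of operating points in ROC or PR space."""

    space: str  # "ROC" or "PR"
    points: tuple[tuple[float, float], ...]
    thresholds: tuple[float, ...]

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def y(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass(frozen=True)
class AUCResult:
    kind: str  # "roc_auc", "pr_auc" or "partial_roc_auc"
    value: float
    fpr_max: float | None = None
    mcclish_corrected: bool | None = None


def cumulative_counts(data: LabeledScores) -> list[tuple[float, int, int]]:
    """(threshold, cumTP, cumFP) at each unique score, descending.

    cumTP/cumFP count the positives/negatives scoring at or above the
    threshold; ties collapse into a single entry.
    """
    data.require_both_classes()
    order = np.argsort(-data.scores, kind="stable")
    scores = data.scores[order]
    labels = data.labels[order]
    cum_tp = np.cumsum(labels)
    cum_fp = np.cumsum(1 - labels)
    # last index of each run of tied scores = the cumulative counts with
    # the whole tie group included
    is_last = np.r_[scores[1:] != scores[:-1], True]
    idx = np.flatnonzero(is_last)
    return [
        (float(scores[i]), int(cum_tp[i]), int(cum_fp[i])) for i in idx
    ]


def roc_curve(data: LabeledScores) -> Curve:
    """ROC curve (FPR, TPR) with a (0, 0) anchor; ends at (1, 1)."""
    counts = cumulative_counts(data)
    p, n = data.n_pos, data.n_neg
    points = [(0.0, 0.0)] + [(fp / n, tp / p) for _, tp, fp in counts]
    thresholds = (np.inf,) + tuple(t for t, _, _ in counts)
    return Curve("ROC", tuple(points), thresholds)


def pr_curve(data: LabeledScores) -> Curve:
    """PR curve (recall, precision) at each unique threshold.

    No anchor point is prepended: the highest measured threshold defines
    the first point, so precision is always computed over a non-empty
    prediction set.
    """
    counts = cumulative_counts(data)
    p = data.n_pos
    points = [(tp / p, tp / (tp + fp)) for _, tp, fp in counts]
    thresholds = tuple(t for t, _, _ in counts)
    return Curve("PR", tuple(points), thresholds)


def roc_auc(data: LabeledScores) -> AUCResult:
    """Trapezoidal area under the ROC curve."""
    curve = roc_curve(data)
    value = float(np.trapezoid(curve.y, curve.x))
    return AUCResult("roc_auc", value)


def pr_auc(data: LabeledScores) -> AUCResult:
    """Average precision: sum_k (R_k - R_{k-1}) * P_k over descending thresholds."""
    curve = pr_curve(data)
    recall = curve.x
    precision = curve.y
    deltas = np.diff(np.r_[0.0, recall])
    return AUCResult("pr_auc", float(np.sum(deltas * precision)))


def partial_auc_from_curve(
    fpr: np.ndarray, tpr: np.ndarray, fpr_max: float, corrected: bool = True
) -> AUCResult:
    """Partial trapezoidal ROC area over FPR in [0, fpr_max] from curve arrays.

    TPR at fpr_max is linearly interpolated when the boundary falls between
    operating points, consistent with trapezoidal ROC semantics.
    """
    if not (0.0 < fpr_max <= 1.0):
        raise ValueError("fpr_max must be in (0, 1]")
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    mask = fpr <= fpr_max
    xs = fpr[mask]
    ys = tpr[mask]
    if xs.size == 0 or xs[-1] < fpr_max:
        boundary_tpr = float(np.interp(fpr_max, fpr, tpr))
        xs = np.r_[xs, fpr_max]
        ys = np.r_[ys, boundary_tpr]
    raw = float(np.trapezoid(ys, xs))
    if not corrected:
        return AUCResult("partial_roc_auc", raw, fpr_max=fpr_max, mcclish_corrected=False)
    a_min = fpr_max**2 / 2.0
    a_max = fpr_max
    value = 0.5 * (1.0 + (raw - a_min) / (a_max - a_min))
    return AUCResult("partial_roc_auc", value, fpr_max=fpr_max, mcclish_corrected=True)


def partial_roc_auc(
    data: LabeledScores, fpr_max: float = 0.1, corrected: bool = True
) -> AUCResult:
    """Partial ROC-AUC of a score dataset up to ``fpr_max``.

    The early-retrieval summary ROC-AUC_0.1 is this with the default
    ``fpr_max=0.1`` and the McClish standardization applied.
    """
    curve = roc_curve(data)
    return partial_auc_from_curve(curve.x, curve.y, fpr_max, corrected)


def mann_whitney_auc(data: LabeledScores) -> float:
    """Tie-corrected pair-counting AUC: (#{pos>neg} + 0.5*#{pos=neg}) / (P*N).

    Exhaustive O(P*N) oracle; intended for cross-checking :func:`roc_auc`
    on small instances, not for production-sized data.
    """
    data.require_both_classes()
    pos = data.positives()[:, None]
    neg = data.negatives()[None, :]
    wins = np.sum(pos > neg) + 0.5 * np.sum(pos == neg)
    return float(wins / (data.n_pos * data.n_neg))


def analytic_binormal_auc(mu: float) -> float:
    """Closed-form ROC-AUC of the unit-variance binormal model: Phi(mu/sqrt(2))."""
    return float(norm.cdf(mu / np.sqrt(2.0)))
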