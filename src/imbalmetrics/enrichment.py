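"""Negative-data enrichment: two ways of changing a dataset's imbalance.

Type I resamples the negative class at random — a subsample without
replacement when shrinking, a resample with replacement when growing — so
the expected negative score distribution is preserved and ROC-AUC is
unchanged in expectation while the PR-AUC moves with the new prevalence.

Type II appends exact copies of the single lowest-scoring negative until
the target ratio is met.  This changes the negative score distribution:
every appended copy is a trivially easy negative, so the ROC-AUC is
inflated by exactly

    AUC_new = (1 - f) * AUC_orig + f * a,

where f is the fraction of negatives that are appended copies and
a = (#{pos > s_min} + 0.5 * #{pos = s_min}) / P is the fraction of
positives ranked above the copied score.  When the copies fall below the
positive score distribution (a ≈ 1), the PR-AUC is essentially unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .synthetic import LabeledScores

__all__ = ["EnrichmentSpec", "enrich_type1", "enrich_type2", "target_negative_count"]


@dataclass(frozen=True)
class EnrichmentSpec:
    """kind: "type_I" (random over/undersampling of negatives, needs a seed)
    or "type_II" (deterministic repetition of the minimum-scoring negative)."""

    kind: str
    target: tuple[int, int]  # target P:N ratio
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("type_I", "type_II"):
            raise ValueError(f"unknown enrichment kind: {self.kind!r}")
        p, n = self.target
        if p < 1 or n < 1:
            raise ValueError("target ratio must be a pair of positive integers")
        if self.kind == "type_I" and self.seed is None:
            raise ValueError("type_I enrichment requires a seed")

    @property
    def target_prevalence(self) -> float:
        p, n = self.target
        return p / (p + n)


def target_negative_count(n_pos: int, target: tuple[int, int]) -> int:
    """Negative count implied by the target P:N ratio with positives fixed."""
    p_parts, n_parts = target
    n_neg = round(n_pos * n_parts / p_parts)
    if n_neg < 1:
        raise ValueError(f"target ratio {target} implies zero negatives for P={n_pos}")
    return n_neg


def enrich_type1(data: LabeledScores, spec: EnrichmentSpec) -> LabeledScores:
    """Random over-/undersampling of negatives to the target ratio.

    Positives are untouched.  Shrinking draws a subset without replacement
    (a true subsample); growing draws with replacement.  Deterministic
    under ``spec.seed``.
    """
    data.require_both_classes()
    if spec.kind != "type_I":
        raise ValueError("enrich_type1 requires a type_I spec")
    pos = data.positives()
    neg = data.negatives()
    n_target = target_negative_count(data.n_pos, spec.target)
    rng = np.random.default_rng(spec.seed)
    if n_target <= neg.size:
        new_neg = rng.choice(neg, size=n_target, replace=False)
    else:
        new_neg = rng.choice(neg, size=n_target, replace=True)
    labels = np.r_[np.ones(pos.size, dtype=np.int8), np.zeros(n_target, dtype=np.int8)]
    return LabeledScores(labels, np.r_[pos, new_neg], seed_record=spec.seed)


def enrich_type2(data: LabeledScores, spec: EnrichmentSpec) -> LabeledScores:
    """Append copies of the minimum-scoring negative up to the target ratio.

    Positives and the original negatives are unchanged; only copies of the
    single lowest-scoring negative are added, so the target prevalence must
    not exceed the current one.  Fully deterministic.
    """
    data.require_both_classes()
    if spec.kind != "type_II":
        raise ValueError("enrich_type2 requires a type_II spec")
    n_target = target_negative_count(data.n_pos, spec.target)
    n_extra = n_target - data.n_neg
    if n_extra < 0:
        raise ValueError(
            "type_II enrichment only adds negatives: target prevalence "
            f"{spec.target_prevalence:.4g} exceeds current {data.prevalence:.4g}"
        )
    s_min = float(data.negatives().min())
    labels = np.r_[data.labels, np.zeros(n_extra, dtype=np.int8)]
    scores = np.r_[data.scores, np.full(n_extra, s_min)]
    return LabeledScores(labels, scores, seed_record=data.seed_record)
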