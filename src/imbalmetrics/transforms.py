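"""Linear transforms of the PR-AUC against its prevalence baseline.

A no-skill classifier's PR-AUC equals the prevalence π, which suggests
three obvious "corrections": subtract the baseline (marginal), divide by
it (normalized, a fold change), or min-max scale between the baseline and
1.  None of them actually removes the imbalance dependence — the PR-AUC's
response to π is non-linear and classifier-specific — which is exactly
what the experiment grid demonstrates.  They are provided so that failure
is reproducible, and because marginal/fold-change reporting is common in
practice.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "TransformedAUC",
    "marginal_pr_auc",
    "normalized_pr_auc",
    "minmax_pr_auc",
    "TRANSFORMS",
]


@dataclass(frozen=True)
class TransformedAUC:
    transform: str  # "marginal", "normalized" or "minmax"
    value: float
    prevalence: float


def _check(pr_auc_value: float, prevalence: float) -> None:
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    if not (0.0 <= pr_auc_value <= 1.0):
        raise ValueError("pr_auc must be in [0, 1]")


def marginal_pr_auc(pr_auc_value: float, prevalence: float) -> TransformedAUC:
    """PR-AUC minus the random baseline π; chance maps to 0."""
    _check(pr_auc_value, prevalence)
    return TransformedAUC("marginal", pr_auc_value - prevalence, prevalence)


def normalized_pr_auc(pr_auc_value: float, prevalence: float) -> TransformedAUC:
    """PR-AUC divided by the random baseline π (fold change); chance maps to 1."""
    _check(pr_auc_value, prevalence)
    return TransformedAUC("normalized", pr_auc_value / prevalence, prevalence)


def minmax_pr_auc(pr_auc_value: float, prevalence: float) -> TransformedAUC:
    """Min-max scaled PR-AUC, (AUC − π)/(1 − π), with min = chance baseline π
    and max = 1; may be negative for below-chance classifiers."""
    _check(pr_auc_value, prevalence)
    return TransformedAUC("minmax", (pr_auc_value - prevalence) / (1.0 - prevalence), prevalence)


TRANSFORMS = {
    "marginal": marginal_pr_auc,
    "normalized": normalized_pr_auc,
    "minmax": minmax_pr_auc,
}
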