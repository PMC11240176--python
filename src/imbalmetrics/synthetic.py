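"""Simulated classifier score distributions at controlled class imbalance.

Score datasets are generated by drawing each class independently from a
fixed distribution, so the per-class score distribution never depends on
the imbalance — the design property that lets ROC/PR behaviour be studied
as a function of class composition alone.

Classifier families
-------------------
binormal
    Negatives ~ Normal(0, 1), positives ~ Normal(mu, 1).  The ROC-AUC has
    the closed form Phi(mu / sqrt(2)).  Presets ``worst``, ``middle`` and
    ``best`` use mu = 0.5, 1.0 and 1.5.
beta
    Positives ~ Beta(alpha_pos, beta_pos), negatives ~ Beta(alpha_neg,
    beta_neg).  Presets ``good_ER`` and ``bad_ER`` both have full ROC-AUC
    of exactly 4/5 but opposite early-retrieval behaviour.
no_skill
    Both classes ~ Normal(0, 1); ROC-AUC 0.5, PR-AUC equal to prevalence.
bimodal_standin
    A fixed bimodal mixture emulating a realistic prediction-score
    distribution (most negatives concentrated at low scores, a minority
    overlapping the positives); see :func:`simulate_bimodal_standin`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ClassifierSpec",
    "ImbalanceSpec",
    "LabeledScores",
    "PRESETS",
    "IMBALANCE_PRESETS",
    "simulate",
    "simulate_bimodal_standin",
    "spawn_seeds",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Generative description of a simulated classifier.

    Parameters
    ----------
    family : {"binormal", "beta", "no_skill", "bimodal_standin"}
    mu : float, optional
        Positive-class mean (binormal only).
    alpha_pos, beta_pos, alpha_neg, beta_neg : float, optional
        Beta shape parameters (beta family only); all must be > 0.
    """

    family: str
    mu: Optional[float] = None
    alpha_pos: Optional[float] = None
    beta_pos: Optional[float] = None
    alpha_neg: Optional[float] = None
    beta_neg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family == "binormal":
            if self.mu is None:
                raise ValueError("binormal family requires mu")
        elif self.family == "beta":
            shapes = (self.alpha_pos, self.beta_pos, self.alpha_neg, self.beta_neg)
            if any(s is None for s in shapes):
                raise ValueError("beta family requires alpha/beta for both classes")
            if any(s <= 0 for s in shapes):  # type: ignore[operator]
                raise ValueError("beta shape parameters must be positive")
        elif self.family in ("no_skill", "bimodal_standin"):
            pass
        else:
            raise ValueError(f"unknown classifier family: {self.family!r}")

    @classmethod
    def preset(cls, name: str) -> "ClassifierSpec":
        try:
            return PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown preset {name!r}; available: {sorted(PRESETS)}"
            ) from None


PRESETS: dict[str, ClassifierSpec] = {
    "worst": ClassifierSpec("binormal", mu=0.5),
    "middle": ClassifierSpec("binormal", mu=1.0),
    "best": ClassifierSpec("binormal", mu=1.5),
    "good_ER": ClassifierSpec("beta", alpha_pos=1, beta_pos=1, alpha_neg=1, beta_neg=4),
    "bad_ER": ClassifierSpec("beta", alpha_pos=4, beta_pos=1, alpha_neg=1, beta_neg=1),
    "no_skill": ClassifierSpec("no_skill"),
    "bimodal_standin": ClassifierSpec("bimodal_standin"),
}


@dataclass(frozen=True)
class ImbalanceSpec:
    """Class composition of a dataset: a P:N ratio and a total size.

    ``ratio`` is a pair of positive integers (P parts, N parts); prevalence
    is ``p / (p + n)``.  The positive count is ``round(prevalence *
    total_n)`` (banker's rounding), clipped so both classes are non-empty.
    """

    ratio: tuple[int, int]
    total_n: int = 10_000

    def __post_init__(self) -> None:
        p, n = self.ratio
        if p < 1 or n < 1 or p != int(p) or n != int(n):
            raise ValueError(f"ratio must be a pair of positive integers, got {self.ratio}")
        if self.total_n < 2:
            raise ValueError("total_n must be at least 2")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError(
                f"imbalance {self.ratio} at total_n={self.total_n} leaves an empty class"
            )

    @property
    def prevalence(self) -> float:
        p, n = self.ratio
        return p / (p + n)

    @property
    def n_pos(self) -> int:
        return min(max(round(self.prevalence * self.total_n), 1), self.total_n - 1)

    @property
    def n_neg(self) -> int:
        return self.total_n - self.n_pos

    @classmethod
    def from_string(cls, text: str, total_n: int = 10_000) -> "ImbalanceSpec":
        """Parse a ratio string like ``"1:99"``."""
        try:
            p, n = (int(part) for part in text.split(":"))
        except ValueError:
            raise ValueError(f"cannot parse imbalance ratio {text!r}") from None
        return cls((p, n), total_n)

    def __str__(self) -> str:
        return f"{self.ratio[0]}:{self.ratio[1]}"


IMBALANCE_PRESETS = ("1:99", "1:9", "1:1")


@dataclass
class LabeledScores:
    """Real-valued classifier scores with binary ground-truth labels."""

    labels: np.ndarray
    scores: np.ndarray
    seed_record: Optional[int] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.labels.shape != self.scores.shape or self.labels.ndim != 1:
            raise ValueError("labels and scores must be 1-D arrays of equal length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        self.labels = self.labels.astype(np.int8)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(self.labels.size - self.labels.sum())

    @property
    def prevalence(self) -> float:
        return self.n_pos / self.labels.size

    def require_both_classes(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one positive and one negative instance")

    def positives(self) -> np.ndarray:
        return self.scores[self.labels == 1]

    def negatives(self) -> np.ndarray:
        return self.scores[self.labels == 0]


def spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent child seeds from a master seed.

    Uses :class:`numpy.random.SeedSequence` spawning, the documented
    splitting scheme: child ``i`` is ``SeedSequence(master_seed).spawn(n)[i]``
    reduced to a single uint32 state word.  Recording a child seed is enough
    to rerun that repeat in isolation.
    """
    children = np.random.SeedSequence(master_seed).spawn(n)
    return np.array([int(c.generate_state(1)[0]) for c in children], dtype=np.uint32)


def _draw(spec: ClassifierSpec, n_pos: int, n_neg: int, rng: np.random.Generator):
    if spec.family == "binormal":
        pos = rng.normal(spec.mu, 1.0, size=n_pos)
        neg = rng.normal(0.0, 1.0, size=n_neg)
    elif spec.family == "beta":
        pos = rng.beta(spec.alpha_pos, spec.beta_pos, size=n_pos)
        neg = rng.beta(spec.alpha_neg, spec.beta_neg, size=n_neg)
    elif spec.family == "no_skill":
        pos = rng.normal(0.0, 1.0, size=n_pos)
        neg = rng.normal(0.0, 1.0, size=n_neg)
    elif spec.family == "bimodal_standin":
        pos = rng.beta(*_STANDIN_POS, size=n_pos)
        low = rng.beta(*_STANDIN_NEG_LOW, size=n_neg)
        high = rng.beta(*_STANDIN_NEG_HIGH, size=n_neg)
        neg = np.where(rng.random(n_neg) < _STANDIN_NEG_LOW_WEIGHT, low, high)
    else:  # pragma: no cover - guarded in ClassifierSpec
        raise ValueError(spec.family)
    return pos, neg


def simulate(
    spec: ClassifierSpec, imb: ImbalanceSpec, seed: int
) -> LabeledScores:
    """Draw a labeled score dataset with exactly the composition of ``imb``.

    Positives precede negatives in the output arrays; identical
    ``(spec, imb, seed)`` yields byte-identical output.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    pos, neg = _draw(spec, imb.n_pos, imb.n_neg, rng)
    labels = np.concatenate([np.ones(imb.n_pos, dtype=np.int8), np.zeros(imb.n_neg, dtype=np.int8)])
    return LabeledScores(labels, np.concatenate([pos, neg]), seed_record=int(seed))


# Fixed mixture parameters of the bimodal stand-in (scores in [0, 1]):
# positives concentrated high; negatives mostly a low-score mode with a
# 20% component overlapping the positives.
_STANDIN_POS = (8.0, 3.0)
_STANDIN_NEG_LOW = (1.5, 10.0)
_STANDIN_NEG_HIGH = (5.0, 3.0)
_STANDIN_NEG_LOW_WEIGHT = 0.8


def simulate_bimodal_standin(imb: ImbalanceSpec, seed: int) -> LabeledScores:
    """Bimodal score dataset emulating a realistic model's output.

    Positives ~ Beta(8, 3); negatives are a 0.8/0.2 mixture of Beta(1.5, 10)
    (the low-score bulk) and Beta(5, 3) (the hard tail overlapping the
    positives).  The resulting ROC-AUC is ~0.9, strictly between chance and
    perfection, and the minimum negative sits far below the positive score
    range, which is what the type II enrichment experiments require.
    """
    return simulate(ClassifierSpec("bimodal_standin"), imb, seed)
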