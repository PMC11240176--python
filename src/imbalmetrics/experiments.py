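"""Simulation grids: classifiers x imbalances x repeats, in tidy long format.

The full grid reproduces the core contrasts of the imbalance study:

* ROC-AUC (and the McClish-corrected ROC-AUC_0.1) is invariant to the
  class composition, because the per-class score distributions are fixed.
* PR-AUC, and every linear transform of it against its prevalence
  baseline, moves with the imbalance.
* At a fixed threshold, G-mean is imbalance-invariant in expectation while
  F1 and MCC are not.

`run_enrichment_study` runs the negative-data-enrichment ladder on the
bimodal stand-in dataset: type I (random resampling of negatives) leaves
ROC-AUC flat while PR-AUC tracks prevalence; type II (copying the lowest
negative) inflates ROC-AUC and leaves PR-AUC unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .curves import partial_roc_auc, pr_auc, roc_auc
from .enrichment import EnrichmentSpec, enrich_type1, enrich_type2
from .metrics import confusion_at_threshold, threshold_metrics
from .synthetic import (
    ClassifierSpec,
    ImbalanceSpec,
    LabeledScores,
    PRESETS,
    simulate,
    simulate_bimodal_standin,
    spawn_seeds,
)
from .transforms import TRANSFORMS

__all__ = [
    "GridConfig",
    "EnrichmentStudyConfig",
    "DEFAULT_METRICS",
    "compute_metrics",
    "run_grid",
    "summarize",
    "run_enrichment_study",
    "load_grid_config",
]

logger = logging.getLogger("imbalmetrics")

DEFAULT_METRICS = (
    "roc_auc",
    "pr_auc",
    "roc_auc_0.1",
    "f1",
    "g_mean",
    "mcc",
    "marginal_pr_auc",
    "normalized_pr_auc",
    "minmax_pr_auc",
)


@dataclass(frozen=True)
class GridConfig:
    """Configuration of a simulation grid; defaults mirror the study design
    (total_n 10,000; imbalances 1:99/1:9/1:1; 1,000 repeats; FPR_max 0.1;
    fixed threshold 0.5)."""

    classifiers: tuple[str, ...] = ("worst", "middle", "best")
    imbalances: tuple[str, ...] = ("1:99", "1:9", "1:1")
    total_n: int = 10_000
    repeats: int = 1_000
    master_seed: int = 0
    fpr_max: float = 0.1
    fixed_threshold: float = 0.5
    metrics: tuple[str, ...] = DEFAULT_METRICS

    def __post_init__(self) -> None:
        for name in self.classifiers:
            if name not in PRESETS:
                raise ValueError(f"unknown classifier preset {name!r}; available: {sorted(PRESETS)}")
        for ratio in self.imbalances:
            ImbalanceSpec.from_string(ratio, self.total_n)  # validates
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        unknown = set(self.metrics) - set(DEFAULT_METRICS)
        if unknown:
            raise ValueError(f"unknown metrics {sorted(unknown)}; available: {DEFAULT_METRICS}")


def compute_metrics(
    data: LabeledScores,
    metrics: Sequence[str] = DEFAULT_METRICS,
    fpr_max: float = 0.1,
    fixed_threshold: float = 0.5,
) -> dict[str, float]:
    """All requested metric values for one labeled score dataset."""
    out: dict[str, float] = {}
    wanted = set(metrics)
    pr = None
    if wanted & {"pr_auc", "marginal_pr_auc", "normalized_pr_auc", "minmax_pr_auc"}:
        pr = pr_auc(data).value
    if "roc_auc" in wanted:
        out["roc_auc"] = roc_auc(data).value
    if "pr_auc" in wanted:
        out["pr_auc"] = pr
    if "roc_auc_0.1" in wanted:
        out["roc_auc_0.1"] = partial_roc_auc(data, fpr_max=fpr_max, corrected=True).value
    if wanted & {"f1", "g_mean", "mcc"}:
        tm = threshold_metrics(confusion_at_threshold(data, fixed_threshold))
        for name in ("f1", "g_mean", "mcc"):
            if name in wanted:
                out[name] = tm[name]
    for name, fn in TRANSFORMS.items():
        key = f"{name}_pr_auc"
        if key in wanted:
            out[key] = fn(pr, data.prevalence).value
    return out


def run_grid(config: GridConfig) -> pd.DataFrame:
    """Run the full simulation grid.

    Returns a tidy table with one row per (classifier, imbalance, repeat,
    metric); every row records the child seed that regenerates its dataset.
    """
    cells = [
        (c, r) for c in config.classifiers for r in config.imbalances
    ]
    seeds = spawn_seeds(config.master_seed, len(cells) * config.repeats)
    rows: list[tuple] = []
    k = 0
    for classifier, ratio in cells:
        spec = ClassifierSpec.preset(classifier)
        imb = ImbalanceSpec.from_string(ratio, config.total_n)
        for repeat in range(config.repeats):
            seed = int(seeds[k])
            k += 1
            data = simulate(spec, imb, seed)
            values = compute_metrics(
                data, config.metrics, config.fpr_max, config.fixed_threshold
            )
            rows.extend(
                (classifier, ratio, repeat, seed, metric, value)
                for metric, value in values.items()
            )
        logger.info(
            "grid cell %s @ %s done: %d repeats, %d rows so far",
            classifier, ratio, config.repeats, len(rows),
        )
    return pd.DataFrame(
        rows, columns=["classifier", "imbalance", "repeat", "seed", "metric", "value"]
    )


def summarize(rows: pd.DataFrame, by: Sequence[str] | None = None) -> pd.DataFrame:
    """Median, mean, IQR and repeat count per (classifier, imbalance, metric)."""
    if rows.empty:
        raise ValueError("cannot summarize an empty result table")
    if by is None:
        by = [c for c in ("enrichment", "classifier", "imbalance", "metric") if c in rows.columns]
    grouped = rows.groupby(list(by), sort=False)["value"]
    out = grouped.agg(
        median="median",
        mean="mean",
        iqr=lambda v: float(np.subtract(*np.percentile(v, [75, 25]))),
        n="count",
    ).reset_index()
    return out


@dataclass(frozen=True)
class EnrichmentStudyConfig:
    """Ladder of target imbalances applied to a common base dataset.

    The base dataset is the bimodal stand-in at imbalance ``base_ratio``
    (default 3:7, i.e. 30% positives — a moderately imbalanced starting
    composition) and the study's canonical dataset size of 10,000.  Type II
    can only add negatives, so its ladder contains only targets at or below
    the base prevalence.  Note the 9:1 undersampling rung keeps only
    ~P/9 negatives, so the partial AUC there is estimated from a coarse
    FPR grid; much smaller base sizes make that rung unreliable.
    """

    base_ratio: tuple[int, int] = (3, 7)
    base_total_n: int = 10_000
    targets_type1: tuple[str, ...] = ("1:99", "1:9", "3:7", "1:1", "9:1")
    targets_type2: tuple[str, ...] = ("3:7", "1:3", "1:9", "1:49", "1:99")
    repeats: int = 50
    master_seed: int = 0
    fpr_max: float = 0.1

    def __post_init__(self) -> None:
        base = self.base_ratio[0] / sum(self.base_ratio)
        for ratio in self.targets_type2:
            p, n = ImbalanceSpec.from_string(ratio).ratio
            if p / (p + n) > base + 1e-12:
                raise ValueError(
                    f"type_II target {ratio} exceeds the base prevalence {base:.3g}"
                )


_STUDY_METRICS = ("roc_auc", "roc_auc_0.1", "pr_auc")


def run_enrichment_study(config: EnrichmentStudyConfig) -> pd.DataFrame:
    """Run both enrichment ladders; one row per (kind, target, repeat, metric).

    The ``baseline`` metric rows record the enriched dataset's prevalence,
    the PR-AUC of a no-skill classifier at that composition.
    """
    seeds = spawn_seeds(config.master_seed, 2 * config.repeats)
    base_imb = ImbalanceSpec(config.base_ratio, config.base_total_n)
    rows: list[tuple] = []
    for repeat in range(config.repeats):
        base_seed = int(seeds[repeat])
        base = simulate_bimodal_standin(base_imb, base_seed)
        enrich_seed = int(seeds[config.repeats + repeat])
        for j, ratio in enumerate(config.targets_type1):
            spec = EnrichmentSpec("type_I", ImbalanceSpec.from_string(ratio).ratio,
                                  seed=enrich_seed + j)
            rows.extend(_study_rows("type_I", ratio, repeat, base_seed,
                                    enrich_type1(base, spec), config.fpr_max))
        for ratio in config.targets_type2:
            spec = EnrichmentSpec("type_II", ImbalanceSpec.from_string(ratio).ratio)
            rows.extend(_study_rows("type_II", ratio, repeat, base_seed,
                                    enrich_type2(base, spec), config.fpr_max))
    logger.info("enrichment study done: %d rows", len(rows))
    return pd.DataFrame(
        rows,
        columns=["enrichment", "imbalance", "repeat", "seed", "metric", "value"],
    )


def _study_rows(kind, ratio, repeat, seed, data, fpr_max):
    values = compute_metrics(data, _STUDY_METRICS, fpr_max=fpr_max)
    values["baseline"] = data.prevalence
    return [(kind, ratio, repeat, seed, m, v) for m, v in values.items()]


def load_grid_config(path) -> GridConfig:
    """Read a GridConfig from flat key = value text.

    Blank lines and ``#`` comments are ignored; list-valued keys
    (``classifiers``, ``imbalances``, ``metrics``) are comma-separated.
    """
    raw: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            raw[key] = value
    kwargs: dict = {}
    for key in ("classifiers", "imbalances", "metrics"):
        if key in raw:
            kwargs[key] = tuple(v.strip() for v in raw.pop(key).split(","))
    for key, cast in (("total_n", int), ("repeats", int), ("master_seed", int),
                      ("fpr_max", float), ("fixed_threshold", float)):
        if key in raw:
            kwargs[key] = cast(raw.pop(key))
    if raw:
        raise ValueError(f"{path}: unknown config keys {sorted(raw)}")
    return GridConfig(**kwargs)
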