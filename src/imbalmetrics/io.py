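"""Reading and writing labeled score tables and curve tables.

Score tables are two-column delimited text with header ``label<sep>score``;
labels are literal 0/1. Tab-separated is the default dialect; a ``.csv``
extension switches to commas on both read and write.
"""

from __future__ import annotations

import os
from typing import Union

import pandas as pd

from .synthetic import LabeledScores

__all__ = ["write_scores", "read_scores", "write_curve"]

PathLike = Union[str, os.PathLike]


def _sep_for(path: PathLike) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def write_scores(data: LabeledScores, path: PathLike) -> None:
    """Write a ``label<TAB>score`` table (comma-separated for ``.csv``)."""
    df = pd.DataFrame({"label": data.labels.astype(int), "score": data.scores})
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_scores(path: PathLike) -> LabeledScores:
    """Read a score table written by :func:`write_scores` (or user-supplied)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if not {"label", "score"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'label' and 'score'")
    return LabeledScores(df["label"].to_numpy(), df["score"].to_numpy())


def write_curve(curve, path: PathLike) -> None:
    """Write a curve as delimited text with one (x, y, threshold) row per point."""
    xs, ys = zip(*curve.points)
    names = ("fpr", "tpr") if curve.space == "ROC" else ("recall", "precision")
    df = pd.DataFrame({names[0]: xs, names[1]: ys, "threshold": curve.thresholds})
    df.to_csv(path, sep=_sep_for(path), index=False)
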