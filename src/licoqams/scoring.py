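"""Composite desirability score Z for ranking extraction conditions.

Within one experimental block (a single-factor sweep, or the DES screening
panel) each compound's extraction rate is normalized to the block maximum
for that compound, giving six index scores in (0, 1]; Z is their weighted
mean (equal weights 1/6 by default).  The condition maximizing Z wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .study_data import COMPOUNDS

__all__ = ["ExtractionTable", "ScoreResult", "index_scores",
           "comprehensive_score", "rank_conditions"]

EQUAL_WEIGHTS = np.full(6, 1.0 / 6.0)


@dataclass
class ExtractionTable:
    """Extraction rates (%) of the six licorice compounds across the
    conditions of one experimental block."""

    group_label: str
    rates: pd.DataFrame  # index: condition label, columns: the six compounds
    sds: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if list(self.rates.columns) != list(COMPOUNDS):
            raise ValueError(
                f"rates must have exactly the six compound columns {COMPOUNDS}")
        if len(self.rates) == 0:
            raise ValueError("table needs at least one condition row")
        if (self.rates.to_numpy() < 0).any():
            raise ValueError("extraction rates must be >= 0")

    @property
    def conditions(self) -> list[str]:
        return list(self.rates.index)


@dataclass(frozen=True)
class ScoreResult:
    condition_label: str
    index_scores: dict[str, float]
    z_score: float


def index_scores(table: ExtractionTable) -> pd.DataFrame:
    """Per-row index scores: each rate divided by its compound's block maximum."""
    maxima = table.rates.max(axis=0)
    dead = maxima[maxima <= 0]
    if len(dead):
        raise ValueError(
            f"all-zero extraction rates for {list(dead.index)} in block "
            f"{table.group_label!r}; index score undefined")
    return table.rates / maxima


def comprehensive_score(scores: Sequence[float],
                        weights: Optional[Sequence[float]] = None) -> float:
    """Weighted mean of the six index scores (weights default to 1/6 each)."""
    s = np.asarray(scores, dtype=float)
    if s.size != 6:
        raise ValueError(f"expected six index scores, got {s.size}")
    if (s < 0).any() or (s > 1 + 1e-12).any():
        raise ValueError("index scores must lie in [0, 1]")
    w = EQUAL_WEIGHTS if weights is None else np.asarray(weights, dtype=float)
    if w.size != 6 or (w < 0).any():
        raise ValueError("need six nonnegative weights")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
    return float(s @ w)


def score_table(table: ExtractionTable,
                weights: Optional[Sequence[float]] = None) -> list[ScoreResult]:
    """Index scores and Z for every condition of a block."""
    idx = index_scores(table)
    out = []
    for label, row in idx.iterrows():
        out.append(ScoreResult(
            condition_label=str(label),
            index_scores=row.to_dict(),
            z_score=comprehensive_score(row.to_numpy(), weights),
        ))
    return out


def rank_conditions(table: ExtractionTable,
                    weights: Optional[Sequence[float]] = None
                    ) -> list[tuple[str, float]]:
    """Conditions ordered by descending Z; ties keep input order and warn."""
    results = score_table(table, weights)
    ranked = sorted(results, key=lambda r: -r.z_score)
    zs = [round(r.z_score, 12) for r in ranked]
    if len(set(zs)) < len(zs):
        warnings.warn(
            f"tied Z scores in block {table.group_label!r}; "
            "tie order follows input order", stacklevel=2)
    return [(r.condition_label, r.z_score) for r in ranked]
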