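"""Rank-summation (Mulamba-Mock) selection index.

Genotypes are ranked per trait in the breeder-chosen direction (rank 1 =
best), the ranks are summed — optionally with positive per-trait economic
weights, here conventionally the genotypic coefficients of variation —
and the genotypes with the smallest index are retained at a chosen
selection intensity.  Being rank-based, the index is invariant to any
strictly monotone transform of a trait and to common positive rescaling
of the weights.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .traits_io import TraitSpec

logger = logging.getLogger(__name__)

TIE_POLICIES = ("average", "min", "first")


@dataclass
class RankMatrix:
    """Genotype x trait matrix of ranks (1 = best after direction)."""

    ranks: pd.DataFrame
    tie_policy: str

    @property
    def genotypes(self) -> pd.Index:
        return self.ranks.index

    @property
    def traits(self) -> list[str]:
        return list(self.ranks.columns)


@dataclass
class SelectionResult:
    """Outcome of truncation on the rank-sum index.

    ``table`` has one row per genotype: index value I, overall rank and a
    selected flag; smaller I is better.
    """

    table: pd.DataFrame
    intensity: float
    n_selected: int
    weights: pd.Series | None = None
    tie_at_cutoff: bool = False

    @property
    def selected_ids(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def rank_traits(
    values: pd.DataFrame,
    specs: Sequence[TraitSpec] | Mapping[str, TraitSpec],
    tie_policy: str = "average",
) -> RankMatrix:
    """Rank genotypes within each trait in its direction of improvement.

    For direction +1 the largest value gets rank 1.  Missing values rank
    last (worst) and are logged; ties follow ``tie_policy`` (``average``,
    ``min`` or ``first``).
    """
    if tie_policy not in TIE_POLICIES:
        raise ValueError(
            f"tie_policy must be one of {TIE_POLICIES}, got {tie_policy!r}")
    spec_map = ({s.name: s for s in specs}
                if not isinstance(specs, Mapping) else dict(specs))
    unknown = [c for c in values.columns if c not in spec_map]
    if unknown:
        raise KeyError(f"traits without a registered direction: {unknown}")

    ranks = pd.DataFrame(index=values.index, columns=values.columns,
                         dtype=float)
    for trait in values.columns:
        col = values[trait].astype(float)
        if col.isna().all():
            raise ValueError(f"trait {trait!r} has no observed values")
        n_missing = int(col.isna().sum())
        if n_missing:
            logger.warning(
                "trait %s: %d genotypes missing; ranked last (%s)",
                trait, n_missing,
                ", ".join(map(str, col.index[col.isna()][:5])))
        ascending = spec_map[trait].direction == -1
        ranks[trait] = col.rank(
            ascending=ascending, method=tie_policy, na_option="bottom")
    return RankMatrix(ranks=ranks, tie_policy=tie_policy)


def mulamba_mock(
    ranks: RankMatrix | pd.DataFrame,
    weights: Mapping[str, float] | pd.Series | None = None,
) -> pd.Series:
    """Weighted sum-of-ranks index I_i = sum_j p_j r_ij (lower is better).

    With ``weights=None`` all p_j = 1 (the unweighted index).  Weights
    must be non-negative and cover every trait in the rank matrix.
    """
    frame = ranks.ranks if isinstance(ranks, RankMatrix) else ranks
    if weights is None:
        index = frame.sum(axis=1)
    else:
        w = pd.Series(weights, dtype=float).reindex(frame.columns)
        if w.isna().any():
            missing = list(w.index[w.isna()])
            raise KeyError(f"missing weights for traits: {missing}")
        if (w < 0).any():
            raise ValueError("economic weights must be non-negative")
        index = frame.mul(w, axis=1).sum(axis=1)
    index.name = "index"
    return index


def weights_from_cvg(cvg: Mapping[str, float] | pd.Series) -> pd.Series:
    """Economic weights p_j = CVg_j (%); zero-CVg traits get weight 0.

    A zero weight effectively drops the trait from the index and is
    logged.
    """
    w = pd.Series(cvg, dtype=float)
    if w.isna().any():
        raise ValueError(
            f"CVg missing for traits: {list(w.index[w.isna()])}")
    if (w < 0).any():
        raise ValueError("CVg values must be non-negative")
    zero = list(w.index[w == 0])
    if zero:
        logger.warning("traits with CVg = 0 receive weight 0: %s", zero)
    w.name = "weight"
    return w


def selection_count(n: int, intensity: float) -> int:
    """Number retained: round(n * intensity) with half-up rounding.

    Intensity 1.0 (keep everybody, zero selection pressure) is allowed
    as a degenerate case.
    """
    if not 0.0 < intensity <= 1.0:
        raise ValueError(
            f"selection intensity must be in (0, 1], got {intensity}")
    return int(math.floor(n * intensity + 0.5))


def select(
    index_values: pd.Series,
    intensity: float,
    ranks: RankMatrix | None = None,
    weights: pd.Series | None = None,
) -> SelectionResult:
    """Truncate the index at the given selection intensity.

    Retains the ``round(n * intensity)`` genotypes (half-up rounding)
    with the smallest index values.  Ties spanning the cutoff are broken
    deterministically by genotype identifier order and logged.
    """
    n = len(index_values)
    k = selection_count(n, intensity)
    if k == 0:
        raise ValueError(
            f"intensity {intensity} of {n} genotypes selects nobody")

    order = index_values.to_frame("index")
    order["_id"] = order.index.astype(str)
    order = order.sort_values(["index", "_id"], kind="mergesort")

    cutoff = order["index"].iloc[k - 1]
    tie_at_cutoff = (k < n) and (order["index"].iloc[k] == cutoff)
    if tie_at_cutoff:
        logger.warning(
            "index tie at the selection cutoff (I = %g); broken by "
            "genotype_id order", cutoff)

    table = order.drop(columns="_id")
    table["overall_rank"] = np.arange(1, n + 1)
    table["selected"] = table["overall_rank"] <= k
    table = table.reindex(index_values.index)
    if ranks is not None:
        table = ranks.ranks.add_prefix("rank_").join(table)
    return SelectionResult(
        table=table, intensity=intensity, n_selected=k,
        weights=weights, tie_at_cutoff=tie_at_cutoff)


def run_selection(
    values: pd.DataFrame,
    specs: Sequence[TraitSpec] | Mapping[str, TraitSpec],
    intensity: float,
    weights: Mapping[str, float] | pd.Series | None = None,
    tie_policy: str = "average",
) -> SelectionResult:
    """Rank, combine and truncate in one call; the module's main entry."""
    ranks = rank_traits(values, specs, tie_policy=tie_policy)
    w = None if weights is None else pd.Series(weights, dtype=float)
    index = mulamba_mock(ranks, w)
    return select(index, intensity, ranks=ranks, weights=w)
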