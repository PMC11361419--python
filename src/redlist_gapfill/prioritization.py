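"""Greedy cell-removal spatial prioritization (zonation-style).

Unprotected grid cells are ranked by iterative greedy removal: at each step
the lowest-valued cells are removed (``warp`` of them per iteration, without
intra-block recomputation), and a cell's value is recomputed from the
species' *remaining* unprotected distributions — q_ij, cell i's fraction of
species j's remaining cells — either additively, value_i = sum_j w_j q_ij
(the rule used by default), or in max-benefit (core-area) form,
value_i = max_j w_j q_ij. The removal order defines a normalized rank in
[0, 1]: the first cell removed (least valuable) gets 0, the last survivor
(highest priority) gets 1. Protected cells are masked out: they are never
ranked and never enter the q_ij denominators (a flag can re-include them in
denominators).

Species weights follow the status-based scheme (Non-Threatened 1, DDNE 2,
Threatened 6) or its sensitivity variant where predicted species are
weighted by the average model vote fraction p: predicted Threatened
2 + p rescaled onto [2, 5], predicted Non-Threatened 2 − p rescaled onto
[1, 2], DDNE 2, while IUCN-evaluated species keep the fixed weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .synthetic_world import DDNE, NON_THREATENED, THREATENED

FIXED_WEIGHTS = {NON_THREATENED: 1.0, DDNE: 2.0, THREATENED: 6.0}


class WeightingError(ValueError):
    pass


class NothingToRankError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class WeightScheme:
    mode: Literal["fixed", "sensitivity"] = "fixed"
    #: how "2 + p (rescaled)" is read: "affine-p" maps the admissible vote
    #: fractions affinely onto the stated interval; "rescale-sum" rescales
    #: the raw 2±p values onto it. Both hit the stated endpoints.
    rescale: Literal["affine-p", "rescale-sum"] = "affine-p"
    consensus_threshold: float = 0.8


def _rescale(x: np.ndarray, src: tuple[float, float], dst: tuple[float, float]) -> np.ndarray:
    s0, s1 = src
    d0, d1 = dst
    return d0 + (np.clip(x, s0, s1) - s0) * (d1 - d0) / (s1 - s0)


def assign_weights(
    status: pd.Series,
    predicted: pd.Series | None = None,
    p: pd.Series | None = None,
    scheme: WeightScheme | None = None,
) -> pd.Series:
    """Per-species prioritization weight.

    ``status`` holds the scenario status (T/NT/DDNE) per species. In
    sensitivity mode, ``predicted`` marks species whose status came from the
    model rather than an assessment, and ``p`` carries their average vote
    fraction; evaluated species keep the fixed weights and predicted ones
    are weighted by consensus strength.
    """
    if scheme is None:
        scheme = WeightScheme()
    bad = set(status.unique()) - set(FIXED_WEIGHTS)
    if bad:
        raise WeightingError(f"unknown status values {sorted(bad)}")
    w = status.map(FIXED_WEIGHTS).astype(float)
    if scheme.mode == "fixed":
        return w
    if predicted is None:
        raise WeightingError("sensitivity mode needs the predicted-species indicator")
    predicted = predicted.reindex(status.index, fill_value=False).astype(bool)
    tau = scheme.consensus_threshold
    for sid in status.index[predicted]:
        st = status[sid]
        if st == DDNE:
            w[sid] = 2.0
            continue
        if p is None or sid not in p.index or pd.isna(p[sid]):
            raise WeightingError(f"species {sid!r} is predicted but has no vote fraction p")
        pv = float(p[sid])
        if st == THREATENED:
            # admissible calls have p in (tau, 1]
            if scheme.rescale == "affine-p":
                w[sid] = float(_rescale(np.array([pv]), (tau, 1.0), (2.0, 5.0))[0])
            else:
                w[sid] = float(_rescale(np.array([2.0 + pv]), (2.0 + tau, 3.0), (2.0, 5.0))[0])
        elif st == NON_THREATENED:
            # admissible calls have agreement 1-p in (tau, 1]
            q = 1.0 - pv
            if scheme.rescale == "affine-p":
                w[sid] = float(_rescale(np.array([q]), (tau, 1.0), (2.0, 1.0))[0])
            else:
                w[sid] = float(_rescale(np.array([2.0 - q]), (1.0, 2.0 - tau), (1.0, 2.0))[0])
    return w


@dataclass(frozen=True)
class ZonationConfig:
    warp: int = 1000
    value_mode: Literal["additive", "max_benefit"] = "additive"
    #: when True, q_ij denominators count a species' protected cells too
    include_protected_in_denominator: bool = False

    def __post_init__(self) -> None:
        if self.warp < 1:
            raise ValueError("warp must be >= 1")


@dataclass
class RankMap:
    """Removal order and normalized priority rank per unprotected cell.

    ``rank`` is NaN and ``removal_order`` −1 on protected cells. Normalized
    rank is (removal position − 1)/(n_unprotected − 1): first removed
    (least valuable) 0, removed last (highest priority) 1. A single
    unprotected cell gets rank 1.0.
    """

    rank: np.ndarray  # flat, length n_cells
    removal_order: np.ndarray  # flat, 1-based removal position; -1 protected
    protected_mask: np.ndarray  # flat bool

    @property
    def n_ranked(self) -> int:
        return int((~self.protected_mask).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_index": np.arange(self.rank.size),
                "protected": self.protected_mask,
                "removal_order": self.removal_order,
                "rank": self.rank,
            }
        )


def _presence_matrix(ranges, n_cells: int) -> tuple[np.ndarray, list[str]]:
    """Boolean (n_species, n_cells) occupancy from a dict of RangeRaster or
    of cell-index arrays."""
    ids = sorted(ranges)
    occ = np.zeros((len(ids), n_cells), dtype=bool)
    for k, sid in enumerate(ids):
        r = ranges[sid]
        cells = r.cells if hasattr(r, "cells") else np.asarray(r, dtype=np.int64)
        occ[k, cells] = True
    return occ, ids


def zonation_rank(
    ranges: dict,
    weights: pd.Series,
    config: ZonationConfig | None = None,
    protected_mask: np.ndarray | None = None,
    n_cells: int | None = None,
) -> RankMap:
    """Rank unprotected cells by iterative greedy removal.

    Parameters
    ----------
    ranges
        Mapping species_id -> RangeRaster (or array of occupied cell
        indices). All species must share one grid.
    weights
        Positive per-species weights indexed by species_id.
    protected_mask
        Boolean mask (any shape that flattens to n_cells); protected cells
        are excluded from ranking.

    Ties in cell value are broken by removing the lowest linear cell index
    first, which makes the ranking deterministic.
    """
    if config is None:
        config = ZonationConfig()
    if n_cells is None:
        first = next(iter(ranges.values()), None)
        if first is None or not hasattr(first, "grid"):
            raise ValueError("pass n_cells when ranges are raw index arrays")
        n_cells = first.grid.n_cells
    occ, ids = _presence_matrix(ranges, n_cells)
    w = weights.reindex(ids)
    if w.isna().any():
        raise WeightingError("every species needs a weight")
    if (w <= 0).any():
        raise WeightingError("weights must be positive")
    w = w.to_numpy(dtype=float)

    protected = (
        np.zeros(n_cells, dtype=bool)
        if protected_mask is None
        else np.asarray(protected_mask, dtype=bool).ravel()
    )
    if protected.size != n_cells:
        raise AlignmentError("protected mask does not match the grid size")
    unprot = ~protected
    n_rank = int(unprot.sum())
    if n_rank == 0:
        raise NothingToRankError("all cells are protected; nothing to rank")

    occ_u = occ[:, :]  # keep full width; operate through alive mask
    if config.include_protected_in_denominator:
        # protected cells stay in the denominator (they are never removed)
        denom_base = occ.sum(axis=1).astype(float)
    else:
        denom_base = occ[:, unprot].sum(axis=1).astype(float)
    active = occ[:, unprot].sum(axis=1) > 0
    if not active.any():
        raise NothingToRankError("no species has unprotected range cells")

    alive = unprot.copy()
    remaining = denom_base.copy()
    removal_order = np.full(n_cells, -1, dtype=np.int64)
    pos = 1
    while alive.any():
        alive_idx = np.nonzero(alive)[0]
        act = active & (remaining > 0)
        per_species = np.zeros_like(remaining)
        per_species[act] = w[act] / remaining[act]
        sub = occ_u[:, alive_idx]
        if config.value_mode == "additive":
            values = per_species @ sub
        else:  # max-benefit: best single-species contribution
            values = (per_species[:, None] * sub).max(axis=0) if sub.shape[0] else np.zeros(len(alive_idx))
        # remove the `warp` lowest-valued cells in one block, lowest value
        # first, ties broken by lowest cell index (lexsort's last key is primary)
        k = min(config.warp, len(alive_idx))
        order = np.lexsort((alive_idx, values))[:k]
        for j in order:
            cell = alive_idx[j]
            removal_order[cell] = pos
            pos += 1
            alive[cell] = False
            remaining -= occ_u[:, cell]
    rank = np.full(n_cells, np.nan)
    if n_rank == 1:
        rank[unprot] = 1.0
    else:
        rank[unprot] = (removal_order[unprot] - 1) / (n_rank - 1)
    return RankMap(rank=rank, removal_order=removal_order, protected_mask=protected)


@dataclass
class DeltaRankMap:
    delta: np.ndarray  # rank_after - rank_before; NaN on protected cells
    protected_mask: np.ndarray


def delta_rank(rank_before: RankMap, rank_after: RankMap) -> DeltaRankMap:
    """Per-cell normalized-rank difference between two scenarios."""
    if rank_before.rank.size != rank_after.rank.size:
        raise AlignmentError("rank maps cover different grids")
    if not np.array_equal(rank_before.protected_mask, rank_after.protected_mask):
        raise AlignmentError("rank maps use different protected masks")
    delta = rank_after.rank - rank_before.rank
    delta[rank_before.protected_mask] = np.nan
    return DeltaRankMap(delta=delta, protected_mask=rank_before.protected_mask.copy())
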