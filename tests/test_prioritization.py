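"""Weight schemes, the greedy removal ranking against a recompute-from-
scratch oracle, and scenario deltas."""

import numpy as np
import pandas as pd
import pytest

import redlist_gapfill as rg
from redlist_gapfill.prioritization import (
    AlignmentError,
    NothingToRankError,
    WeightingError,
)
from redlist_gapfill.synthetic_world import DDNE, NON_THREATENED, THREATENED


def greedy_oracle(occ, w, protected, warp=1, mode="additive"):
    """Exhaustive greedy removal, recomputing every cell value from scratch
    at each iteration from the definition of q_ij."""
    n_species, n_cells = occ.shape
    alive = [i for i in range(n_cells) if not protected[i]]
    removal = np.full(n_cells, -1)
    pos = 1
    while alive:
        values = {}
        denoms = [sum(occ[j, c] for c in alive) for j in range(n_species)]
        for i in alive:
            contribs = [
                w[j] / denoms[j] for j in range(n_species) if occ[j, i] and denoms[j] > 0
            ]
            values[i] = sum(contribs) if mode == "additive" else max(contribs, default=0.0)
        block = sorted(alive, key=lambda i: (values[i], i))[: min(warp, len(alive))]
        for c in block:
            removal[c] = pos
            pos += 1
            alive.remove(c)
    n = int((~protected).sum())
    rank = np.full(n_cells, np.nan)
    unprot = ~protected
    rank[unprot] = 1.0 if n == 1 else (removal[unprot] - 1) / (n - 1)
    return removal, rank


def as_ranges(occ):
    return {f"sp{j}": np.nonzero(occ[j])[0] for j in range(occ.shape[0])}


class TestWeights:
    def test_fixed_weights(self):
        status = pd.Series({"a": NON_THREATENED, "b": DDNE, "c": THREATENED})
        w = rg.assign_weights(status)
        assert w.tolist() == [1.0, 2.0, 6.0]

    def test_unknown_status_raises(self):
        with pytest.raises(WeightingError):
            rg.assign_weights(pd.Series({"a": "Extinct"}))

    def test_sensitivity_keeps_fixed_weights_for_evaluated_species(self):
        status = pd.Series({"a": THREATENED, "b": NON_THREATENED, "c": DDNE})
        predicted = pd.Series({"a": False, "b": False, "c": False})
        w = rg.assign_weights(status, predicted, scheme=rg.WeightScheme(mode="sensitivity"))
        assert w.tolist() == [6.0, 1.0, 2.0]

    def test_sensitivity_endpoints_for_predicted_species(self):
        status = pd.Series(
            {"t_max": THREATENED, "t_min": THREATENED, "n_max": NON_THREATENED, "n_min": NON_THREATENED, "d": DDNE}
        )
        predicted = pd.Series(True, index=status.index)
        p = pd.Series({"t_max": 1.0, "t_min": 0.8, "n_max": 0.0, "n_min": 0.2, "d": np.nan})
        w = rg.assign_weights(status, predicted, p, rg.WeightScheme(mode="sensitivity"))
        assert w["t_max"] == pytest.approx(5.0)  # full consensus Threatened
        assert w["t_min"] == pytest.approx(2.0)  # minimal admissible consensus
        assert w["n_max"] == pytest.approx(1.0)  # full consensus Non-Threatened
        assert w["n_min"] == pytest.approx(2.0)
        assert w["d"] == 2.0
        # both rescaling readings hit the stated endpoints
        w2 = rg.assign_weights(status, predicted, p, rg.WeightScheme(mode="sensitivity", rescale="rescale-sum"))
        assert w2["t_max"] == pytest.approx(5.0) and w2["t_min"] == pytest.approx(2.0)
        assert w2["n_max"] == pytest.approx(1.0) and w2["n_min"] == pytest.approx(2.0)

    def test_sensitivity_missing_p_raises(self):
        status = pd.Series({"a": THREATENED})
        predicted = pd.Series({"a": True})
        with pytest.raises(WeightingError):
            rg.assign_weights(status, predicted, None, rg.WeightScheme(mode="sensitivity"))


class TestZonationRank:
    def test_uniform_species_ties_follow_lowest_index_rule(self):
        occ = np.ones((1, 4), dtype=bool)
        rank = rg.zonation_rank(as_ranges(occ), pd.Series({"sp0": 1.0}), rg.ZonationConfig(warp=1), n_cells=4)
        assert np.allclose(rank.rank, [0.0, 1 / 3, 2 / 3, 1.0])

    def test_two_species_unequal_weights_match_oracle_on_3x3(self):
        occ = np.zeros((2, 9), dtype=bool)
        occ[0, [0, 1, 2, 4]] = True
        occ[1, [4, 5, 8]] = True
        w = pd.Series({"sp0": 1.0, "sp1": 6.0})
        protected = np.zeros(9, dtype=bool)
        rank = rg.zonation_rank(as_ranges(occ), w, rg.ZonationConfig(warp=1), protected, n_cells=9)
        removal, rk = greedy_oracle(occ, [1.0, 6.0], protected)
        assert np.array_equal(rank.removal_order, removal)
        assert np.allclose(rank.rank, rk, equal_nan=True)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_recompute_from_scratch_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows, cols = rng.integers(2, 5, size=2)
        n_cells = int(rows * cols)
        n_species = int(rng.integers(1, 4))
        occ = rng.random((n_species, n_cells)) < 0.6
        occ[:, 0] |= ~occ.any(axis=1)  # every species occupies something
        protected = rng.random(n_cells) < 0.25
        if protected.all():
            protected[0] = False
        if not occ[:, ~protected].any():
            occ[0, np.nonzero(~protected)[0][0]] = True
        w = rng.uniform(0.5, 6.0, n_species)
        warp = int(rng.integers(1, 3))
        mode = ["additive", "max_benefit"][seed % 2]
        cfg = rg.ZonationConfig(warp=warp, value_mode=mode)
        rank = rg.zonation_rank(
            as_ranges(occ), pd.Series(w, index=[f"sp{j}" for j in range(n_species)]), cfg, protected, n_cells=n_cells
        )
        removal, rk = greedy_oracle(occ, list(w), protected, warp=warp, mode=mode)
        assert np.array_equal(rank.removal_order, removal)
        assert np.allclose(rank.rank, rk, equal_nan=True)

    def test_protected_cells_are_masked_and_ranks_complete(self, rng):
        occ = rng.random((3, 16)) < 0.5
        occ[:, 0] = True
        protected = np.zeros(16, dtype=bool)
        protected[[2, 5, 11]] = True
        w = pd.Series(1.0, index=[f"sp{j}" for j in range(3)])
        rank = rg.zonation_rank(as_ranges(occ), w, rg.ZonationConfig(), protected, n_cells=16)
        assert np.isnan(rank.rank[protected]).all()
        assert (rank.removal_order[protected] == -1).all()
        got = np.sort(rank.rank[~protected])
        assert np.allclose(got, np.linspace(0, 1, 13))  # a full permutation of ranks

    def test_weight_scaling_invariance(self, rng):
        occ = rng.random((3, 12)) < 0.5
        occ[:, 0] = True
        ranges = as_ranges(occ)
        w = pd.Series([1.0, 2.0, 6.0], index=[f"sp{j}" for j in range(3)])
        r1 = rg.zonation_rank(ranges, w, rg.ZonationConfig(), n_cells=12)
        r2 = rg.zonation_rank(ranges, 7.3 * w, rg.ZonationConfig(), n_cells=12)
        assert np.array_equal(r1.removal_order, r2.removal_order)

    def test_all_protected_raises(self):
        occ = np.ones((1, 4), dtype=bool)
        with pytest.raises(NothingToRankError):
            rg.zonation_rank(as_ranges(occ), pd.Series({"sp0": 1.0}), protected_mask=np.ones(4, bool), n_cells=4)

    def test_nonpositive_weight_raises(self):
        occ = np.ones((1, 4), dtype=bool)
        with pytest.raises(WeightingError):
            rg.zonation_rank(as_ranges(occ), pd.Series({"sp0": 0.0}), n_cells=4)


class TestDeltaRank:
    def build(self, occ, w, n_cells, protected=None):
        ids = [f"sp{j}" for j in range(occ.shape[0])]
        return rg.zonation_rank(as_ranges(occ), pd.Series(w, index=ids), rg.ZonationConfig(), protected, n_cells=n_cells)

    def test_identical_scenarios_give_zero_delta(self, rng):
        occ = rng.random((2, 9)) < 0.6
        occ[:, 0] = True
        r = self.build(occ, [1.0, 2.0], 9)
        d = rg.delta_rank(r, r)
        assert np.nanmax(np.abs(d.delta)) == 0.0

    def test_antisymmetry(self, rng):
        occ = rng.random((2, 9)) < 0.6
        occ[:, 0] = True
        ra = self.build(occ, [1.0, 2.0], 9)
        rb = self.build(occ, [6.0, 1.0], 9)
        dab = rg.delta_rank(ra, rb).delta
        dba = rg.delta_rank(rb, ra).delta
        assert np.allclose(dab, -dba, equal_nan=True)

    def test_mismatched_masks_raise(self):
        occ = np.ones((1, 4), dtype=bool)
        ra = self.build(occ, [1.0], 4)
        rb = self.build(occ, [1.0], 4, protected=np.array([True, False, False, False]))
        with pytest.raises(AlignmentError):
            rg.delta_rank(ra, rb)

    def test_upweighting_a_species_does_not_demote_its_exclusive_cells(self):
        # 6x6 world: species A holds an exclusive block, species B the rest
        occ = np.zeros((2, 36), dtype=bool)
        exclusive = [0, 1, 6, 7]
        occ[0, exclusive] = True
        occ[1, 12:] = True
        before = self.build(occ, [1.0, 1.0], 36)
        after = self.build(occ, [6.0, 1.0], 36)
        d = rg.delta_rank(before, after).delta
        assert np.nanmean(d[exclusive]) >= 0.0
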