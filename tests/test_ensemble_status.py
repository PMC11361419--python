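"""Balanced subsetting, cross-validated model counts, and the strict
within-algorithm consensus rule."""

import numpy as np
import pandas as pd
import pytest

import redlist_gapfill as rg
from redlist_gapfill.ensemble_status import NO_CALL, BalanceError, consensus_call
from redlist_gapfill.synthetic_world import DDNE, NON_THREATENED, THREATENED

from conftest import model_table


def labels_of(n_t: int, n_nt: int) -> pd.Series:
    idx = [f"t{i}" for i in range(n_t)] + [f"n{i}" for i in range(n_nt)]
    return pd.Series([THREATENED] * n_t + [NON_THREATENED] * n_nt, index=idx)


def separable_table(n: int, seed: int, threshold: float = 0.4) -> pd.DataFrame:
    """Labels are a deterministic threshold on one feature; rest is noise."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(index=[f"s{i}" for i in range(n)])
    for c in rg.PREDICTORS:
        if c in ("growth_k", "max_length_cm", "depth_min_m", "depth_max_m", "trophic_level"):
            df[c] = rng.normal(size=n)
        else:
            df[c] = rng.choice(["a", "b"], size=n)
    df["family"] = rng.choice([f"F{k}" for k in range(5)], size=n)
    df["genus"] = df["family"] + "_g"
    df["observed_status"] = np.where(df["growth_k"] > threshold, THREATENED, NON_THREATENED)
    return df


TINY_RF = {"n_estimators": 15}


class TestBalancedSubsets:
    def test_single_subset(self):
        cfg = rg.EnsembleConfig(n_subsets=1, cv_folds=2)
        (subset,) = rg.make_balanced_subsets(labels_of(5, 20), cfg)
        assert len(subset) == 10

    def test_reference_composition(self):
        """24 subsets of 324 Threatened + 324 sampled Non-Threatened each."""
        labels = labels_of(324, 7750)
        cfg = rg.EnsembleConfig(n_subsets=24, cv_folds=10, seed=1)
        subsets = rg.make_balanced_subsets(labels, cfg)
        assert len(subsets) == 24
        for s in subsets:
            assert len(s) == 648
            vc = labels.loc[s].value_counts()
            assert vc[THREATENED] == 324 and vc[NON_THREATENED] == 324

    def test_exact_partition_when_counts_divide(self):
        labels = labels_of(10, 40)
        cfg = rg.EnsembleConfig(n_subsets=4, cv_folds=2, seed=2)
        subsets = rg.make_balanced_subsets(labels, cfg)
        nt_draws = [sid for s in subsets for sid in s if sid.startswith("n")]
        counts = pd.Series(nt_draws).value_counts()
        assert len(counts) == 40 and (counts == 1).all()

    def test_near_partition_before_reuse(self):
        labels = labels_of(10, 35)  # 4 subsets need 40 NT draws from 35
        cfg = rg.EnsembleConfig(n_subsets=4, cv_folds=2, seed=3)
        subsets = rg.make_balanced_subsets(labels, cfg)
        counts = pd.Series([sid for s in subsets for sid in s if sid.startswith("n")]).value_counts()
        assert counts.max() <= 2 and (counts >= 1).all()

    def test_balance_error(self):
        with pytest.raises(BalanceError):
            rg.make_balanced_subsets(labels_of(10, 5), rg.EnsembleConfig(n_subsets=1))


class TestFitEnsemble:
    def test_model_count_is_subsets_times_folds(self):
        table = separable_table(90, 4)
        cfg = rg.EnsembleConfig(n_subsets=24, cv_folds=10, learner_params={"n_estimators": 3}, seed=5)
        fit = rg.fit_ensemble(table, cfg)
        assert fit.n_models == 240

    def test_minimal_configuration_gives_two_models(self):
        table = separable_table(40, 6)
        cfg = rg.EnsembleConfig(n_subsets=1, cv_folds=2, learner_params=TINY_RF, seed=7)
        fit = rg.fit_ensemble(table, cfg)
        assert fit.n_models == 2

    def test_fold_error_when_folds_exceed_class_size(self):
        table = separable_table(12, 8)
        cfg = rg.EnsembleConfig(n_subsets=1, cv_folds=10, learner_params=TINY_RF)
        with pytest.raises(ValueError, match="cv_folds"):
            rg.fit_ensemble(table, cfg)

    @pytest.mark.parametrize("seed", range(5))
    def test_separable_labels_are_learned(self, seed):
        table = separable_table(200, 50 + seed)
        cfg = rg.EnsembleConfig(n_subsets=2, cv_folds=3, learner_params={"n_estimators": 50}, seed=seed)
        fit = rg.fit_ensemble(table, cfg)
        assert fit.metrics.accuracy >= 0.95

    def test_three_way_tally_partitions_evaluated_cases(self):
        table = separable_table(120, 9, threshold=0.5)
        cfg = rg.EnsembleConfig(n_subsets=3, cv_folds=3, learner_params=TINY_RF, seed=10)
        fit = rg.fit_ensemble(table, cfg)
        m = fit.metrics
        assert m.true_positive_pct + m.false_positive_pct + m.false_negative_pct == pytest.approx(100.0)


class TestConsensus:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (1.0, THREATENED),
            (0.8, NO_CALL),  # strictly-greater-than rule at the boundary
            (200 / 240, THREATENED),  # 0.8333 > 0.8
            (0.0, NON_THREATENED),
            (0.5, NO_CALL),
            (1 - 0.8, NO_CALL),
        ],
    )
    def test_consensus_call_rule(self, p, expected):
        assert consensus_call(p, 0.8) == expected

    def test_predictions_and_missing_feature_flagging(self):
        table = separable_table(150, 11)
        ddne = separable_table(30, 12)
        ddne["observed_status"] = DDNE
        full = pd.concat([table, ddne.set_index(pd.Index([f"d{i}" for i in range(30)]))])
        cfg = rg.EnsembleConfig(n_subsets=2, cv_folds=3, learner_params={"n_estimators": 40}, seed=13)
        encoder = rg.FeatureEncoder().fit(full)
        fit = rg.fit_ensemble(full, cfg, encoder=encoder)
        unlabeled = full[full["observed_status"] == DDNE].copy()
        unlabeled.loc[unlabeled.index[:3], "growth_k"] = np.nan
        votes = rg.consensus_predict(fit, unlabeled)
        assert (votes.loc[unlabeled.index[:3], "call"] == NO_CALL).all()
        assert (votes.loc[unlabeled.index[:3], "reason"] == "missing-features").all()
        ok = votes.loc[unlabeled.index[3:]]
        assert (ok["votes_total"] == fit.n_models).all()
        # separable problem: essentially every usable species gets a call
        assert (ok["call"] != NO_CALL).mean() > 0.9
        # calls respect the vote-fraction invariant
        for _, row in ok.iterrows():
            assert row["call"] == consensus_call(row["p"], 0.8)

    def test_calls_invariant_to_model_ordering(self):
        table = separable_table(120, 14)
        ddne = separable_table(20, 15)
        ddne["observed_status"] = DDNE
        ddne.index = pd.Index([f"d{i}" for i in range(20)])
        full = pd.concat([table, ddne])
        cfg = rg.EnsembleConfig(n_subsets=2, cv_folds=2, learner_params=TINY_RF, seed=16)
        encoder = rg.FeatureEncoder().fit(full)
        fit = rg.fit_ensemble(full, cfg, encoder=encoder)
        votes1 = rg.consensus_predict(fit, ddne)
        fit.voters = list(reversed(fit.voters))
        votes2 = rg.consensus_predict(fit, ddne)
        pd.testing.assert_series_equal(votes1["call"], votes2["call"])

    def test_label_shuffled_pool_behaves_like_chance(self, signal_pool, rng):
        table = model_table(signal_pool)
        labeled = table[table["observed_status"] != DDNE].copy()
        labeled["observed_status"] = rng.permutation(labeled["observed_status"].to_numpy())
        cfg = rg.EnsembleConfig(n_subsets=4, cv_folds=3, learner_params={"n_estimators": 60}, seed=17)
        encoder = rg.FeatureEncoder().fit(table)
        fit = rg.fit_ensemble(labeled, cfg, encoder=encoder)
        assert abs(fit.metrics.accuracy - 0.5) < 0.05
        ddne = table[table["observed_status"] == DDNE]
        votes = rg.consensus_predict(fit, ddne)
        assert (votes["call"] == NO_CALL).mean() > 0.5
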