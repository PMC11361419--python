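"""Balanced down-sampled ensembles and within-algorithm consensus calls.

The labeled pool is highly imbalanced (few Threatened, many Non-Threatened
species), so B balanced subsets are formed, each containing every Threatened
species plus an equal-sized, near-disjoint sample of Non-Threatened species.
Each subset is fit with k-fold cross-validation, yielding B*k models per
algorithm (24 subsets x 10 folds = 240 in the reference configuration). Two
learner families are supported: a random-forest classifier and a one-hidden-
layer feed-forward network. Every model votes on every DDNE species; a
status is attributed only when the vote fraction p for one class strictly
exceeds the consensus threshold (p > 0.8 by default), otherwise no call is
made. Cross-validated accuracy and the three-way true-positive /
false-positive / false-negative tally are aggregated over all held-out folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .synthetic_world import CATEGORICAL_TRAITS, CONTINUOUS_TRAITS, DDNE, NON_THREATENED, THREATENED

Algorithm = Literal["tree-ensemble", "feed-forward-network"]

NO_CALL = "NoCall"


class BalanceError(ValueError):
    """Raised when the labeled pool cannot be down-sampled into balanced subsets."""


@dataclass(frozen=True)
class EnsembleConfig:
    n_subsets: int = 24
    cv_folds: int = 10
    consensus_threshold: float = 0.8
    algorithm: Algorithm = "tree-ensemble"
    learner_params: dict = field(default_factory=dict)
    refit_votes: bool = False  # alternative: B full-subset refits vote instead of all B*k fold models
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.5 < self.consensus_threshold <= 1.0:
            raise ValueError("consensus_threshold must lie in (0.5, 1]")


@dataclass
class CVMetrics:
    """Accuracy and the three-way percentage tally over held-out folds.

    true_positive is the share of held-out cases predicted correctly,
    false_positive the share of Non-Threatened predicted Threatened, and
    false_negative the share of Threatened predicted Non-Threatened; the
    three percentages partition every evaluated case.
    """

    accuracy: float
    accuracy_sd: float
    true_positive_pct: float
    true_positive_sd: float
    false_positive_pct: float
    false_positive_sd: float
    false_negative_pct: float
    false_negative_sd: float
    per_fold: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            k: round(float(getattr(self, k)), 6)
            for k in (
                "accuracy", "accuracy_sd",
                "true_positive_pct", "true_positive_sd",
                "false_positive_pct", "false_positive_sd",
                "false_negative_pct", "false_negative_sd",
            )
        }


class FeatureEncoder:
    """One-hot + standardization encoder with a frozen schema.

    Categorical predictors (and the genus/family taxonomy columns, which the
    models receive as ordinary categorical predictors) are one-hot encoded
    with levels frozen at fit time; continuous predictors are z-scored with
    fit-time moments so tree and network learners share one design matrix.
    """

    #: continuous columns that enter the design matrix on a log10 scale
    LOG_FEATURES = ("range_km2",)

    def __init__(self, categorical: list[str] | None = None, continuous: list[str] | None = None):
        self.categorical = categorical if categorical is not None else CATEGORICAL_TRAITS + ["genus", "family"]
        # range size (km², from the range builder) is a first-class predictor
        # alongside the trait block whenever the table carries it
        self.continuous = continuous if continuous is not None else list(CONTINUOUS_TRAITS) + ["range_km2"]
        self.levels_: dict[str, list] = {}
        self.means_: pd.Series | None = None
        self.sds_: pd.Series | None = None
        self.columns_: list[str] = []

    def fit(self, table: pd.DataFrame) -> "FeatureEncoder":
        self.categorical = [c for c in self.categorical if c in table.columns]
        self.continuous = [c for c in self.continuous if c in table.columns]
        for c in self.categorical:
            self.levels_[c] = sorted(table[c].dropna().astype(str).unique().tolist())
        cont = self._continuous_block(table)
        self.means_ = cont.mean()
        sds = cont.std(ddof=0)
        self.sds_ = sds.mask(sds == 0, 1.0)
        self.columns_ = list(self.continuous) + [
            f"{c}={lvl}" for c in self.categorical for lvl in self.levels_[c]
        ]
        return self

    def _continuous_block(self, table: pd.DataFrame) -> pd.DataFrame:
        cont = table[self.continuous].astype(float)
        for c in self.LOG_FEATURES:
            if c in cont.columns:
                cont[c] = np.log10(cont[c])
        return cont

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        cont = self._continuous_block(table)
        parts = [(cont - self.means_) / self.sds_]
        for c in self.categorical:
            vals = table[c].astype(object)
            block = pd.DataFrame(
                {f"{c}={lvl}": (vals == lvl).astype(float) for lvl in self.levels_[c]},
                index=table.index,
            )
            # A NaN category leaves all indicator columns 0 but must still
            # surface as "missing features" to consensus_predict.
            block.loc[vals.isna()] = np.nan
            parts.append(block)
        return pd.concat(parts, axis=1)[self.columns_]

    def feature_groups(self) -> dict[str, list[str]]:
        """Map each original predictor to its design-matrix columns."""
        groups = {c: [c] for c in self.continuous}
        for c in self.categorical:
            groups[c] = [f"{c}={lvl}" for lvl in self.levels_[c]]
        return groups


@dataclass
class EnsembleFit:
    config: EnsembleConfig
    encoder: FeatureEncoder
    models: list
    voters: list
    metrics: CVMetrics

    @property
    def n_models(self) -> int:
        return len(self.models)


def make_balanced_subsets(
    labels: pd.Series, config: EnsembleConfig, rng: np.random.Generator | None = None
) -> list[pd.Index]:
    """Form B balanced subsets: all Threatened plus equal-size NT samples.

    Non-Threatened species are drawn from successive shuffled permutations,
    so coverage is maximized (each NT species appears once before any is
    reused; with n_NT = B*n_T the samples form an exact partition).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t_ids = labels.index[labels == THREATENED]
    nt_ids = labels.index[labels == NON_THREATENED]
    n_t, n_nt = len(t_ids), len(nt_ids)
    if n_t < 1:
        raise BalanceError("no Threatened species in the labeled pool")
    if n_nt < n_t:
        raise BalanceError(f"need at least {n_t} Non-Threatened species, have {n_nt}")
    needed = config.n_subsets * n_t
    draw_order: list = []
    while len(draw_order) < needed:
        draw_order.extend(nt_ids[rng.permutation(n_nt)])
    subsets = []
    for b in range(config.n_subsets):
        nt_sample = pd.Index(draw_order[b * n_t : (b + 1) * n_t])
        subsets.append(t_ids.append(nt_sample))
    return subsets


def _make_learner(config: EnsembleConfig, seed: int):
    params = dict(config.learner_params)
    if config.algorithm == "tree-ensemble":
        params.setdefault("n_estimators", 500)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if config.algorithm == "feed-forward-network":
        # one hidden layer, rectified units, patient early stopping — sized
        # for the few-hundred-row balanced subsets this pipeline produces
        params.setdefault("hidden_layer_sizes", (32,))
        params.setdefault("activation", "relu")
        params.setdefault("early_stopping", True)
        params.setdefault("validation_fraction", 0.2)
        params.setdefault("n_iter_no_change", 40)
        params.setdefault("learning_rate_init", 0.01)
        params.setdefault("max_iter", 1000)
        return MLPClassifier(random_state=seed, **params)
    raise ValueError(f"unknown algorithm {config.algorithm!r}")


def fit_ensemble(
    table: pd.DataFrame,
    config: EnsembleConfig,
    encoder: FeatureEncoder | None = None,
    label_col: str = "observed_status",
) -> EnsembleFit:
    """Fit B*k cross-validated models on balanced subsets of the labeled pool.

    ``table`` holds the completed predictor block plus taxonomy and the
    status column; only Threatened / Non-Threatened rows are used for
    training (DDNE rows may be present and are ignored here, but should be
    included when fitting the ``encoder`` so prediction-time categories are
    known). Returns the fitted models, the voter set (all B*k fold models,
    or B full-subset refits when ``config.refit_votes``), and cross-validated
    metrics aggregated over every held-out fold.
    """
    ss = np.random.SeedSequence(config.seed)
    subset_rng = np.random.default_rng(ss.spawn(1)[0])
    if encoder is None:
        encoder = FeatureEncoder().fit(table)
    labels = table[label_col]
    labeled = table.loc[labels.isin([THREATENED, NON_THREATENED])]
    X_all = encoder.transform(labeled)
    # Rows with unresolved (ungated) trait gaps cannot inform the models;
    # they are left out of training, mirroring the NoCall rule at prediction.
    complete = ~X_all.isna().any(axis=1)
    labeled, X_all = labeled.loc[complete], X_all.loc[complete]
    subsets = make_balanced_subsets(labeled[label_col], config, rng=subset_rng)
    y_all = labeled[label_col]

    models: list = []
    refits: list = []
    fold_rows = []
    model_seeds = np.random.default_rng(ss.spawn(1)[0]).integers(2**31, size=config.n_subsets * (config.cv_folds + 1))
    si = 0
    for b, subset in enumerate(subsets):
        X_sub, y_sub = X_all.loc[subset], y_all.loc[subset]
        min_class = y_sub.value_counts().min()
        if config.cv_folds > min_class:
            raise ValueError(
                f"cv_folds={config.cv_folds} exceeds the smallest class count {min_class} in subset {b}"
            )
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=int(model_seeds[si]) % 2**31)
        si += 1
        for train_pos, test_pos in skf.split(X_sub, y_sub):
            model = _make_learner(config, seed=int(model_seeds[si]))
            si += 1
            model.fit(X_sub.iloc[train_pos], y_sub.iloc[train_pos])
            models.append(model)
            pred = model.predict(X_sub.iloc[test_pos])
            truth = y_sub.iloc[test_pos].to_numpy()
            n = len(truth)
            tp = float(np.mean(pred == truth))
            fp = float(np.mean((truth == NON_THREATENED) & (pred == THREATENED)))
            fn = float(np.mean((truth == THREATENED) & (pred == NON_THREATENED)))
            fold_rows.append({"subset": b, "n": n, "accuracy": tp, "tp": tp, "fp": fp, "fn": fn})
        if config.refit_votes:
            model = _make_learner(config, seed=int(model_seeds[(b + 1) * (config.cv_folds + 1) - 1]))
            model.fit(X_sub, y_sub)
            refits.append(model)
    per_fold = pd.DataFrame(fold_rows)
    metrics = CVMetrics(
        accuracy=float(per_fold["accuracy"].mean()),
        accuracy_sd=float(per_fold["accuracy"].std(ddof=1)) if len(per_fold) > 1 else 0.0,
        true_positive_pct=float(per_fold["tp"].mean() * 100),
        true_positive_sd=float(per_fold["tp"].std(ddof=1) * 100) if len(per_fold) > 1 else 0.0,
        false_positive_pct=float(per_fold["fp"].mean() * 100),
        false_positive_sd=float(per_fold["fp"].std(ddof=1) * 100) if len(per_fold) > 1 else 0.0,
        false_negative_pct=float(per_fold["fn"].mean() * 100),
        false_negative_sd=float(per_fold["fn"].std(ddof=1) * 100) if len(per_fold) > 1 else 0.0,
        per_fold=per_fold,
    )
    voters = refits if config.refit_votes else models
    return EnsembleFit(config=config, encoder=encoder, models=models, voters=voters, metrics=metrics)


def consensus_call(p: float, tau: float) -> str:
    """Vote fraction -> call: strictly more than tau of the votes must agree."""
    if p > tau:
        return THREATENED
    if (1.0 - p) > tau:
        return NON_THREATENED
    return NO_CALL


def consensus_predict(
    fit: EnsembleFit,
    unlabeled: pd.DataFrame,
    tau: float | None = None,
) -> pd.DataFrame:
    """Vote every model over the DDNE species and apply the consensus rule.

    Returns a VoteTable frame indexed by species id with columns
    ``algorithm, votes_threatened, votes_total, p, call, reason``. Species
    with missing features after gating receive NoCall with reason
    ``missing-features``; otherwise ``call`` follows the strict consensus
    rule (Threatened iff p > tau; Non-Threatened iff 1 − p > tau; else
    NoCall).
    """
    if tau is None:
        tau = fit.config.consensus_threshold
    X = fit.encoder.transform(unlabeled)
    usable = ~X.isna().any(axis=1)
    out = pd.DataFrame(index=unlabeled.index)
    out["algorithm"] = fit.config.algorithm
    out["votes_threatened"] = 0
    out["votes_total"] = 0
    out["p"] = np.nan
    out["call"] = NO_CALL
    out["reason"] = np.where(usable, "", "missing-features")
    if usable.any():
        Xu = X.loc[usable]
        votes = np.zeros(len(Xu), dtype=int)
        for model in fit.voters:
            votes += (model.predict(Xu) == THREATENED).astype(int)
        total = len(fit.voters)
        p = votes / total
        out.loc[usable, "votes_threatened"] = votes
        out.loc[usable, "votes_total"] = total
        out.loc[usable, "p"] = p
        out.loc[usable, "call"] = [consensus_call(v, tau) for v in p]
    out.index.name = "species_id"
    return out


def classify_pool(
    table: pd.DataFrame,
    config_rf: EnsembleConfig,
    config_ann: EnsembleConfig | None = None,
    label_col: str = "observed_status",
) -> tuple[dict[str, EnsembleFit], dict[str, pd.DataFrame]]:
    """Fit both algorithms on the labeled part of ``table`` and vote on its
    DDNE part. Returns fits and vote tables keyed by algorithm name."""
    encoder = FeatureEncoder().fit(table)
    ddne = table.loc[table[label_col] == DDNE]
    configs = {"tree-ensemble": config_rf}
    if config_ann is not None:
        configs["feed-forward-network"] = config_ann
    fits, votes = {}, {}
    for name, cfg in configs.items():
        fit = fit_ensemble(table, cfg, encoder=encoder, label_col=label_col)
        fits[name] = fit
        votes[name] = consensus_predict(fit, ddne)
    return fits, votes
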