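"""Performance-gated iterative trait imputation.

Deep learners cannot handle missing predictor values, so gaps in the
12-predictor trait block are filled with an iterative tree-ensemble imputer
(the missForest recipe: initialize missing entries, then repeatedly regress
or classify each incomplete trait on all others until the imputations
stabilize). Imputation quality is first measured per trait on a holdout of
the complete cases — the imputer is trained on 80% of the complete data and
scored on the remaining 20% — and only traits whose holdout performance
strictly exceeds the gate (R² > 0.6 for continuous traits, accuracy > 0.6
for categorical ones) are actually imputed; the rest keep their gaps.
Species with too many unresolved predictor gaps are excluded from the
predictive framework and flagged "unpredictable".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import accuracy_score, r2_score

from .synthetic_world import CATEGORICAL_TRAITS, CONTINUOUS_TRAITS, PREDICTORS

GATE_THRESHOLD = 0.6  # strict: performance must EXCEED this to impute
MAX_MISSING_FIELDS = 6  # of the 12 predictors


@dataclass
class ImputationReport:
    """Per-trait holdout performance and gate decision.

    ``table`` has one row per trait with columns ``task``
    (regression|classification), ``performance`` (R² or accuracy; NaN when
    un-evaluable), ``evaluable`` and ``gate`` (imputed|left-missing).
    """

    table: pd.DataFrame
    threshold: float
    holdout_fraction: float

    def gated_traits(self) -> list[str]:
        return list(self.table.index[self.table["gate"] == "imputed"])


def _trait_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in PREDICTORS if c in table.columns]


def _design_matrix(table: pd.DataFrame, feature_cols: list[str]) -> pd.DataFrame:
    """Numeric design matrix: continuous traits as-is, categorical one-hot."""
    parts = []
    for c in feature_cols:
        if c in CONTINUOUS_TRAITS:
            parts.append(table[[c]].astype(float))
        else:
            parts.append(pd.get_dummies(table[c].astype(object), prefix=c, dtype=float))
    return pd.concat(parts, axis=1)


def _fit_predict_trait(
    train: pd.DataFrame,
    test: pd.DataFrame,
    target: str,
    features: list[str],
    seed: int,
    n_estimators: int,
):
    """Fit a per-trait random forest on ``train`` and predict ``target`` on
    ``test``; both frames must be complete in ``features``."""
    X_all = _design_matrix(pd.concat([train, test]), features)
    X_train, X_test = X_all.iloc[: len(train)], X_all.iloc[len(train):]
    if target in CONTINUOUS_TRAITS:
        model = RandomForestRegressor(n_estimators=n_estimators, random_state=seed, n_jobs=1)
        model.fit(X_train, train[target].astype(float))
        return model.predict(X_test)
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    model.fit(X_train, train[target].astype(str))
    return model.predict(X_test)


def evaluate_imputer(
    table: pd.DataFrame,
    holdout_fraction: float = 0.2,
    seed: int = 0,
    threshold: float = GATE_THRESHOLD,
    n_estimators: int = 100,
) -> ImputationReport:
    """Measure per-trait imputation quality on a holdout of complete cases.

    Complete rows (no gap in any predictor) are split into a training part
    (1 − holdout_fraction) and a testing part; for each trait, a forest
    trained to predict that trait from the other predictors on the training
    part is scored on the testing part (R² for continuous, accuracy for
    categorical). Traits that cannot be evaluated (entirely missing, or no
    complete rows) are reported un-evaluable and left missing.
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must lie in (0, 1)")
    traits = _trait_columns(table)
    if len(traits) < 2:
        raise ValueError("need at least 2 traits to evaluate imputation")
    rng = np.random.default_rng(seed)
    complete = table[traits].notna().all(axis=1)
    complete_rows = table.loc[complete, traits]
    rows = []
    n_test = int(round(holdout_fraction * len(complete_rows)))
    if len(complete_rows) >= 2 and n_test >= 1:
        order = rng.permutation(len(complete_rows))
        test_idx = complete_rows.index[order[:n_test]]
        train_idx = complete_rows.index[order[n_test:]]
        train, test = complete_rows.loc[train_idx], complete_rows.loc[test_idx]
    else:
        train = test = None
    for trait in traits:
        task = "regression" if trait in CONTINUOUS_TRAITS else "classification"
        if table[trait].isna().all() or train is None or len(train) == 0:
            rows.append((trait, task, np.nan, False))
            continue
        features = [t for t in traits if t != trait]
        pred = _fit_predict_trait(
            train, test, trait, features, seed=int(rng.integers(2**31)), n_estimators=n_estimators
        )
        if task == "regression":
            truth = test[trait].astype(float).to_numpy()
            perf = r2_score(truth, pred) if len(truth) >= 2 and truth.std() > 0 else float(
                np.allclose(truth, pred)
            )
        else:
            perf = accuracy_score(test[trait].astype(str), pred)
        rows.append((trait, task, float(perf), True))
    rep = pd.DataFrame(rows, columns=["trait", "task", "performance", "evaluable"]).set_index("trait")
    rep["gate"] = np.where(
        rep["evaluable"] & (rep["performance"] > threshold), "imputed", "left-missing"
    )
    return ImputationReport(table=rep, threshold=threshold, holdout_fraction=holdout_fraction)


def impute(
    table: pd.DataFrame,
    report: ImputationReport,
    threshold: float | None = None,
    max_missing_fields: int = MAX_MISSING_FIELDS,
    seed: int = 0,
    max_iter: int = 10,
    tol: float = 1e-3,
    n_estimators: int = 100,
) -> tuple[pd.DataFrame, list[str]]:
    """Fill gated traits in ``table``; exclude species with too many gaps.

    Species with more than ``max_missing_fields`` missing predictors are
    dropped from the returned table (they are "unpredictable" and keep their
    DDNE status downstream). Gated traits (holdout performance strictly
    above ``threshold``) are filled by the iterative forest loop: missing
    entries start at the column mean/mode, then each incomplete gated trait
    is re-predicted from all other predictors until the imputed values change
    by less than ``tol`` (normalized squared change for continuous, fraction
    of flipped labels for categorical) or ``max_iter`` sweeps pass. Observed
    values are never altered; ungated traits keep their gaps.

    Returns the completed table (original non-trait columns preserved) and
    the list of excluded species ids.
    """
    if threshold is None:
        threshold = report.threshold
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    traits = _trait_columns(table)
    rng = np.random.default_rng(seed)

    n_missing = table[traits].isna().sum(axis=1)
    excluded = list(table.index[n_missing > max_missing_fields].astype(str))
    work = table.loc[n_missing <= max_missing_fields].copy()

    rep = report.table
    gated = [
        t
        for t in traits
        if t in rep.index and bool(rep.loc[t, "evaluable"]) and rep.loc[t, "performance"] > threshold
    ]
    miss = {t: work[t].isna() for t in gated if work[t].isna().any()}
    if not miss or len(work) == 0:
        return work, excluded

    # Mean/mode initialization of the gated gaps only.
    filled = work.copy()
    for t in miss:
        if t in CONTINUOUS_TRAITS:
            filled[t] = filled[t].astype(float).fillna(filled[t].astype(float).mean())
        else:
            mode = filled[t].mode(dropna=True)
            filled[t] = filled[t].fillna(mode.iloc[0] if len(mode) else "unknown")
    # Ungated gaps would poison the design matrix; patch them with neutral
    # fill values for prediction only (they stay missing in the output).
    ungated_miss = {
        t: work[t].isna() for t in traits if t not in gated and work[t].isna().any()
    }
    for t in ungated_miss:
        if t in CONTINUOUS_TRAITS:
            filled[t] = filled[t].astype(float).fillna(filled[t].astype(float).mean())
        else:
            mode = filled[t].mode(dropna=True)
            filled[t] = filled[t].fillna(mode.iloc[0] if len(mode) else "unknown")

    order = sorted(miss, key=lambda t: int(miss[t].sum()))  # least-missing first
    for _ in range(max_iter):
        max_change = 0.0
        for t in order:
            m = miss[t]
            obs_rows, mis_rows = filled.loc[~m], filled.loc[m]
            features = [c for c in traits if c != t]
            pred = _fit_predict_trait(
                obs_rows, mis_rows, t, features,
                seed=int(rng.integers(2**31)), n_estimators=n_estimators,
            )
            if t in CONTINUOUS_TRAITS:
                old = filled.loc[m, t].astype(float).to_numpy()
                denom = float(np.sum(np.square(pred))) or 1.0
                change = float(np.sum(np.square(pred - old))) / denom
                filled.loc[m, t] = pred
            else:
                old = filled.loc[m, t].astype(str).to_numpy()
                change = float(np.mean(old != pred.astype(str)))
                filled.loc[m, t] = pred
            max_change = max(max_change, change)
        if max_change < tol:
            break

    out = work.copy()
    for t in miss:
        out.loc[miss[t], t] = filled.loc[miss[t], t]
    return out, excluded
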