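"""Model explainability and phylogenetic signal of status.

Three diagnostics accompany the classifier: (i) relative feature importance,
averaged over all tree-ensemble models and normalized to percent (one-hot
indicator columns are folded back into their source predictor); (ii) partial
dependence of the predicted threat probability on a single predictor,
averaged over the data distribution and over models; and (iii) the D
statistic for a binary trait on a rooted phylogeny — a permutation /
Brownian-threshold normalized sum of sister-clade differences that is ~1
when the trait is randomly distributed over the tips and ~0 when it is
phylogenetically clumped (Brownian-like). When several candidate trees are
supplied, D is reported per tree and as mean ± SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .synthetic_world import THREATENED


class SchemaError(ValueError):
    """Raised when model feature schemas are inconsistent or a feature is unknown."""


@dataclass
class ImportanceProfile:
    """Per-predictor relative importance in percent (sums to 100)."""

    percent: pd.Series

    def top(self, k: int = 4) -> pd.Series:
        return self.percent.sort_values(ascending=False).head(k)


@dataclass
class PartialCurve:
    feature: str
    grid: np.ndarray
    mean_probability: np.ndarray  # P(Threatened) at each grid value


@dataclass
class DResult:
    d: float
    n_perm: int
    per_tree: list[float] = field(default_factory=list)
    mean: float = float("nan")
    sd: float = float("nan")


def _schema_of(model) -> tuple:
    names = getattr(model, "feature_names_in_", None)
    return tuple(names) if names is not None else (getattr(model, "n_features_in_", None),)


def relative_importance(models: list, feature_groups: dict[str, list[str]] | None = None) -> ImportanceProfile:
    """Average tree-ensemble importances over models, normalized to percent.

    ``feature_groups`` (e.g., from ``FeatureEncoder.feature_groups``) maps a
    predictor to its design-matrix columns so one-hot indicator importances
    are summed back into their source predictor.
    """
    if not models:
        raise ValueError("need at least one fitted tree-ensemble model")
    schema = _schema_of(models[0])
    total = None
    for m in models:
        if _schema_of(m) != schema:
            raise SchemaError("models were fitted on different feature schemas")
        imp = np.asarray(m.feature_importances_, dtype=float)
        total = imp if total is None else total + imp
    mean_imp = pd.Series(total / len(models), index=list(schema))
    if feature_groups is not None:
        mean_imp = pd.Series(
            {feat: mean_imp.reindex(cols).fillna(0.0).sum() for feat, cols in feature_groups.items()}
        )
    s = mean_imp.sum()
    if s <= 0:
        raise ValueError("all importances are zero")
    return ImportanceProfile(percent=100.0 * mean_imp / s)


def _prob_threatened(model, X: pd.DataFrame) -> np.ndarray:
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    return proba[:, classes.index(THREATENED)]


def partial_dependence(
    models: list,
    X: pd.DataFrame,
    feature: str,
    n_grid: int = 50,
    grid: np.ndarray | None = None,
) -> PartialCurve:
    """Standard partial dependence of P(Threatened) on one design column.

    The feature is swept over ``grid`` (default: ``n_grid`` evenly spaced
    values across its observed span) while every other column keeps its
    observed joint distribution; predictions are averaged over rows and
    over models.
    """
    if feature not in X.columns:
        raise SchemaError(f"unknown feature {feature!r}")
    if grid is None:
        lo, hi = float(X[feature].min()), float(X[feature].max())
        grid = np.linspace(lo, hi, n_grid)
    means = np.empty(len(grid))
    Xw = X.copy()
    for i, v in enumerate(grid):
        Xw[feature] = v
        means[i] = float(np.mean([_prob_threatened(m, Xw).mean() for m in models]))
    return PartialCurve(feature=feature, grid=np.asarray(grid, dtype=float), mean_probability=means)


# ------------------------------------------------------------ D statistic

class _TreeArrays:
    """Flattened rooted tree for fast repeated trait sums.

    Value slots 0..n_tips-1 hold tip states; internal nodes (postorder)
    average their children. Sum-of-sister-differences for a tip-value vector
    is then a single postorder sweep.
    """

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        self.tip_labels = [t.taxon.label for t in tips]
        self.n_tips = len(tips)
        slot = {id(nd): i for i, nd in enumerate(tips)}
        self.internal_children: list[np.ndarray] = []
        for nd in nodes:
            if nd.is_leaf():
                continue
            slot[id(nd)] = self.n_tips + len(self.internal_children)
            self.internal_children.append(
                np.array([slot[id(ch)] for ch in nd.child_nodes()], dtype=np.int64)
            )
        # Preorder parent/edge arrays for Brownian simulation.
        pre = list(tree.preorder_node_iter())
        self.pre_slots = np.array([slot[id(nd)] for nd in pre], dtype=np.int64)
        self.pre_parent = np.array(
            [slot[id(nd.parent_node)] if nd.parent_node is not None else -1 for nd in pre],
            dtype=np.int64,
        )
        self.pre_elen = np.array(
            [nd.edge.length if nd.edge.length and nd.edge.length > 0 else 1.0 for nd in pre],
            dtype=float,
        )
        self.n_nodes = self.n_tips + len(self.internal_children)

    def sister_diff_sum(self, tip_values: np.ndarray) -> float:
        vals = np.empty(self.n_nodes)
        vals[: self.n_tips] = tip_values
        total = 0.0
        i = self.n_tips
        for children in self.internal_children:
            cv = vals[children]
            m = cv.mean()
            vals[i] = m
            total += float(np.abs(cv - m).sum())
            i += 1
        return total

    def brownian_tips(self, rng: np.random.Generator) -> np.ndarray:
        vals = np.zeros(self.n_nodes)
        incr = rng.normal(0.0, np.sqrt(self.pre_elen))
        for k in range(len(self.pre_slots)):
            s, p = self.pre_slots[k], self.pre_parent[k]
            vals[s] = incr[k] + (vals[p] if p >= 0 else 0.0)
        return vals[: self.n_tips]


def _coerce_trait(trait, labels: list[str]) -> np.ndarray:
    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    missing = [lab for lab in labels if lab not in trait]
    if missing:
        raise SchemaError(f"trait missing for tips {missing[:5]}{'...' if len(missing) > 5 else ''}")
    values = np.array([float(trait[lab]) for lab in labels])
    if not set(np.unique(values)) <= {0.0, 1.0}:
        raise ValueError("trait must be binary (0/1)")
    return values


def phylo_D(
    tree: dendropy.Tree,
    trait,
    n_perm: int = 1000,
    seed: int = 0,
) -> DResult:
    """Phylogenetic signal D for a binary trait on a rooted tree.

    D = (Sd_obs − mean Sd_Brownian) / (mean Sd_random − mean Sd_Brownian),
    where Sd is the sum over internal nodes of the absolute sister-clade
    differences of the (estimated) trait value. The random null permutes
    tip labels; the Brownian null simulates Brownian motion along branches
    and thresholds the tip values so the simulated prevalence matches the
    observed one. Both nulls use ``n_perm`` draws.
    """
    ta = _TreeArrays(tree)
    values = _coerce_trait(trait, ta.tip_labels)
    k = int(values.sum())
    if k == 0 or k == ta.n_tips:
        raise ValueError("trait is constant across tips; D is undefined")
    rng = np.random.default_rng(seed)
    d_obs = ta.sister_diff_sum(values)
    d_rand = np.empty(n_perm)
    d_brown = np.empty(n_perm)
    for i in range(n_perm):
        d_rand[i] = ta.sister_diff_sum(rng.permutation(values))
        bm = ta.brownian_tips(rng)
        thresh = np.zeros(ta.n_tips)
        thresh[np.argsort(bm)[-k:]] = 1.0  # top-k tips -> state 1, matching prevalence
        d_brown[i] = ta.sister_diff_sum(thresh)
    denom = d_rand.mean() - d_brown.mean()
    d = (d_obs - d_brown.mean()) / denom if denom != 0 else float("nan")
    return DResult(d=float(d), n_perm=n_perm)


def phylo_D_trees(
    trees: list[dendropy.Tree] | dendropy.TreeList,
    trait,
    n_perm: int = 1000,
    seed: int = 0,
) -> DResult:
    """D over a set of candidate trees: per-tree values plus mean ± SD."""
    rng = np.random.default_rng(seed)
    per_tree = [
        phylo_D(t, trait, n_perm=n_perm, seed=int(rng.integers(2**31))).d for t in trees
    ]
    arr = np.asarray(per_tree)
    return DResult(
        d=float(arr.mean()),
        n_perm=n_perm,
        per_tree=[float(v) for v in per_tree],
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
    )


def load_trees(path) -> dendropy.TreeList:
    return dendropy.TreeList.get(path=str(path), schema="newick")
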