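"""Random-forest feature importance for positive-versus-negative calls.

SNPs labeled by the scoring model (positive: score > 0.5; negative:
score < 0.5; exactly 0.5 excluded) are fed to a random forest on their
binary feature vectors. Per-feature importance is the Mean Decrease Gini
(MDG): the average over trees of the total node-count-weighted decrease in
Gini impurity at splits on that feature. Empirical p-values come from
refitting under label permutations, and category-level enrichment of
significant features uses the upper-tail hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.ensemble import RandomForestClassifier

from .evaluate import PredictionRecord
from .features import BlockFeatureMatrix
from .util import rng_from

DEFAULT_N_TREES = 500
DEFAULT_N_PERM = 1000
SIGNIFICANCE_LEVEL = 0.05


@dataclass
class ForestConfig:
    n_trees: int = DEFAULT_N_TREES
    max_features: str | int = "sqrt"
    seed: int = 0


@dataclass
class CategorySpec:
    """A named feature category (e.g. neural, immune) for enrichment tests."""

    name: str
    members: set[str] = field(default_factory=set)


def label_snps_for_importance(
    records: list[PredictionRecord],
    blocks: list[BlockFeatureMatrix],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(X, y, feature_ids): one row per scored SNP, label by 0.5 threshold.

    SNPs scoring exactly 0.5 are excluded (neither positive nor negative).
    """
    columns: dict[tuple[str, str], np.ndarray] = {}
    feature_ids: list[str] | None = None
    for blk in blocks:
        if feature_ids is None:
            feature_ids = list(blk.feature_ids)
        for j, snp_id in enumerate(blk.snp_ids):
            columns[(blk.block_id, snp_id)] = blk.X[:, j]
    rows, labels = [], []
    for rec in records:
        if rec.score == 0.5:
            continue
        col = columns.get((rec.block_id, rec.snp_id))
        if col is None:
            continue
        rows.append(col)
        labels.append(1 if rec.score > 0.5 else 0)
    if not rows:
        raise ValueError("no scored SNPs to label")
    y = np.array(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("importance analysis needs both positive and negative calls")
    return np.array(rows, dtype=float), y, feature_ids or []


def _fit_forest(X: np.ndarray, y: np.ndarray, config: ForestConfig, seed: int):
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        max_features=config.max_features,
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def _forest_mdg(forest, n_features: int) -> np.ndarray:
    """Average over trees of the total weighted Gini decrease per feature.

    Computed from tree internals on the raw node-sample-count scale (the
    classical MDG), rather than the normalized importances the estimator
    exposes.
    """
    total = np.zeros(n_features)
    for est in forest.estimators_:
        t = est.tree_
        decrease = np.zeros(n_features)
        for node in range(t.node_count):
            left, right = t.children_left[node], t.children_right[node]
            if left == -1:  # leaf
                continue
            w = t.weighted_n_node_samples
            drop = (
                w[node] * t.impurity[node]
                - w[left] * t.impurity[left]
                - w[right] * t.impurity[right]
            )
            decrease[t.feature[node]] += drop
        total += decrease
    return total / len(forest.estimators_)


def mdg_importance(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    config: ForestConfig | None = None,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-feature MDG table (feature_id, group, mdg)."""
    config = config or ForestConfig()
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need at least two samples in each class")
    forest = _fit_forest(X, y, config, config.seed)
    mdg = _forest_mdg(forest, X.shape[1])
    groups = groups or {}
    return pd.DataFrame(
        {
            "feature_id": feature_ids,
            "group": [groups.get(f, "") for f in feature_ids],
            "mdg": mdg,
        }
    )


def mdg_permutation_pvalue(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    config: ForestConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical per-feature p-values by refitting under label permutations.

    perm_p = (1 + #{null MDG >= observed}) / (n_perm + 1); the add-one
    estimator keeps p strictly positive.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    config = config or ForestConfig()
    forest = _fit_forest(X, y, config, config.seed)
    observed = _forest_mdg(forest, X.shape[1])
    rng = rng_from(config.seed)
    exceed = np.zeros(X.shape[1], dtype=int)
    for i in range(n_perm):
        y_null = rng.permutation(y)
        null_forest = _fit_forest(X, y_null, config, seed=(config.seed + 1 + i) % (2**31 - 1))
        exceed += _forest_mdg(null_forest, X.shape[1]) >= observed
    perm_p = (1 + exceed) / (n_perm + 1)
    return observed, perm_p


def importance_table(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    n_perm: int = DEFAULT_N_PERM,
    config: ForestConfig | None = None,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Full importance report: mdg, perm_p, significance at p < 0.05."""
    mdg, perm_p = mdg_permutation_pvalue(X, y, n_perm=n_perm, config=config)
    groups = groups or {}
    return pd.DataFrame(
        {
            "feature_id": feature_ids,
            "group": [groups.get(f, "") for f in feature_ids],
            "mdg": mdg,
            "perm_p": perm_p,
            "significant": perm_p < SIGNIFICANCE_LEVEL,
        }
    )


def category_enrichment(
    significant: set[str],
    category: CategorySpec,
    catalog: list[str],
) -> float:
    """Upper-tail hypergeometric P(X >= k).

    Population = retained catalog (N), successes = category members in the
    catalog (K), draws = significant features (n), observed = overlap (k).
    """
    catalog_set = set(catalog)
    members = category.members & catalog_set
    if not members:
        raise ValueError(f"category {category.name!r} shares no feature with the catalog")
    N = len(catalog_set)
    K = len(members)
    draws = significant & catalog_set
    n = len(draws)
    k = len(draws & members)
    return float(hypergeom.sf(k - 1, N, K, n))
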