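"""Feature partitioning and classifier-based prioritization.

Features (genes and metabolites, already z-score standardized) are points in
sample space.  A k-means pass first splits them into a few crude expression-
profile clusters so that, when a random forest subsequently ranks features by
their power to classify samples as control vs treatment, features from one
profile cannot crowd out equally informative features from another.  Within
each cluster the forest's mean decrease in Gini impurity gives the ranking,
and the top-N features form that cluster's prioritized panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier

from .matrix_io import CONTROL, TREATMENT, FeatureMatrix

DEFAULT_K = 3
DEFAULT_N_RESTARTS = 50
DEFAULT_N_TREES = 10_000
DEFAULT_TOP_N = 29


@dataclass
class ClusterModel:
    k: int
    assignment: pd.Series  # feature id -> cluster index in 1..k
    centroids: np.ndarray  # k x n_samples
    inertia: float
    seed: int
    n_restarts: int

    def members(self, cluster_index: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster_index])

    def sizes(self) -> dict[int, int]:
        return {i: int((self.assignment == i).sum()) for i in range(1, self.k + 1)}


@dataclass
class ImportancePanel:
    """Per-cluster feature ranking by mean decrease in Gini impurity."""

    cluster_index: int
    entries: pd.DataFrame  # columns: feature_id, importance, rank
    n_trees: int
    seed: int
    out_of_bag_accuracy: float


def kmeans_partition(
    m: FeatureMatrix,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = DEFAULT_N_RESTARTS,
) -> ClusterModel:
    """Best-of-``n_restarts`` k-means (k-means++ seeding, Euclidean distance)
    over the standardized feature rows.  Deterministic given the seed."""
    n_features = m.shape[0]
    if k > n_features:
        raise ValueError(f"k={k} exceeds the {n_features} available features")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(m.values.to_numpy())
    assignment = pd.Series(labels + 1, index=m.values.index)
    return ClusterModel(
        k=k,
        assignment=assignment,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        seed=seed,
        n_restarts=n_restarts,
    )


def pca_project(m: FeatureMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Project features onto the leading principal components of sample space.

    Returns per-feature coordinates and the explained-variance fractions
    (non-increasing, summing to at most 1).
    """
    n_feat, n_samp = m.shape
    if n_components > min(n_feat, n_samp):
        raise ValueError("n_components exceeds matrix rank bound")
    arr = m.values.to_numpy()
    if not np.any(arr - arr.mean(axis=0)):
        raise ValueError("degenerate (rank-0) matrix")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(arr)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=m.values.index, columns=cols), pca.explained_variance_ratio_


def _unnormalized_gini_importance(forest: RandomForestClassifier) -> np.ndarray:
    """Mean decrease in Gini impurity per feature: per-tree impurity decreases
    summed over the tree's splits (weighted by node sample fraction), averaged
    over trees without per-tree normalization."""
    total = np.zeros(forest.n_features_in_)
    for tree in forest.estimators_:
        total += tree.tree_.compute_feature_importances(normalize=False)
    return total / len(forest.estimators_)


def rf_rank(
    m: FeatureMatrix,
    cluster: ClusterModel,
    cluster_index: int,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> ImportancePanel:
    """Grow a random forest classifying samples as control vs treatment from
    the cluster's features, and rank those features by mean decrease in Gini
    impurity (descending; ties broken by feature id)."""
    members = cluster.members(cluster_index)
    if not members:
        raise ValueError(f"cluster {cluster_index} is empty")
    y = m.condition.to_numpy()
    if len(set(y)) < 2:
        raise ValueError("need samples from both conditions")
    X = m.values.loc[members].to_numpy().T  # samples x features
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    imp = _unnormalized_gini_importance(forest)
    entries = pd.DataFrame({"feature_id": members, "importance": imp})
    entries = entries.sort_values(
        ["importance", "feature_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    entries["rank"] = np.arange(1, len(entries) + 1)
    return ImportancePanel(
        cluster_index=cluster_index,
        entries=entries,
        n_trees=n_trees,
        seed=seed,
        out_of_bag_accuracy=float(forest.oob_score_),
    )


def top_n(panel: ImportancePanel, n: int = DEFAULT_TOP_N) -> list[str]:
    """First min(n, panel size) feature ids of the sorted panel."""
    return panel.entries["feature_id"].head(n).tolist()


def write_assignment(cluster: ClusterModel, path) -> None:
    cluster.assignment.rename("cluster").to_csv(path, index_label="feature_id")


def write_panel(panel: ImportancePanel, path) -> None:
    panel.entries[["rank", "feature_id", "importance"]].to_csv(path, index=False)
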