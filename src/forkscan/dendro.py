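"""Agglomerative clustering of prioritized biomolecules.

After the forest has ranked features within each k-means cluster, the top
panel is hierarchically clustered so that biomolecules with similar
measurement patterns across the cohort — e.g. substrates of one transporter,
or a family of related lipids — end up adjacent in the dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .matrix_io import FeatureMatrix

METRICS = ("euclidean", "correlation")
LINKAGES = ("average", "complete", "single", "ward")

DEFAULT_METRIC = "euclidean"
DEFAULT_LINKAGE = "average"


@dataclass
class Dendrogram:
    """Agglomeration over features.

    ``leaves`` lists the feature ids in the (sorted) order used to build the
    tree; node i < n is leaf ``leaves[i]``, node n + j is the cluster formed
    by merge j.  ``merges`` holds (left_node, right_node, height) rows.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]
    linkage_name: str
    metric_name: str
    _Z: np.ndarray = None  # scipy linkage matrix

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distance matrix over the leaves."""
        return hierarchy.cophenet(self._Z)


def hclust_features(
    m: FeatureMatrix,
    metric: str = DEFAULT_METRIC,
    linkage: str = DEFAULT_LINKAGE,
) -> Dendrogram:
    """Agglomerate the matrix's features bottom-up.

    Features are sorted by id before distances are computed, so the result is
    invariant to the input row order (distance ties are then resolved by the
    same lexicographic pair order on every run).
    """
    if m.shape[0] < 2:
        raise ValueError("hierarchical clustering needs >= 2 features")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if linkage == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")

    leaves = sorted(str(f) for f in m.feature_ids)
    arr = m.values.loc[leaves].to_numpy()
    dist = pdist(arr, metric=metric)
    Z = hierarchy.linkage(dist, method=linkage)
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    return Dendrogram(leaves=leaves, merges=merges, linkage_name=linkage, metric_name=metric, _Z=Z)


def cut_groups(d: Dendrogram, n_groups: int) -> dict[str, int]:
    """Partition the leaves by cutting the tree into ``n_groups`` clusters."""
    if not 1 <= n_groups <= d.n_leaves:
        raise ValueError(f"n_groups must be in [1, {d.n_leaves}], got {n_groups}")
    labels = hierarchy.fcluster(d._Z, t=n_groups, criterion="maxclust")
    return {leaf: int(g) for leaf, g in zip(d.leaves, labels)}


def to_newick(d: Dendrogram) -> str:
    """Serialize as a Newick string; each branch length is the difference
    between the parent merge height and the child's own height (leaves sit at
    height 0), so root-to-leaf path lengths equal the root merge height."""
    n = d.n_leaves

    def render(node: int, parent_h: float) -> str:
        if node < n:
            return f"{d.leaves[node]}:{float(parent_h)}"
        left, right, h = d.merges[node - n]
        inner = f"({render(left, h)},{render(right, h)})"
        return f"{inner}:{float(parent_h - h)}"

    left, right, h = d.merges[-1]
    return f"({render(left, h)},{render(right, h)});"


def write_merge_table(d: Dendrogram, path) -> None:
    pd.DataFrame(d.merges, columns=["left", "right", "height"]).to_csv(path, index=False)
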