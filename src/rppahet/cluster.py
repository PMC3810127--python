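"""Non-supervised hierarchical clustering of RPPA samples.

Pipeline: log2-transform and median-center each protein row, compute a
Spearman rank-correlation distance (1 - rho) between samples over
pairwise-complete proteins, then agglomerate with average linkage (UPGMA).
Rank-based distances make the tree invariant to any strictly monotone
per-sample transformation of the expression values, and UPGMA guarantees
monotone merge heights.  A co-clustering score quantifies whether samples
from the same patient end up together when the tree is cut into k flat
clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .synthetic import TISSUE_TUMOR


def preprocess(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2-transform, then median-center each protein row.

    Missing entries stay missing; non-positive values are rejected with the
    offending cell named.  Not idempotent: centered values are no longer
    positive, so apply exactly once.
    """
    vals = matrix.to_numpy(dtype=float)
    bad = np.isfinite(vals) & (vals <= 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"preprocess: non-positive value {vals[i, j]} at "
            f"protein={matrix.index[i]!r} sample={matrix.columns[j]!r}")
    logged = np.log2(vals)
    centered = logged - np.nanmedian(logged, axis=1, keepdims=True)
    return pd.DataFrame(centered, index=matrix.index, columns=matrix.columns)


def spearman_distance(matrix: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise sample distance 1 - Spearman rho over pairwise-complete proteins.

    Midranks handle ties; the distance is symmetric with zero diagonal and
    range [0, 2].  Every sample pair must share at least ``min_shared``
    non-missing proteins.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("spearman_distance: need >= 2 samples")
    vals = matrix.to_numpy(dtype=float)
    n = matrix.shape[1]
    if not np.isnan(vals).any():
        if n == 2:
            r = stats.spearmanr(vals[:, 0], vals[:, 1]).statistic
            rho = np.array([[1.0, r], [r, 1.0]])
        else:
            rho = stats.spearmanr(vals, axis=0).statistic
        dist = 1.0 - rho
    else:
        dist = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                shared = np.isfinite(vals[:, a]) & np.isfinite(vals[:, b])
                if shared.sum() < min_shared:
                    raise ValidationError(
                        "spearman_distance: samples "
                        f"({matrix.columns[a]!r}, {matrix.columns[b]!r}) share only "
                        f"{int(shared.sum())} proteins (< {min_shared})")
                r = stats.spearmanr(vals[shared, a], vals[shared, b]).statistic
                dist[a, b] = dist[b, a] = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=matrix.columns, columns=matrix.columns)


@dataclass(frozen=True)
class ClusterTree:
    """UPGMA merge tree over samples.

    Wraps a SciPy linkage matrix together with the (lexicographically
    sorted) leaf labels it was built over.
    """

    linkage: np.ndarray
    labels: tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels (1..k) from a straight cut into k clusters."""
        if k < 1:
            raise ValidationError(f"cut: k must be >= 1, got {k}")
        assignments = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(assignments, index=list(self.labels), name="cluster")

    def to_newick(self) -> str:
        """Newick string with branch lengths from the ultrametric merge heights."""
        root = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = fmt(root.left, root.dist)
        right = fmt(root.right, root.dist)
        return f"({left},{right}):0;"


def average_linkage(distances: pd.DataFrame) -> ClusterTree:
    """UPGMA agglomeration of a symmetric distance table.

    Samples are ordered lexicographically before agglomeration, so distance
    ties resolve deterministically toward the smallest sample id.
    """
    if distances.shape[0] != distances.shape[1]:
        raise ValidationError("average_linkage: distance table must be square")
    if list(distances.index) != list(distances.columns):
        raise ValidationError("average_linkage: index and columns must match")
    order = sorted(distances.index)
    d = distances.loc[order, order].to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("average_linkage: distance table is not symmetric")
    condensed = squareform(d, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    return ClusterTree(linkage=linkage, labels=tuple(order))


@dataclass(frozen=True)
class CoclusterResult:
    score: float                      # within-patient co-membership rate
    per_patient_scattered: pd.Series  # True when a patient's samples span > 1 cluster
    assignments: pd.Series

    @property
    def n_scattered(self) -> int:
        return int(self.per_patient_scattered.sum())


def cocluster_score(tree: ClusterTree, meta: pd.DataFrame, k: int) -> CoclusterResult:
    """Do same-patient samples co-cluster when the tree is cut into k clusters?

    The score is the proportion of same-patient tumor sample pairs assigned
    to the same flat cluster; a patient is 'scattered' when their samples
    span more than one cluster.  Only tumor samples present in the tree
    enter the score.
    """
    if k > len(tree.labels):
        raise ValidationError(
            f"cocluster_score: k={k} exceeds number of samples {len(tree.labels)}")
    assignments = tree.cut(k)
    tumor = meta[meta["tissue_class"] == TISSUE_TUMOR]
    tumor = tumor[tumor["sample_id"].isin(assignments.index)]
    same, total = 0, 0
    scattered = {}
    for patient_id, grp in tumor.groupby("patient_id", sort=False):
        clusters = assignments[grp["sample_id"]].to_numpy()
        scattered[patient_id] = bool(np.unique(clusters).size > 1)
        m = clusters.size
        total += m * (m - 1) // 2
        for c in np.unique(clusters):
            mc = int((clusters == c).sum())
            same += mc * (mc - 1) // 2
    if total == 0:
        raise ValidationError(
            "cocluster_score: no patient has >= 2 tumor samples in the tree")
    return CoclusterResult(score=same / total,
                           per_patient_scattered=pd.Series(scattered,
                                                           name="scattered"),
                           assignments=assignments)


def cluster_samples(matrix: pd.DataFrame) -> ClusterTree:
    """Preprocess, compute Spearman distances, and build the UPGMA tree."""
    return average_linkage(spearman_distance(preprocess(matrix)))


def per_tumor_mean_matrix(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Collapse tumor samples to per-patient mean profiles, keeping normals.

    Reproduces the tumor-vs-normal clustering layout: one mean column per
    tumor patient plus every normal-tissue sample unchanged.
    """
    tumor = meta[meta["tissue_class"] == TISSUE_TUMOR]
    cols = {}
    for patient_id, grp in tumor.groupby("patient_id", sort=False):
        ids = [s for s in grp["sample_id"] if s in matrix.columns]
        cols[patient_id] = matrix[ids].mean(axis=1)
    for _, row in meta[meta["tissue_class"] != TISSUE_TUMOR].iterrows():
        if row["sample_id"] in matrix.columns:
            cols[row["sample_id"]] = matrix[row["sample_id"]]
    return pd.DataFrame(cols)
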