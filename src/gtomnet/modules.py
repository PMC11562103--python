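"""TF module detection on GTOM matrices and the (cutoff, k, m) parameter scan.

Clustering is agglomerative on the dissimilarity 1 − t (the standard
topological-overlap dissimilarity), cut to a requested number of clusters.
Ward linkage is the default; average linkage is available.  Cluster labels
are canonicalized by descending cluster size, which also fixes the cluster
order used by the asymmetric second term of the total score S_k.

The parameter scan evaluates, for every (cutoff, k, n_clusters) grid point:
adjacency → GTOM(k) → clustering → pairwise cluster GTOM scores → S_k, plus
the standard deviation of cluster sizes (population convention).  High S_k
flags partitions with multiple cores and attached satellites; low size SD
guards against one giant cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .expression import ExpressionMatrix
from .gtom import GtomMatrix, adjacency_from_correlation, correlation_matrix, gtom, gtom_score, total_score

__all__ = [
    "ClusterPartition",
    "ScanRecord",
    "cluster_gtom",
    "cluster_count_diagnostics",
    "cluster_score_matrix",
    "parameter_scan",
]


@dataclass
class ClusterPartition:
    """Assignment of entities to clusters, canonically ordered by size.

    ``labels[i]`` is the cluster index (0-based, 0 = largest cluster) of
    entity i; ``sizes`` and ``ratios`` follow that order.
    """

    labels: np.ndarray
    entity_ids: list[str]
    linkage_method: str

    n_clusters: int = field(init=False)
    sizes: np.ndarray = field(init=False)
    ratios: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape[0] != len(self.entity_ids):
            raise ValueError("one label per entity required")
        self.n_clusters = int(self.labels.max()) + 1
        self.sizes = np.bincount(self.labels, minlength=self.n_clusters)
        if np.any(self.sizes == 0):
            raise ValueError("empty cluster in partition")
        self.ratios = self.sizes / self.sizes.sum()

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)

    def size_sd(self) -> float:
        """Population standard deviation of cluster sizes."""
        return float(np.std(self.sizes))


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters as 0..m−1 by descending size (ties: lowest raw id)."""
    ids, counts = np.unique(raw, return_counts=True)
    order = np.lexsort((ids, -counts))
    mapping = {int(ids[pos]): rank for rank, pos in enumerate(order)}
    return np.array([mapping[int(v)] for v in raw])


def _condensed_dissimilarity(t: GtomMatrix) -> np.ndarray:
    diss = 1.0 - np.clip(t.values, 0.0, 1.0)
    diss = (diss + diss.T) / 2.0
    np.fill_diagonal(diss, 0.0)
    return squareform(diss, checks=False)


def cluster_gtom(t: GtomMatrix, n_clusters: int, linkage_method: str = "ward") -> ClusterPartition:
    """Cut an agglomerative tree on 1 − t into ``n_clusters`` groups."""
    if linkage_method not in ("ward", "average"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    d = t.values.shape[0]
    if not 2 <= n_clusters <= d:
        raise ValueError(f"n_clusters must be in [2, {d}]")
    if n_clusters == d:
        labels = np.arange(d)
    else:
        tree = linkage(_condensed_dissimilarity(t), method=linkage_method)
        labels = fcluster(tree, t=n_clusters, criterion="maxclust") - 1
    return ClusterPartition(
        labels=_canonical_labels(labels),
        entity_ids=list(t.entity_ids),
        linkage_method=linkage_method,
    )


def cluster_count_diagnostics(
    t: GtomMatrix, counts: Sequence[int], linkage_method: str = "ward"
) -> pd.DataFrame:
    """Mean silhouette width on 1 − t for each candidate cluster count."""
    d = t.values.shape[0]
    diss = squareform(_condensed_dissimilarity(t), checks=False)
    rows = []
    for m in counts:
        if not 2 <= m <= d - 1:
            raise ValueError(f"cluster count {m} outside [2, {d - 1}]")
        part = cluster_gtom(t, m, linkage_method)
        if part.n_clusters < 2:
            sil = float("nan")
        else:
            sil = float(silhouette_score(diss, part.labels, metric="precomputed"))
        rows.append({"n_clusters": m, "silhouette": sil})
    return pd.DataFrame(rows)


def cluster_score_matrix(t: GtomMatrix, partition: ClusterPartition) -> np.ndarray:
    """m × m matrix of pairwise cluster GTOM scores G_k(i, j), canonical order."""
    m = partition.n_clusters
    g = np.zeros((m, m))
    members = [partition.members(i) for i in range(m)]
    for i in range(m):
        for j in range(i, m):
            if i == j and members[i].size < 2:
                g[i, i] = 1.0  # singleton: vacuous self-score
                continue
            g[i, j] = g[j, i] = gtom_score(t, members[i], members[j])
    return g


@dataclass
class ScanRecord:
    """One grid point of the parameter scan."""

    cutoff: float
    k: int
    n_clusters: int
    total_score: float
    size_sd: float
    cluster_sizes: list[int]


def parameter_scan(
    x: ExpressionMatrix,
    cutoffs: Sequence[float],
    ks: Sequence[int],
    n_clusters_list: Sequence[int],
    linkage_method: str = "ward",
    corr_method: str = "pearson",
) -> list[ScanRecord]:
    """Score every (cutoff, k, n_clusters) grid point on the TF network.

    Correlations are computed once; each cutoff yields an adjacency, each k a
    GTOM matrix, and each cluster count a partition scored by S_k and the
    cluster-size SD.  Records are independent of grid enumeration order.
    """
    if not (len(cutoffs) and len(ks) and len(n_clusters_list)):
        raise ValueError("empty scan grid")
    corr = correlation_matrix(x, method=corr_method, axis="genes")
    records: list[ScanRecord] = []
    for cutoff in cutoffs:
        adj = adjacency_from_correlation(corr, cutoff)
        for k in ks:
            t = gtom(adj, k)
            for m in n_clusters_list:
                part = cluster_gtom(t, m, linkage_method)
                g = cluster_score_matrix(t, part)
                s_k = total_score(g, part.ratios)
                records.append(
                    ScanRecord(
                        cutoff=float(cutoff),
                        k=int(k),
                        n_clusters=int(m),
                        total_score=s_k,
                        size_sd=part.size_sd(),
                        cluster_sizes=[int(s) for s in part.sizes],
                    )
                )
    return records


def scan_to_frame(records: Sequence[ScanRecord]) -> pd.DataFrame:
    """Tabulate scan records (one row per grid point)."""
    return pd.DataFrame(
        {
            "cutoff": [r.cutoff for r in records],
            "k": [r.k for r in records],
            "n_clusters": [r.n_clusters for r in records],
            "total_score": [r.total_score for r in records],
            "size_sd": [r.size_sd for r in records],
            "cluster_sizes": ["|".join(map(str, r.cluster_sizes)) for r in records],
        }
    )


def plot_scan(records: Sequence[ScanRecord], path: str, n_clusters: int | None = None):
    """Line charts of S_k (left axis) and cluster-size SD (right axis)
    against the cutoff, one panel per overlap order k."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = scan_to_frame(records)
    if n_clusters is not None:
        frame = frame[frame["n_clusters"] == n_clusters]
    ks = sorted(frame["k"].unique())
    fig, axes = plt.subplots(1, len(ks), figsize=(4 * len(ks), 3.2), squeeze=False)
    for ax, k in zip(axes[0], ks):
        sub = frame[frame["k"] == k].sort_values("cutoff")
        ax.plot(sub["cutoff"], sub["total_score"], color="tab:blue", label="total score")
        ax.set_xlabel("cutoff")
        ax.set_ylabel("total score", color="tab:blue")
        twin = ax.twinx()
        twin.plot(sub["cutoff"], sub["size_sd"], color="tab:green", label="size SD")
        twin.set_ylabel("cluster-size SD", color="tab:green")
        ax.set_title(f"GTOM({k})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig
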