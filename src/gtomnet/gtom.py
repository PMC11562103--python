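"""Correlation networks and the generalized topological overlap measure.

The GTOM(k) similarity of nodes i ≠ j in an unweighted graph with adjacency
``a`` is

    t_ij = (|N_{k+1}(i) ∩ N_{k+1}(j)| + a_ij) / (min(|N_{k+1}(i)|, |N_{k+1}(j)|) + 1 − a_ij)

where N_p(i) is the set of nodes (excluding i) reachable from i within a
path of length p; t_ii = 1.  k = 0 gives the classic topological overlap;
larger k lets two nodes count as similar when they share multi-step
neighborhoods even without a direct edge.

Group-level scores: ``gtom_score(C, D)`` is the mean of t_ij over ordered
pairs (i, j) ∈ C × D with i ≠ j, ``gtom_diff(A, B) = score(A, A) −
score(A, B)`` (high ⇒ A is internally tight and separated from B), and
``total_score`` is the composite S_k over a cluster partition that rewards
multiple distinct cores plus weakly self-connected satellites attached to a
core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .expression import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "AdjacencyMatrix",
    "GtomMatrix",
    "correlation_matrix",
    "adjacency_from_correlation",
    "reachable_sets",
    "gtom",
    "gtom_score",
    "gtom_diff",
    "total_score",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric correlation matrix with entity labels (TFs or patients)."""

    values: np.ndarray
    method: str
    entity_ids: list[str]


@dataclass
class AdjacencyMatrix:
    """Binary, symmetric, hollow adjacency from a signed correlation cutoff."""

    values: np.ndarray
    cutoff: float
    entity_ids: list[str]


@dataclass
class GtomMatrix:
    """GTOM(k) overlap matrix in [0, 1] with unit diagonal."""

    values: np.ndarray
    order_k: int
    entity_ids: list[str]
    source: Optional[AdjacencyMatrix] = None


def correlation_matrix(
    x: ExpressionMatrix, method: str = "pearson", axis: str = "genes"
) -> CorrelationMatrix:
    """Pearson or Spearman correlations between genes or between samples.

    Constant rows (zero variance over the correlated axis) get correlation 0
    to every partner; the diagonal is 1 throughout.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if axis not in ("genes", "samples"):
        raise ValueError(f"unknown axis {axis!r}")
    data = x.values if axis == "genes" else x.values.T
    ids = x.gene_ids if axis == "genes" else x.sample_ids
    if data.shape[0] < 2:
        raise ValueError("need at least two entities to correlate")
    if data.shape[1] < 3:
        raise ValueError("need at least three observations per pair")
    if method == "spearman":
        data = rankdata(data, axis=1)  # average ranks for ties
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms <= 0
    if np.any(constant):
        logger.warning("%d constant rows yield correlation 0", int(constant.sum()))
    safe = np.where(constant, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    corr[constant, constant] = 0.0
    return CorrelationMatrix(values=corr, method=method, entity_ids=list(ids))


def adjacency_from_correlation(c: CorrelationMatrix, cutoff: float) -> AdjacencyMatrix:
    """Threshold at ``corr >= cutoff`` (signed: anti-correlation never links).

    The boundary is inclusive and the diagonal is removed.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    adj = (c.values >= cutoff).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    adj = adj & adj.T  # symmetry is already guaranteed; keep it explicit
    return AdjacencyMatrix(values=adj, cutoff=cutoff, entity_ids=list(c.entity_ids))


def _reach_matrix(adj: np.ndarray, path_len: int) -> np.ndarray:
    """Boolean matrix R with R[i, j] = (0 < distance(i, j) <= path_len)."""
    a = adj.astype(bool)
    # float32 matmul hits BLAS; counts stay < 2**24 so the arithmetic is exact
    a_f = a.astype(np.float32)
    reach = a.copy()
    frontier = a.copy()
    for _ in range(path_len - 1):
        frontier = (frontier.astype(np.float32) @ a_f) > 0
        new = frontier & ~reach
        if not new.any():
            break
        reach |= frontier
    np.fill_diagonal(reach, False)
    return reach


def reachable_sets(a: AdjacencyMatrix, path_len: int) -> list[set[int]]:
    """N_path_len(i) for every node i: nodes (≠ i) within graph distance path_len."""
    if path_len < 1:
        raise ValueError("path_len must be at least 1")
    reach = _reach_matrix(a.values, path_len)
    return [set(np.flatnonzero(row)) for row in reach]


def gtom(a: AdjacencyMatrix, k: int = 0) -> GtomMatrix:
    """GTOM(k) overlap matrix of the graph ``a`` (k ≥ 0, k = 0 is classic TOM).

    An isolated pair (both neighborhoods empty, no edge) scores 0.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    adj = a.values.astype(np.int64)
    reach = _reach_matrix(adj, k + 1)
    r_f = reach.astype(np.float32)
    # |N(i) ∩ N(j)|; reach is symmetric and counts < 2**24, so exact
    inter = np.rint(r_f @ r_f.T).astype(np.int64)
    sizes = reach.sum(axis=1)
    min_sizes = np.minimum(sizes[:, None], sizes[None, :])
    num = inter + adj
    den = min_sizes + 1 - adj
    t = num / den
    np.fill_diagonal(t, 1.0)
    return GtomMatrix(values=t, order_k=int(k), entity_ids=list(a.entity_ids), source=a)


def _as_matrix(t: GtomMatrix | AdjacencyMatrix) -> np.ndarray:
    return t.values.astype(float)


def gtom_score(
    t: GtomMatrix | AdjacencyMatrix, group_c: Sequence[int], group_d: Sequence[int]
) -> float:
    """Mean of t_ij over ordered pairs (i, j) ∈ C × D with i ≠ j.

    On an adjacency matrix this is the (cross-)edge density of the groups.
    """
    c_idx = np.asarray(sorted(set(group_c)), dtype=int)
    d_idx = np.asarray(sorted(set(group_d)), dtype=int)
    if c_idx.size == 0 or d_idx.size == 0:
        raise ValueError("groups must be non-empty")
    mat = _as_matrix(t)
    block = mat[np.ix_(c_idx, d_idx)]
    shared = np.intersect1d(c_idx, d_idx)
    n_pairs = c_idx.size * d_idx.size - shared.size
    if n_pairs == 0:
        raise ValueError("no ordered pair (i, j) with i != j in C x D")
    # drop the i == j entries that fall inside the block (t_ii = 1, a_ii = 0)
    diag = float(mat[shared, shared].sum()) if shared.size else 0.0
    return float((block.sum() - diag) / n_pairs)


def gtom_diff(
    t: GtomMatrix | AdjacencyMatrix, group_a: Sequence[int], group_b: Sequence[int]
) -> float:
    """score(A, A) − score(A, B): within-A tightness minus A↔B interconnection."""
    a_idx = sorted(set(group_a))
    if len(a_idx) < 2:
        raise ValueError("group A needs at least two members")
    if len(set(group_b)) < 1:
        raise ValueError("group B must be non-empty")
    return gtom_score(t, a_idx, a_idx) - gtom_score(t, a_idx, list(group_b))


def total_score(
    gtom_scores: np.ndarray, cluster_ratios: Sequence[float], symmetrized: bool = False
) -> float:
    """Composite score S_k over an m × m matrix of cluster-pair GTOM scores.

    S_k = (1/d_C) Σ_{i<j} r_i r_j [G(i,i)G(j,j)(1−G(i,j)) + G(i,i)(1−G(j,j))G(i,j)]

    with d_C = m(m−1)/2.  The first term rewards pairs of distinct cores,
    the second a weakly self-connected cluster j attached to a core i.  The
    second term is asymmetric in (i, j); the caller fixes the cluster order
    (the package convention is descending size).  ``symmetrized=True``
    averages the (i, j) and (j, i) evaluations instead.
    """
    g = np.asarray(gtom_scores, dtype=float)
    r = np.asarray(cluster_ratios, dtype=float)
    m = r.size
    if g.shape != (m, m):
        raise ValueError("gtom_scores must be m x m for m cluster ratios")
    if m < 2:
        raise ValueError("need at least two clusters")
    if np.any(g < -1e-12) or np.any(g > 1 + 1e-12):
        raise ValueError("GTOM scores must lie in [0, 1]")
    if abs(r.sum() - 1.0) > 1e-8:
        raise ValueError(f"cluster ratios must sum to 1 (got {r.sum()})")
    d_c = m * (m - 1) / 2
    total = 0.0
    for i in range(m):
        for j in range(i + 1, m):
            term = g[i, i] * g[j, j] * (1 - g[i, j]) + g[i, i] * (1 - g[j, j]) * g[i, j]
            if symmetrized:
                term = 0.5 * (
                    term
                    + g[j, j] * g[i, i] * (1 - g[j, i])
                    + g[j, j] * (1 - g[i, i]) * g[j, i]
                )
            total += r[i] * r[j] * term
    return float(total / d_c)
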