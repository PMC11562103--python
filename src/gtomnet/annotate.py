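"""Cluster characterization: signature counts, cross-tabulation, overlays.

``signature_counts`` tallies how many genes of each detected cluster fall in
each named gene set (e.g., adrenergic/mesenchymal tumor-state signatures or
fetal adrenal cell-type markers).  ``cross_tabulate`` compares two cluster
partitions of (nearly) the same gene universe, as used to check whether
modules found in one cohort reappear in another.  ``overlay_attributes``
attaches clinical attributes to patient-graph nodes for export and plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .gtom import AdjacencyMatrix
from .modules import ClusterPartition

__all__ = [
    "GeneSetCollection",
    "CrossTab",
    "read_gmt",
    "signature_counts",
    "cross_tabulate",
    "overlay_attributes",
    "adjacency_to_graph",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with ids uppercased and trimmed on construction."""

    sets: dict[str, set[str]]

    @classmethod
    def from_lists(cls, named: Mapping[str, Sequence[str]]) -> "GeneSetCollection":
        return cls({name: {str(g).strip().upper() for g in ids} for name, ids in named.items()})


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read GMT-style gene sets: name, description, then member ids, tab-separated."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not parts[0]:
            continue
        name = parts[0]
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        sets[name] = {g.strip().upper() for g in parts[2:] if g.strip()}
    return GeneSetCollection(sets)


def signature_counts(partition: ClusterPartition, sets: GeneSetCollection) -> pd.DataFrame:
    """Cluster × gene-set membership counts; a gene in several sets counts in each.

    A final ``total`` row holds column totals over clusters.
    """
    genes = [g.strip().upper() for g in partition.entity_ids]
    universe = set(genes)
    if not any(universe & s for s in sets.sets.values()):
        logger.warning("no overlap between partition genes and any gene set")
    rows = {}
    for c in range(partition.n_clusters):
        members = {genes[i] for i in partition.members(c)}
        rows[f"cluster_{c}"] = {name: len(members & s) for name, s in sets.sets.items()}
    table = pd.DataFrame(rows).T
    table.loc["total"] = table.sum(axis=0)
    return table.astype(int)


@dataclass
class CrossTab:
    """Cross-tabulation of two partitions over a shared gene universe."""

    counts: pd.DataFrame       # rows: reference clusters; columns: other clusters
    row_percent: pd.DataFrame  # per-row percentages (sum to 100 within rounding)
    best_match: pd.Series      # max row percentage per reference cluster


def cross_tabulate(
    p_ref: ClusterPartition,
    p_other: ClusterPartition,
    merged_ref_clusters: Optional[Sequence[Sequence[int]]] = None,
) -> CrossTab:
    """Count how genes of each reference cluster distribute over the other
    partition's clusters.

    Partitions are intersected on shared gene ids (the intersection size is
    logged).  ``merged_ref_clusters`` optionally adds rows for caller-defined
    super-clusters (e.g., a union of a core and its satellites).
    """
    ref_map = dict(zip(p_ref.entity_ids, p_ref.labels))
    other_map = dict(zip(p_other.entity_ids, p_other.labels))
    shared = [g for g in p_ref.entity_ids if g in other_map]
    if not shared:
        raise ValueError("partitions share no gene ids")
    logger.info("cross-tabulating %d shared genes", len(shared))
    n_ref, n_other = p_ref.n_clusters, p_other.n_clusters
    counts = np.zeros((n_ref, n_other), dtype=int)
    for g in shared:
        counts[ref_map[g], other_map[g]] += 1
    index = [f"ref_{i}" for i in range(n_ref)]
    cols = [f"other_{j}" for j in range(n_other)]
    frame = pd.DataFrame(counts, index=index, columns=cols)
    if merged_ref_clusters:
        for group in merged_ref_clusters:
            name = "ref_" + "+".join(str(i) for i in group)
            frame.loc[name] = counts[list(group)].sum(axis=0)
    row_sums = frame.sum(axis=1)
    percent = frame.div(row_sums.replace(0, np.nan), axis=0) * 100.0
    return CrossTab(counts=frame, row_percent=percent, best_match=percent.max(axis=1))


def adjacency_to_graph(a: AdjacencyMatrix, min_degree: int = 0) -> nx.Graph:
    """Adjacency → networkx graph; nodes below ``min_degree`` are hidden.

    The degree filter is a display convention only — all scores in this
    package are computed on the full matrix.
    """
    graph = nx.from_numpy_array(a.values)
    nx.relabel_nodes(graph, dict(enumerate(a.entity_ids)), copy=False)
    if min_degree > 0:
        drop = [v for v, deg in graph.degree() if deg < min_degree]
        graph.remove_nodes_from(drop)
    return graph


def overlay_attributes(
    graph_or_adjacency: nx.Graph | AdjacencyMatrix,
    clinical: pd.DataFrame,
    attributes: Sequence[str] = ("stage", "vital_state", "mycn", "mki", "diagnostic_category"),
    id_column: str = "sample_id",
) -> nx.Graph:
    """Attach clinical attributes to patient-graph nodes.

    ``clinical`` has one row per sample; attributes missing for a node are
    encoded as the string ``"unknown"``.  Clinical rows without a matching
    node are logged and ignored.
    """
    graph = (
        graph_or_adjacency
        if isinstance(graph_or_adjacency, nx.Graph)
        else adjacency_to_graph(graph_or_adjacency)
    )
    if id_column not in clinical.columns:
        raise ValueError(f"clinical table lacks column {id_column!r}")
    table = clinical.set_index(clinical[id_column].astype(str))
    unmatched = [s for s in table.index if s not in graph.nodes]
    if unmatched:
        logger.info("%d clinical rows without a graph node (ignored)", len(unmatched))
    for node in graph.nodes:
        row = table.loc[str(node)] if str(node) in table.index else None
        for attr in attributes:
            value = None if row is None or attr not in table.columns else row[attr]
            if value is None or (isinstance(value, float) and np.isnan(value)):
                value = "unknown"
            graph.nodes[node][attr] = str(value)
    return graph
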