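"""End-to-end orchestration of the coexpression-network analysis.

Flow: read expression → (unit conversion) → restrict to the TF list →
(denoise) → TF Pearson correlations → thresholded adjacency → GTOM(k) →
Ward clustering → per-cluster patient Spearman networks → separation curves
→ tables and graph exports.  Every artifact is written under the output
directory together with the resolved configuration, the package version and
a manifest of SHA-256 checksums, so a rerun with the same configuration is
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .annotate import adjacency_to_graph, overlay_attributes
from .expression import (
    ExpressionMatrix,
    convert_log2fpkm_to_tpm,
    read_expression,
    restrict_to_tf_list,
    write_expression,
)
from .gtom import adjacency_from_correlation, correlation_matrix, gtom
from .modules import cluster_gtom, cluster_score_matrix, scan_to_frame
from .recode import apply_recode
from .separation import PatientGroups, separation_curve
from .gtom import total_score

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_pipeline"]


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run."""

    expression_path: str
    output_dir: str
    tf_list_path: Optional[str] = None
    clinical_path: Optional[str] = None
    groups_path: Optional[str] = None  # CSV: sample_id, group in {4, 4S}
    unit: str = "arbitrary"
    log1p: bool = False
    recode: bool = True
    recode_ell: Optional[int] = None
    cutoff: float = 0.7
    k: int = 2
    n_clusters: int = 5
    linkage: str = "ward"
    patient_cutoffs: Sequence[float] = field(
        default_factory=lambda: [round(c, 2) for c in np.arange(0.50, 0.951, 0.01)]
    )
    seed: int = 0

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["patient_cutoffs"] = [float(c) for c in self.patient_cutoffs]
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_pipeline(cfg: RunConfig) -> dict:
    """Execute the full flow and return a manifest of written artifacts."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("stage: %s", name)

    stage("read")
    x = read_expression(cfg.expression_path, unit=cfg.unit)
    if cfg.unit == "log2_fpkm_plus1":
        stage("convert_units")
        x = convert_log2fpkm_to_tpm(x)
    if cfg.tf_list_path:
        stage("restrict_tfs")
        x = restrict_to_tf_list(x, cfg.tf_list_path)
    if cfg.recode:
        stage("denoise")
        x = apply_recode(x, ell=cfg.recode_ell)
        write_expression(x, out / "expression_denoised.tsv")
    if cfg.log1p:
        x = ExpressionMatrix(np.log1p(np.clip(x.values, 0, None)), x.gene_ids, x.sample_ids, "arbitrary")

    stage("tf_network")
    corr = correlation_matrix(x, method="pearson", axis="genes")
    adj = adjacency_from_correlation(corr, cfg.cutoff)
    t = gtom(adj, cfg.k)

    stage("cluster")
    part = cluster_gtom(t, cfg.n_clusters, cfg.linkage)
    g = cluster_score_matrix(t, part)
    s_k = total_score(g, part.ratios)
    pd.DataFrame(
        {"gene_id": part.entity_ids, "cluster": part.labels}
    ).to_csv(out / "tf_clusters.csv", index=False)
    pd.DataFrame(
        g,
        index=[f"cluster_{i}" for i in range(part.n_clusters)],
        columns=[f"cluster_{i}" for i in range(part.n_clusters)],
    ).to_csv(out / "cluster_gtom_scores.csv")

    tf_graph = adjacency_to_graph(adj)
    for node, label in zip(part.entity_ids, part.labels):
        tf_graph.nodes[node]["cluster"] = int(label)
    nx.write_graphml(tf_graph, out / "tf_network.graphml")

    curves_frame = None
    if cfg.groups_path:
        stage("patient_separation")
        gtable = pd.read_csv(cfg.groups_path, dtype=str)
        groups = PatientGroups(dict(zip(gtable["sample_id"], gtable["group"])))
        curve_rows = []
        clinical = pd.read_csv(cfg.clinical_path, dtype=str) if cfg.clinical_path else None
        for c in range(part.n_clusters):
            genes = [part.entity_ids[i] for i in part.members(c)]
            if len(genes) < 3:
                continue
            curve = separation_curve(x, genes, groups, cfg.patient_cutoffs, name=f"cluster_{c}")
            for cut, sep in zip(curve.cutoffs, curve.separation):
                curve_rows.append({"subset": curve.tf_subset_name, "cutoff": cut, "separation": sep})
            # one representative patient graph per cluster at the median cutoff
            mid = cfg.patient_cutoffs[len(cfg.patient_cutoffs) // 2]
            from .separation import patient_network

            pnet = patient_network(x, genes, mid)
            pgraph = adjacency_to_graph(pnet)
            for node in pgraph.nodes:
                pgraph.nodes[node]["stage"] = groups.labels.get(str(node), "unknown")
            if clinical is not None:
                pgraph = overlay_attributes(pgraph, clinical)
            nx.write_graphml(pgraph, out / f"patient_network_cluster_{c}.graphml")
        curves_frame = pd.DataFrame(curve_rows)
        curves_frame.to_csv(out / "separation_curves.csv", index=False)

    stage("manifest")
    (out / "run_config.json").write_text(
        json.dumps({"version": __version__, "config": cfg.to_dict()}, indent=2)
    )
    artifacts = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "total_score": s_k,
        "cluster_sizes": [int(s) for s in part.sizes],
        "files": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
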