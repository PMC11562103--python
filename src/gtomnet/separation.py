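"""Patient-network separation of the two tumor stages.

For a chosen TF subset (a detected module or a baseline gene set), patients
are connected when their Spearman correlation across those TFs reaches a
cutoff.  Separation of stage 4 from stage 4S is the within-stage-4 edge
density minus the 4↔4S cross density — the group-difference score evaluated
directly on the adjacency matrix (Spearman is preferred over Pearson because
expression levels are heavy-tailed).  Sweeping the cutoff from ~0.5 to ~0.95
yields a separation curve per TF subset; subsets that carry the stage signal
dominate at high cutoffs.

Baselines: ``q3_filter`` keeps genes above the bottom quartile of per-gene
medians; ``de_subset`` is a light two-group differential test (Welch t on
log1p values with Benjamini–Hochberg control) standing in for an external
differential-expression gene list, which can also be supplied verbatim.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix
from .gtom import (
    AdjacencyMatrix,
    adjacency_from_correlation,
    correlation_matrix,
    gtom,
    gtom_diff,
)

__all__ = [
    "PatientGroups",
    "SeparationCurve",
    "patient_network",
    "separation_score",
    "separation_curve",
    "q3_filter",
    "de_subset",
]

logger = logging.getLogger(__name__)


@dataclass
class PatientGroups:
    """Stage label ("4" or "4S") per sample id."""

    labels: dict[str, str]

    def indices(self, sample_ids: Sequence[str], group: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(sample_ids) if self.labels.get(s) == group])


@dataclass
class SeparationCurve:
    """Separation score as a function of the patient-correlation cutoff."""

    tf_subset_name: str
    cutoffs: list[float]
    separation: list[float]  # NaN where a group has no within-pair


def patient_network(
    x: ExpressionMatrix, tf_subset: Sequence[str], cutoff: float, method: str = "spearman"
) -> AdjacencyMatrix:
    """Patient–patient adjacency from correlations across ``tf_subset`` rows."""
    subset = [str(g) for g in tf_subset]
    if len(subset) < 3:
        raise ValueError("need at least three TFs for a patient network")
    sub = x.subset_genes(subset)
    corr = correlation_matrix(sub, method=method, axis="samples")
    return adjacency_from_correlation(corr, cutoff)


def separation_score(
    a: AdjacencyMatrix,
    groups: PatientGroups,
    use_overlap: bool = False,
    symmetric: bool = False,
) -> float:
    """Within-stage-4 density minus 4↔4S cross density on a patient graph.

    Group A of the difference score is stage 4.  ``use_overlap=True``
    evaluates on the first-order overlap matrix instead of the raw adjacency
    (a sensitivity check); ``symmetric=True`` averages the two within-group
    densities before subtracting the cross density.
    """
    idx4 = groups.indices(a.entity_ids, "4")
    idx4s = groups.indices(a.entity_ids, "4S")
    if idx4.size < 2 or idx4s.size < 2:
        raise ValueError("both stage groups need at least two patients")
    mat = gtom(a, 0) if use_overlap else a
    if symmetric:
        within = 0.5 * (gtom_diff(mat, idx4, idx4s) + gtom_diff(mat, idx4s, idx4))
        return float(within)
    return float(gtom_diff(mat, idx4, idx4s))


def separation_curve(
    x: ExpressionMatrix,
    tf_subset: Sequence[str],
    groups: PatientGroups,
    cutoffs: Sequence[float],
    name: str = "subset",
    method: str = "spearman",
) -> SeparationCurve:
    """Evaluate the separation score over a strictly increasing cutoff grid."""
    cuts = [float(c) for c in cutoffs]
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cutoffs must be strictly increasing")
    subset = [str(g) for g in tf_subset]
    sub = x.subset_genes(subset)
    corr = correlation_matrix(sub, method=method, axis="samples")
    scores: list[float] = []
    for cutoff in cuts:
        adj = adjacency_from_correlation(corr, cutoff)
        try:
            scores.append(separation_score(adj, groups))
        except ValueError:
            scores.append(math.nan)
    return SeparationCurve(tf_subset_name=name, cutoffs=cuts, separation=scores)


def plot_separation_curves(curves: Sequence[SeparationCurve], path: str):
    """One line per TF subset: separation score against the patient cutoff."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    for curve in curves:
        ax.plot(curve.cutoffs, curve.separation, label=curve.tf_subset_name)
    ax.axhline(0.0, color="grey", linewidth=0.6)
    ax.set_xlabel("patient correlation cutoff")
    ax.set_ylabel("separation (within-4 minus cross density)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def q3_filter(x: ExpressionMatrix) -> list[str]:
    """Genes whose median expression is strictly above the bottom quartile.

    The 25th percentile of per-gene medians uses the linear-interpolation
    convention; with all-distinct medians exactly 75% of the genes survive.
    If every median ties, the filter is degenerate and all genes are kept.
    """
    if x.n_genes < 4:
        raise ValueError("need at least four genes")
    medians = np.median(x.values, axis=1)
    q1 = np.percentile(medians, 25)
    keep = medians > q1
    if not keep.any():
        logger.warning("all per-gene medians tie at %.4g; keeping every gene", q1)
        keep = np.ones(x.n_genes, dtype=bool)
    return [g for g, k in zip(x.gene_ids, keep) if k]


def de_subset(
    x: ExpressionMatrix,
    groups: PatientGroups,
    alpha: float = 0.01,
    external_list: Optional[Sequence[str]] = None,
) -> list[str]:
    """Differentially expressed genes between stages 4 and 4S.

    A pre-computed external gene list (e.g., from a dedicated count-based
    differential-expression tool) is accepted verbatim.  Otherwise each gene
    gets a Welch two-sample t-test on log1p values with Benjamini–Hochberg
    adjustment; genes with adjusted p < alpha are returned.  Genes with zero
    variance in both groups are excluded with a warning.
    """
    if external_list is not None:
        present = set(x.gene_ids)
        return [str(g) for g in external_list if str(g) in present]
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if alpha == 0.0:
        return []
    idx4 = groups.indices(x.sample_ids, "4")
    idx4s = groups.indices(x.sample_ids, "4S")
    if idx4.size < 2 or idx4s.size < 2:
        raise ValueError("both groups need at least two samples")
    logged = np.log1p(np.clip(x.values, 0.0, None))
    a, b = logged[:, idx4], logged[:, idx4s]
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    if degenerate.any():
        logger.warning("%d zero-variance genes excluded from testing", int(degenerate.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.asarray(pvals)
    valid = ~degenerate & np.isfinite(pvals)
    if not valid.any():
        return []
    rejected = np.zeros(x.n_genes, dtype=bool)
    rejected[valid] = multipletests(pvals[valid], alpha=alpha, method="fdr_bh")[0]
    return [g for g, r in zip(x.gene_ids, rejected) if r]
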