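"""Noise reduction by PCA eigenvalue shrinkage (RECODE).

For a genes × samples matrix X (d × n) the denoiser changes coordinates into
the principal axes of the sample covariance S = (X − X̄)(X − X̄)ᵀ/(n−1),
shrinks each retained eigenvalue by the mean of its trailing eigenvalues,

    λ̃_i = λ_i − mean(λ_{i+1}, …, λ_D)   for i ≤ ℓ,      λ̃_i = 0 for i > ℓ,

with PCA dimension D = min{n−1, d}, and transforms back.  The trailing mean
estimates the isotropic-noise contribution to each leading eigenvalue, so
the leading components keep their signal variance while the trailing
components — noise under a low-rank-signal-plus-isotropic-noise model — are
zeroed.  On noiseless data of rank r with ℓ = r the map is the identity.

The eigendecomposition is taken through the SVD of the centered matrix
(equivalently, the n × n Gram route), so cost is O(d n²) even for d ≫ n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .expression import ExpressionMatrix

__all__ = ["EigenSystem", "pca_decompose", "shrink_eigenvalues", "select_ell", "apply_recode"]

logger = logging.getLogger(__name__)


@dataclass
class EigenSystem:
    """Truncated eigensystem of a sample covariance matrix.

    ``eigenvectors`` holds the leading D orthonormal columns (d × D) and
    ``eigenvalues`` the matching non-increasing spectrum; ``ell`` and
    ``shrunk_eigenvalues`` are filled once a retention parameter is chosen.
    """

    mean_profile: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    pca_dimension: int
    n_samples: Optional[int] = None
    ell: Optional[int] = None
    shrunk_eigenvalues: Optional[np.ndarray] = None


def pca_decompose(x: ExpressionMatrix) -> EigenSystem:
    """Eigensystem of the sample covariance of ``x``, truncated to D components."""
    if x.n_samples < 2:
        raise ValueError("need at least two samples")
    d, n = x.values.shape
    big_d = min(n - 1, d)
    mean = x.values.mean(axis=1)
    centered = x.values - mean[:, None]
    # SVD of the centered matrix == Gram-matrix route; O(d n^2) for d >> n
    u_mat, sv, _ = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = sv**2 / (n - 1)
    u_mat = u_mat[:, :big_d]
    eigenvalues = eigenvalues[:big_d]
    tol = 1e-10 * eigenvalues[0] if eigenvalues.size and eigenvalues[0] > 0 else 0.0
    eigenvalues = np.where(eigenvalues < tol, 0.0, eigenvalues)
    return EigenSystem(
        mean_profile=mean,
        eigenvectors=u_mat,
        eigenvalues=eigenvalues,
        pca_dimension=big_d,
        n_samples=n,
    )


def shrink_eigenvalues(eigenvalues: np.ndarray, ell: int, pca_dimension: int) -> np.ndarray:
    """Trailing-mean shrinkage of the leading ``ell`` eigenvalues.

    ``λ̃_i = λ_i − (1/(D−i+1)) Σ_{j>i} λ_j`` for i ≤ ell, else 0.  A shrunk
    value that goes negative (an eigenvalue below its own tail mean) is
    clipped to zero with a warning; the source formula leaves that case open.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    big_d = int(pca_dimension)
    if lam.shape[0] < big_d:
        raise ValueError("eigenvalue vector shorter than pca_dimension")
    if not 1 <= ell <= big_d:
        raise ValueError(f"ell={ell} out of range [1, {big_d}]")
    lam = lam[:big_d]
    out = np.zeros(big_d)
    # tail_sum[i] = sum of lam[i+1:], divided by D - i (count of the tail + 1
    # slot) in 1-based terms: 1/(D-i+1) * sum_{j=i+1}^{D}
    rev_cumsum = np.concatenate([np.cumsum(lam[::-1])[::-1][1:], [0.0]])
    for i in range(min(ell, big_d)):
        denom = big_d - i  # = D - (i+1) + 1 with 1-based index i+1
        out[i] = lam[i] - rev_cumsum[i] / denom
    negative = out < 0
    if np.any(negative):
        logger.warning("clipped %d negative shrunk eigenvalues to 0", int(negative.sum()))
        out[negative] = 0.0
    return out


def select_ell(eigen: EigenSystem, method: str = "elbow", fixed: Optional[int] = None) -> int:
    """Choose the number of signal components ℓ.

    ``method="fixed"`` returns the user-supplied value.  ``method="elbow"``
    (default) returns the largest i < D whose eigenvalue exceeds the mean of
    its trailing eigenvalues by the Marchenko–Pastur edge factor
    (1 + sqrt(n/d))²: under pure isotropic noise the largest bulk eigenvalue
    sits exactly that far above the bulk mean, so components above the bar
    are signal under the low-rank-plus-isotropic-noise model.  On noiseless
    low-rank data the rule recovers the exact rank (any positive eigenvalue
    beats a zero tail).  The choice is logged.
    """
    lam = eigen.eigenvalues
    big_d = eigen.pca_dimension
    if lam.size == 0 or lam[0] <= 0:
        raise ValueError("degenerate data: all covariance eigenvalues are zero")
    if method == "fixed":
        if fixed is None or not 1 <= fixed <= big_d:
            raise ValueError(f"fixed ell must be in [1, {big_d}]")
        return int(fixed)
    if method != "elbow":
        raise ValueError(f"unknown method {method!r}")
    d = eigen.eigenvectors.shape[0]
    n = eigen.n_samples if eigen.n_samples is not None else big_d + 1
    edge_factor = (1.0 + np.sqrt(n / d)) ** 2
    best = 0
    for i in range(big_d - 1):  # 0-based; tail is non-empty
        tail_mean = lam[i + 1 : big_d].mean()
        if lam[i] > edge_factor * tail_mean:
            best = i + 1
    if best == 0:
        # flat spectrum (or D == 1): keep the leading component
        best = 1
    logger.info("selected ell=%d of D=%d (MP edge factor %.3f)", best, big_d, edge_factor)
    return best


def apply_recode(
    x: ExpressionMatrix,
    ell: Optional[int] = None,
    eigen: Optional[EigenSystem] = None,
) -> ExpressionMatrix:
    """Denoise ``x``: rescale each retained PC direction by sqrt(λ̃_i/λ_i),
    zero the rest, and return to the original coordinates.

    Per-gene means are preserved exactly and the covariance trace never
    increases (Σλ̃ ≤ Σλ).  The ratio rule sets 0/0 → 0, which agrees with
    the Λ^{−1/2} formulation wherever that is defined.
    """
    if eigen is None:
        eigen = pca_decompose(x)
    if ell is None:
        ell = select_ell(eigen)
    lam = eigen.eigenvalues
    shrunk = shrink_eigenvalues(lam, ell, eigen.pca_dimension)
    eigen.ell = int(ell)
    eigen.shrunk_eigenvalues = shrunk
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.sqrt(np.where(lam > 0, shrunk / np.where(lam > 0, lam, 1.0), 0.0))
    centered = x.values - eigen.mean_profile[:, None]
    coords = eigen.eigenvectors.T @ centered
    rebuilt = eigen.eigenvectors @ (scale[:, None] * coords) + eigen.mean_profile[:, None]
    return ExpressionMatrix(rebuilt, x.gene_ids, x.sample_ids, x.unit)
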