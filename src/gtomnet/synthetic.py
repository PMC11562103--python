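"""Planted-module synthetic expression data.

Generates TF-by-sample matrices whose coexpression structure is known by
construction: strongly intra-correlated *core* modules, weakly
intra-correlated *bridge* modules coupled to a localized region of one core,
and an *isolated* remainder with correlations below any useful edge
threshold.  Two patient groups (majority "4" / minority "4S") differ only
through the latent factors of designated modules, so every downstream stage
(denoising, network construction, module detection, patient separation) has
ground truth.

Generative model
----------------
Each module *m* carries a global factor ``f_m`` (one value per sample) and a
chain of ``q`` local sub-factors ``h_0..h_{q-1}``.  A TF at chain position
``u`` sees the interpolated local profile

    phi_m(u) = ((1-frac) h_i + frac h_{i+1}) / sqrt((1-frac)^2 + frac^2)

with ``i = floor(u)``, so correlation between two TFs decays smoothly with
chain distance and vanishes beyond two sub-factor segments.  The standardized
biological signal of TF *j* in a core or isolated module is

    z_j = sqrt(0.40 w) f_m + sqrt(0.60 w) phi_m(u_j) + sqrt(1-w) g_j

where ``w`` is the role's ``within_module_corr`` (the peak within-module
correlation) and ``g_j`` is idiosyncratic.  A bridge TF additionally couples
to its host core through an anchor construct — a 60/40 mix of the core's
global factor and the core's local profile at the bridge's attachment
region — with variance ``b * taper(u)^2`` where ``b = bridge_to_core_corr``
and the taper falls linearly from 1 at the anchor end of the bridge chain to
0.2 at the far end; the bridge's own factors carry the remaining within
share.  Only the anchor-end bridge TFs therefore exceed a high correlation
threshold against the core, which keeps the bridge a weakly attached
satellite rather than part of the core.  With ``q = 1`` and ``w = 1`` the
model collapses to a single noiseless common factor (all within-module
correlations are exactly 1).

The group difference of a differential module enters through its local
sub-factors, each shifted for minority-group samples by ``effect_size``
times a signed per-factor coefficient: the resulting per-gene mean
difference varies along the module chain, which is what across-gene patient
correlations can see (a shift uniform over a module's genes is absorbed by
per-sample profile centering and separates nothing).  Optionally a block of
isolated-module genes becomes low-expression "decoys": genes with a strong
group shift *relative to their own tiny amplitude* — prominently flagged by
per-gene differential tests, yet contributing almost nothing to across-gene
patient correlations, like low-expression genes flagged from count data.

Observed values are ``baseline_j + amplitude_j * (z_j + noise)`` followed by
one global affine shift into the non-negative (TPM-like) range; the shift
preserves every planted correlation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, write_expression

__all__ = [
    "ModuleSpec",
    "SyntheticSpec",
    "SyntheticTruth",
    "default_spec",
    "generate_planted_expression",
    "generate_lowrank_noiseless",
    "DEFAULT_NOISE_SD",
]

ROLES = ("core", "bridge", "isolated")

#: isotropic measurement-noise level used by denoising stress experiments
DEFAULT_NOISE_SD = 0.5

# variance split of the within-module share w: global factor vs local chain
_GLOBAL_FRAC = 0.44
_LOCAL_FRAC = 0.56
# variance split of the bridge->core coupling construct: core global vs core local
_BRIDGE_GLOBAL_FRAC = 0.60
_BRIDGE_LOCAL_FRAC = 0.40
# split of a bridge TF's own (non-coupled) signal: own global vs own chain
_BRIDGE_OWN_GLOBAL_FRAC = 0.15
_BRIDGE_OWN_LOCAL_FRAC = 0.85
# fraction of the attached core's chain covered by one bridge's anchor region
_ATTACH_SPAN = 0.15
# coupling taper along the bridge chain: full strength at the anchor end,
# decaying linearly to this floor at the far end
_TAPER_FLOOR = 0.20
# slope of the linear taper in units of relative chain position
_TAPER_STEEPNESS = 3.0


@dataclass(frozen=True)
class ModuleSpec:
    """One planted module: id, number of TFs, role, and (bridges) host core."""

    module_id: str
    size: int
    role: str
    attached_core: Optional[str] = None


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic cohort; bit-reproducible given ``seed``."""

    n_tfs: int
    n_samples_major: int
    n_samples_minor: int
    module_layout: Sequence[ModuleSpec]
    within_module_corr: Mapping[str, float] = field(
        default_factory=lambda: {"core": 0.95, "bridge": 0.85, "isolated": 0.30}
    )
    bridge_to_core_corr: float = 0.65
    n_subfactors: Mapping[str, int] = field(
        default_factory=lambda: {"core": 3, "bridge": 3, "isolated": 3}
    )
    differential_modules: frozenset[str] = field(default_factory=frozenset)
    effect_size: float = 1.0
    noise_sd: float = 0.0
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5
    # low-expression decoys: isolated-module genes with a strong *relative*
    # group shift but a small absolute amplitude, mimicking genes that a
    # per-gene differential test flags although they contribute almost
    # nothing to across-gene patient correlations
    n_decoys: int = 0
    decoy_effect: float = 2.0
    decoy_scale: float = 0.03
    decoy_baseline_mean: float = 1.0
    decoy_baseline_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_tfs <= 0 or self.n_samples_major <= 0 or self.n_samples_minor <= 0:
            raise ValueError("counts must be positive")
        if not self.module_layout:
            raise ValueError("module_layout is empty")
        total = sum(m.size for m in self.module_layout)
        if total != self.n_tfs:
            raise ValueError(f"module sizes sum to {total}, expected n_tfs={self.n_tfs}")
        ids = [m.module_id for m in self.module_layout]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate module ids")
        cores = {m.module_id for m in self.module_layout if m.role == "core"}
        for m in self.module_layout:
            if m.role not in ROLES:
                raise ValueError(f"unknown role {m.role!r}")
            if m.size <= 0:
                raise ValueError(f"module {m.module_id}: size must be positive")
            if m.role == "bridge":
                if m.attached_core is None or m.attached_core not in cores:
                    raise ValueError(f"bridge {m.module_id}: attached_core must name a core")
            elif m.attached_core is not None:
                raise ValueError(f"{m.module_id}: only bridges have attached_core")
        for role in ("core", "bridge", "isolated"):
            w = self.within_module_corr.get(role)
            if w is None or not (0.0 < w <= 1.0):
                raise ValueError(f"within_module_corr[{role!r}] must be in (0, 1]")
        if not self.within_module_corr["core"] > self.within_module_corr["bridge"]:
            raise ValueError("within_module_corr: core must exceed bridge")
        if not (0.0 < self.bridge_to_core_corr < self.within_module_corr["bridge"]):
            raise ValueError("bridge_to_core_corr must lie in (0, within_module_corr[bridge])")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be non-negative")
        if self.n_decoys < 0 or self.decoy_scale <= 0:
            raise ValueError("n_decoys must be >= 0 and decoy_scale > 0")
        n_isolated = sum(m.size for m in self.module_layout if m.role == "isolated")
        if self.n_decoys > n_isolated:
            raise ValueError("n_decoys exceeds the isolated-module gene count")
        unknown = self.differential_modules - {m.module_id for m in self.module_layout}
        if unknown:
            raise ValueError(f"differential_modules not in layout: {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated matrix."""

    tf_module_labels: list[str]
    patient_group_labels: list[str]
    latent_factors: pd.DataFrame  # module ids × sample ids (global factors)

    def labels_for(self, gene_ids: Sequence[str], all_gene_ids: Sequence[str]) -> list[str]:
        lookup = dict(zip(all_gene_ids, self.tf_module_labels))
        return [lookup[g] for g in gene_ids]


def default_spec(
    seed: int = 0,
    noise_sd: float = 0.0,
    differential_modules: frozenset[str] = frozenset({"red", "green", "magenta"}),
    effect_size: float = 1.0,
    n_decoys: Optional[int] = None,
) -> SyntheticSpec:
    """The study-condition cohort: 1,500 TFs × (127 + 21) samples, five modules.

    Module sizes mirror the observed five-cluster proportions of a
    1,531-TF tumor cohort scaled to 1,500: two cores ("red" 545, "cyan" 205),
    two bridges on the first core ("green" 292, "magenta" 67), and an
    unconnected remainder ("blue" 391).
    """
    layout = [
        ModuleSpec("red", 545, "core"),
        ModuleSpec("green", 292, "bridge", attached_core="red"),
        ModuleSpec("magenta", 67, "bridge", attached_core="red"),
        ModuleSpec("cyan", 205, "core"),
        ModuleSpec("blue", 391, "isolated"),
    ]
    return SyntheticSpec(
        n_tfs=1500,
        n_samples_major=127,
        n_samples_minor=21,
        module_layout=layout,
        differential_modules=frozenset(differential_modules),
        effect_size=effect_size,
        noise_sd=noise_sd,
        # decoy genes carry amplitude-scaled (hence non-isotropic) noise, so
        # the measurement-noise stress cohort omits them to keep its noise
        # exactly isotropic as the denoiser's model assumes
        n_decoys=(330 if noise_sd == 0 else 0) if n_decoys is None else n_decoys,
        seed=seed,
    )


def _chain_profile(h: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Interpolated, unit-variance local profiles for chain positions ``u``.

    ``h`` is (q, n) iid standard-normal sub-factors; returns (len(u), n).
    """
    q = h.shape[0]
    u = np.clip(u, 0.0, q - 1.0)
    i = np.minimum(u.astype(int), q - 2) if q > 1 else np.zeros(len(u), dtype=int)
    frac = u - i if q > 1 else np.zeros(len(u))
    w0 = (1.0 - frac)[:, None]
    w1 = frac[:, None]
    norm = np.sqrt((1.0 - frac) ** 2 + frac**2)[:, None]
    return (w0 * h[i] + w1 * h[np.minimum(i + 1, q - 1)]) / norm


def generate_planted_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one synthetic cohort from ``spec``.

    Randomness fans out from ``spec.seed`` into one independent substream per
    module, so resizing or re-rolling one module leaves the others untouched.
    """
    spec.validate()
    n = spec.n_samples_major + spec.n_samples_minor
    group_labels = ["4"] * spec.n_samples_major + ["4S"] * spec.n_samples_minor
    minority = np.array([g == "4S" for g in group_labels])
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(len(spec.module_layout))
    rngs = {m.module_id: np.random.default_rng(c) for m, c in zip(spec.module_layout, children)}

    # pass 1: per-module latent factors (own substream each).  Group
    # difference enters through the local sub-factors with per-factor
    # coefficients: a shift that were uniform across a module's genes would
    # be absorbed by per-sample centering in across-gene patient
    # correlations, so the differential signal must vary along the chain.
    factors: dict[str, dict[str, np.ndarray]] = {}
    for m in spec.module_layout:
        rng = rngs[m.module_id]
        q = int(spec.n_subfactors.get(m.role, 1))
        f = rng.standard_normal(n)
        h = rng.standard_normal((q, n))
        if m.module_id in spec.differential_modules and spec.effect_size > 0:
            # signed per-sub-factor coefficients: the group difference varies
            # along the chain, which keeps it visible to across-gene patient
            # correlations (a shift uniform over a module's genes would be
            # absorbed by per-sample profile centering)
            coeff = rng.standard_normal(q)
            h = h + spec.effect_size * coeff[:, None] * minority[None, :]
        factors[m.module_id] = {"f": f, "h": h}

    # bridges attached to each core, in layout order, get staggered regions
    bridges_of: dict[str, list[str]] = {}
    for m in spec.module_layout:
        if m.role == "bridge":
            bridges_of.setdefault(m.attached_core, []).append(m.module_id)

    values = np.empty((spec.n_tfs, n))
    labels: list[str] = []
    gene_ids: list[str] = []
    row = 0
    decoys_left = int(spec.n_decoys)
    for m in spec.module_layout:
        rng = rngs[m.module_id]
        w = float(spec.within_module_corr[m.role])
        q = int(spec.n_subfactors.get(m.role, 1))
        u = np.linspace(0.0, q - 1.0, m.size) if q > 1 else np.zeros(m.size)
        phi_own = _chain_profile(factors[m.module_id]["h"], u)
        f_own = factors[m.module_id]["f"]

        if m.role == "bridge":
            # tapered anchor attachment: bridge TFs near the chain start couple
            # strongly to one localized region of the host core (their "anchor"),
            # the rest keep mostly their own structure; total variance stays 1
            b = float(spec.bridge_to_core_corr)
            core = next(c for c in spec.module_layout if c.module_id == m.attached_core)
            q_core = int(spec.n_subfactors.get("core", 1))
            siblings = bridges_of[m.attached_core]
            pos = siblings.index(m.module_id)
            start = 0.0 if len(siblings) == 1 else pos * (1.0 - _ATTACH_SPAN) / (len(siblings) - 1)
            span = max(q_core - 1.0, 1e-12)
            rel = u / max(q - 1.0, 1e-12) if q > 1 else np.full(m.size, 0.5)
            u_map = (start + rel * _ATTACH_SPAN) * span
            phi_core = _chain_profile(factors[core.module_id]["h"], u_map)
            f_core = factors[core.module_id]["f"]
            taper = np.maximum(_TAPER_FLOOR, 1.0 - _TAPER_STEEPNESS * rel)
            v_couple = b * taper**2
            v_own = w - v_couple  # >= w - b > 0 by spec validation
            z = (
                np.sqrt(v_couple)[:, None]
                * (
                    np.sqrt(_BRIDGE_GLOBAL_FRAC) * f_core[None, :]
                    + np.sqrt(_BRIDGE_LOCAL_FRAC) * phi_core
                )
                + np.sqrt(_BRIDGE_OWN_GLOBAL_FRAC * v_own)[:, None] * f_own[None, :]
                + np.sqrt(_BRIDGE_OWN_LOCAL_FRAC * v_own)[:, None] * phi_own
            )
        else:
            z = (
                np.sqrt(_GLOBAL_FRAC * w) * f_own[None, :]
                + np.sqrt(_LOCAL_FRAC * w) * phi_own
            )
        idio = 1.0 - w
        if idio > 0:
            z = z + np.sqrt(idio) * rng.standard_normal((m.size, n))
        baseline = spec.baseline_mean + spec.baseline_sd * rng.standard_normal(m.size)
        amplitude = np.ones(m.size)
        if m.role == "isolated" and decoys_left > 0:
            n_dec = min(decoys_left, m.size)
            decoys_left -= n_dec
            dec = np.arange(n_dec)
            signs = rng.choice([-1.0, 1.0], size=n_dec)
            z[dec] = z[dec] + spec.decoy_effect * signs[:, None] * minority[None, :]
            baseline[dec] = (
                spec.decoy_baseline_mean
                + spec.decoy_baseline_sd * rng.standard_normal(n_dec)
            )
            amplitude[dec] = spec.decoy_scale
        if spec.noise_sd > 0:
            z = z + spec.noise_sd * rng.standard_normal((m.size, n))
        x = baseline[:, None] + amplitude[:, None] * z
        values[row : row + m.size] = x
        labels.extend([m.module_id] * m.size)
        gene_ids.extend(f"TF{row + i + 1:05d}" for i in range(m.size))
        row += m.size

    # affine shift into the non-negative range preserves all correlations
    low = values.min()
    if low < 0:
        values = values - low

    matrix = ExpressionMatrix(values, gene_ids, sample_ids, unit="tpm")
    latent = pd.DataFrame(
        {m.module_id: factors[m.module_id]["f"] for m in spec.module_layout},
        index=sample_ids,
    ).T
    truth = SyntheticTruth(labels, group_labels, latent)
    return matrix, truth


def generate_lowrank_noiseless(d: int, n: int, rank: int, seed: int) -> ExpressionMatrix:
    """A d × n matrix whose sample covariance has exactly ``rank`` nonzero
    eigenvalues — the reference fixture for denoising identity checks.

    Built as ``U diag(s) Q^T`` plus arbitrary row means, with orthonormal
    ``U`` (d × rank) and orthonormal, column-centered ``Q`` (n × rank); the
    covariance eigenvalues are exactly ``s_i^2 / (n - 1)``.
    """
    if rank < 1:
        raise ValueError("rank must be at least 1")
    if rank > min(n - 1, d):
        raise ValueError(f"rank {rank} exceeds min(n-1, d) = {min(n - 1, d)}")
    rng = np.random.default_rng(seed)
    u_mat, _ = np.linalg.qr(rng.standard_normal((d, rank)))
    g = rng.standard_normal((n, rank))
    g = g - g.mean(axis=0, keepdims=True)  # columns centered => span ⊥ ones
    q_mat, _ = np.linalg.qr(g)
    # distinct positive spectrum, descending
    sv = np.sqrt(np.arange(rank, 0, -1, dtype=float) * (n - 1))
    values = (u_mat * sv) @ q_mat.T
    values = values + (10.0 + rng.standard_normal(d))[:, None]
    gene_ids = [f"G{i + 1:04d}" for i in range(d)]
    sample_ids = [f"S{j + 1:03d}" for j in range(n)]
    return ExpressionMatrix(values, gene_ids, sample_ids, unit="arbitrary")


def write_truth(truth: SyntheticTruth, matrix: ExpressionMatrix, out_dir: str | Path) -> None:
    """Write the matrix as TSV plus truth sidecars (CSV) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(matrix, out / "expression.tsv")
    pd.DataFrame({"gene_id": matrix.gene_ids, "module": truth.tf_module_labels}).to_csv(
        out / "tf_modules.csv", index=False
    )
    pd.DataFrame(
        {"sample_id": matrix.sample_ids, "group": truth.patient_group_labels}
    ).to_csv(out / "patient_groups.csv", index=False)
    truth.latent_factors.to_csv(out / "latent_factors.csv")
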