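# Methods

## Pipeline

For a genes × samples matrix X (d TFs, n patients) the analysis flow is:
optional unit conversion (log2(1+FPKM) → TPM with per-sample renormalization
to 10⁶) → restriction to a transcription-factor list → denoising → Pearson
TF–TF correlations → binary adjacency aᵢⱼ = 1 iff corr ≥ cutoff (signed
rule, boundary inclusive, zero diagonal) → GTOM(k) → agglomerative
clustering of the dissimilarity 1 − t → per-module patient Spearman
networks and separation curves → annotation tables and graph exports.
Defaults: cutoff 0.7, k = 2, five clusters, Ward linkage, patient cutoffs
0.50–0.95.

## Denoising by eigenvalue shrinkage

The sample covariance S = (X − X̄)(X − X̄)ᵀ/(n−1) is eigendecomposed
(through the SVD of the centered matrix, so the cost is O(dn²) even for
d ≫ n); with PCA dimension D = min(n−1, d), the spectrum is modified to

λ̃ᵢ = λᵢ − mean(λᵢ₊₁, …, λ_D)  for i ≤ ℓ,  λ̃ᵢ = 0 for i > ℓ,

and the data are rebuilt with each principal direction scaled by
√(λ̃ᵢ/λᵢ) (0/0 → 0). Per-gene means are preserved exactly and the
covariance trace never increases. Negative shrunk values (an eigenvalue
below its own tail mean) are clipped to zero with a warning.

Two consequences of the formula worth knowing:

- On noiseless data of rank 1 with ℓ = 1 the map is the exact identity
  (the subtracted tail is empty of mass). For rank r > 1 the tail mean
  subtracted from a leading eigenvalue still contains the remaining
  *signal* eigenvalues, so the map perturbs even noiseless data by
  O(Σⱼ₌ᵢ₊₁ λⱼ/(D−i+1)) per component — vanishing as D grows, but not zero.
  The test suite asserts the exact rank-1 identity and the bounded
  perturbation at higher rank.
- Genes whose total variance sits far below the noise floor are projected
  almost entirely onto the retained components; if they share any retained
  direction (for example a group-difference direction) they emerge from
  denoising strongly mutually correlated. This is a real artifact of
  aggressive spectrum truncation, and the reason the noise-stress cohort
  below contains no low-amplitude decoy genes.

**Choosing ℓ.** The number of signal components is selected as the largest
i < D whose eigenvalue exceeds the mean of its trailing eigenvalues by the
factor (1 + √(n/d))². Under the low-rank-plus-isotropic-noise model this
factor is exactly the ratio of the Marchenko–Pastur bulk edge to the bulk
mean, so components above the bar are inconsistent with pure noise. The
rule recovers the exact rank on noiseless low-rank data, and on the default
noisy synthetic cohort selects ℓ ≈ 18–20, matching the cohort's true latent
dimension (20). A fixed ℓ can always be supplied instead; the selected
value is logged.

## GTOM and network scores

N_{k+1}(i) is the set of nodes (excluding i) within graph distance k+1,
computed by boolean adjacency expansion with early termination (float32
matrix products against BLAS; counts stay below 2²⁴ so the arithmetic is
exact, and the implementation is tested for exact equality against a
brute-force BFS-set oracle). The overlap matrix, group score (mean tᵢⱼ
over ordered cross pairs), group difference (within minus cross), and the
composite score

S_k = (1/d_C) Σ_{i<j} rᵢ rⱼ [G(i,i)G(j,j)(1−G(i,j)) + G(i,i)(1−G(j,j))G(i,j)]

follow the printed formulas. The second S_k term is asymmetric in (i, j);
the package fixes the cluster order canonically (descending size), which
makes the score deterministic; a symmetrized variant is available behind a
flag. Isolated pairs score 0 (denominator 1); the diagonal is 1.

## Module detection

Clustering is scipy agglomerative linkage on the condensed 1 − t matrix.
Ward is the default (accepting, as is common in coexpression practice, a
non-Euclidean dissimilarity); average linkage is available. Labels are
canonicalized by descending cluster size. Cluster-count diagnostics report
the mean silhouette width on 1 − t; the count itself is a configuration
choice. The parameter scan evaluates every (cutoff, k, n_clusters) grid
point — default grid 0.50–0.90 in steps of 0.02, k ∈ {0,1,2,3},
n_clusters ∈ {4,5} — recording S_k and the population standard deviation of
cluster sizes; good operating points combine high S_k with low size SD.

## Patient separation

For a TF subset, patients are correlated by Spearman (average ranks for
ties) across those TFs and thresholded over a cutoff grid. The separation
score is evaluated directly on the adjacency (edge densities): group A is
stage 4, and the score is within-4 density minus 4↔4S cross density. A
first-order-overlap variant and a symmetric variant exist for sensitivity
checks. Baselines: the Q3 filter keeps genes whose median expression is
strictly above the 25th percentile of per-gene medians
(linear-interpolation quantile; with all-distinct medians exactly 75%
survive), and the differential-expression subset is a Welch t-test on
log1p values with Benjamini–Hochberg control — a deliberately light
stand-in for count-based tools, which can also accept an externally
computed gene list verbatim.

## The synthetic cohort

The generator emulates the statistical shape of a ~1,500 TF × ~150 tumor
cohort. Default layout (sizes scaled from a five-cluster decomposition of a
1,531-TF cohort): cores "red" (545) and "cyan" (205), bridges "green" (292)
and "magenta" (67) attached to red, isolated pool "blue" (391); patients
127 stage-4 + 21 stage-4S; differential modules {red, green, magenta}.

Each module carries a global factor plus a short chain of q = 3 local
sub-factors; a TF at chain position u sees an interpolated, unit-variance
local profile, so within-module correlation decays smoothly with chain
distance (peak w = 0.95 for cores, 0.85 for bridges, 0.30 for the isolated
pool; shared variance split 44/56 between global and local). This graded
"band" structure is the load-bearing design choice: a pure one-factor
module yields threshold graphs whose (k+1)-step neighborhoods saturate the
whole connected component, making every within-component overlap ≈ 1 and
bridges indistinguishable from their core at any k ≥ 1. With the chain
geometry (edge band ≈ 0.4 of the chain span), three-step neighborhoods
just saturate a module while one-step neighborhoods do not — exactly the
regime in which GTOM(2) + Ward recovers the planted partition
(mean adjusted Rand index ≈ 0.95 over ten cohorts) while GTOM(0) + Ward
does not (≈ 0.69–0.81). Setting q = 1 and w = 1 collapses the model to a
single noiseless common factor (all |r| = 1), the degenerate case used in
tests.

Bridges couple to one localized region of their host core through an
anchor construct (a 60/40 mix of the core's global factor and its local
profile at the attachment region, total coupling share b = 0.65) tapered
linearly along the bridge chain (slope 3, floor 0.2): only the anchor-end
bridge TFs cross a 0.7 correlation threshold against the core, so the
bridge is a weakly attached satellite, not a core annex.

The two-group difference enters through the local sub-factors of the
differential modules, each shifted for minority samples by effect size
(default 1.0) times a signed standard-normal coefficient. The shift must
vary across a module's genes: across-gene patient correlation centers each
patient's profile, so a shift uniform over the subset separates nothing —
this is why the group difference lives in the local factors.

The default noiseless cohort additionally contains 330 low-expression
"decoy" genes in the isolated pool: amplitude 0.03 of a normal gene, low
baseline, and a strong shift *relative to their own amplitude*. A per-gene
differential test flags them prominently (test statistics are
scale-invariant) although they contribute almost nothing to across-gene
patient correlations — emulating low-expression genes that count-based
differential tools report but that carry no usable co-variation, which is
the regime in which module-based selection outperforms a
differential-expression gene list. The median-based Q3 filter removes
exactly these genes, as it is designed to. The measurement-noise stress
cohort (noise_sd = 0.5, used for denoising experiments) omits decoys so
that its noise is exactly isotropic, as the denoiser's model assumes.

Observed values are per-gene baseline (N(5, 1.5²)) plus the standardized
signal plus N(0, noise_sd²) noise, scaled by the per-gene amplitude and
affinely shifted into the non-negative range; the affine shift preserves
all planted correlations exactly. Randomness fans out from one seed into
per-module substreams, so resizing one module leaves the others bit-
identical.

What the generator does *not* emulate: read counts and library-size
effects, batch structure, heavy-tailed expression distributions, the full
31,849-gene transcriptome, and count-scale differential-expression
behavior. Passing tests therefore demonstrate the pipeline's correctness
and its qualitative claims under a Gaussian latent-factor model, not
performance guarantees on sequencing data.

## Evaluation conventions and problem sizes

Module-recovery and separation experiments run at the full study scale
(1,500 × 148) over ten cohorts (seeds 0–9 in the test suite); denoising
experiments over twenty. Separation curves are compared by their mean over
the upper half of the patient-cutoff grid (0.75–0.95), the regime in which
clique persistence distinguishes gene subsets whose correlation scales
differ; each differential module must beat the equal-size null module and
permuted labels, and the differential modules collectively (their mean)
must beat the Q3 and differential-expression baselines, whose curves live
at opposite ends of the cutoff range. The permutation check uses 100
label shuffles and requires the mean within two standard errors of zero.

## Known limitations

- Ward linkage on 1 − t is not Euclidean-consistent; it is the field's
  convention and is treated as such.
- The composite score S_k is used as printed, including its asymmetric
  second term; conclusions could shift under a symmetrized definition
  (available as an option).
- The ℓ-selection rule assumes isotropic noise; strongly heteroscedastic
  noise (e.g., the decoy channel) violates it, and denoising then distorts
  near-constant genes (see above).
- The differential-expression stand-in is a two-sample t-test on the same
  matrix; it is a baseline for synthetic experiments, not a replacement for
  count-based differential analysis on real data.
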