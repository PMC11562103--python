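# gtomnet

Gene coexpression network analysis for distinguishing patient groups —
built around three ingredients:

1. **RECODE-style denoising**: PCA eigenvalue shrinkage for
   high-dimensional expression matrices (d genes ≫ n samples), where each
   retained eigenvalue λᵢ is reduced by the mean of its trailing
   eigenvalues and the rest are zeroed — the trailing mean estimates the
   isotropic-noise inflation of the leading components.
2. **GTOM(k)**, the generalized topological overlap measure: similarity of
   two network nodes based on their shared (k+1)-step neighborhoods,

   t⁽ᵏ⁾ᵢⱼ = (|N_{k+1}(i) ∩ N_{k+1}(j)| + aᵢⱼ) / (min(|N_{k+1}(i)|, |N_{k+1}(j)|) + 1 − aᵢⱼ),

   followed by Ward clustering of the dissimilarity 1 − t into TF modules.
3. **Patient-network separation scoring**: for any TF subset, a Spearman
   patient–patient correlation graph is thresholded over a cutoff range and
   scored by GTOMdiff₀(A, B) = within-A edge density − A↔B cross density,
   quantifying how well the subset separates two patient groups (e.g.
   metastatic stage-4 versus spontaneously regressing stage-4S
   neuroblastoma).

The motivating application is neuroblastoma transcription-factor (TF)
networks: ~1,500 TFs over ~150 tumors, where the interesting biology sits
in *intermediate-scale* modules — satellites weakly attached to a core
network — that plain adjacency-based clustering cannot isolate. A composite
score S_k over the cluster-pair GTOM scores, together with the standard
deviation of cluster sizes, drives the choice of correlation cutoff and
overlap order k.

Because the original tumor cohorts are access-controlled, the package ships
a first-class **synthetic cohort generator** that plants known module
topology (two cores, two bridge satellites, an unconnected remainder) and a
known two-group difference, so every stage of the pipeline can be tested
against ground truth.

## Worked example

```python
import gtomnet as gn
from sklearn.metrics import adjusted_rand_score

# simulate a 1,500-TF x 148-patient cohort with five planted modules
x, truth = gn.generate_planted_expression(gn.default_spec(seed=0))

# network: Pearson -> adjacency at 0.7 -> GTOM(2) -> Ward, five clusters
corr = gn.correlation_matrix(x)
adj = gn.adjacency_from_correlation(corr, cutoff=0.7)
t = gn.gtom(adj, k=2)
part = gn.cluster_gtom(t, n_clusters=5)
print("cluster sizes:", list(part.sizes))
print("ARI vs planted modules:",
      round(adjusted_rand_score(truth.tf_module_labels, part.labels), 3))

g = gn.cluster_score_matrix(t, part)
print("total score S_2:", round(gn.total_score(g, part.ratios), 4))

groups = gn.PatientGroups(dict(zip(x.sample_ids, truth.patient_group_labels)))
red = [gid for gid, lab in zip(x.gene_ids, truth.tf_module_labels) if lab == "red"]
curve = gn.separation_curve(x, red, groups, [0.80, 0.85, 0.90], name="red")
print("red-module separation at 0.80/0.85/0.90:",
      [round(s, 3) for s in curve.separation])
```

Output:

```
cluster sizes: [564, 391, 292, 205, 48]
ARI vs planted modules: 0.974
total score S_2: 0.0145
red-module separation at 0.80/0.85/0.90: [0.385, 0.428, 0.381]
```

The five detected clusters recover the planted layout almost exactly
(adjusted Rand index 0.974; the 545-TF core gains a few anchor TFs from its
satellites). The red module — planted as group-differential — separates the
two patient groups clearly at high correlation cutoffs: its within-group-4
edge density exceeds the cross-group density by ≈ 0.4, while a module with
no planted group difference scores near zero.

A command-line interface mirrors the library
(`gtomnet simulate | recode | network | scan | cluster | separate | run`);
`gtomnet run --config cfg.json` executes the full flow — input → unit
conversion → TF restriction → denoising → TF network → module detection →
patient separation → annotated exports — and writes a checksummed manifest.

## Layout

- `src/gtomnet/synthetic.py` — planted-module cohort generator (ground truth).
- `src/gtomnet/recode.py` — PCA eigenvalue-shrinkage denoiser.
- `src/gtomnet/gtom.py` — correlations, adjacency, GTOM(k), network scores.
- `src/gtomnet/modules.py` — Ward module detection, silhouette diagnostics,
  (cutoff, k, n_clusters) parameter scan.
- `src/gtomnet/separation.py` — patient networks, separation curves, Q3 and
  differential-expression baselines.
- `src/gtomnet/annotate.py` — signature counts, partition cross-tabulation,
  clinical overlays.
- `src/gtomnet/expression.py`, `pipeline.py`, `cli.py` — I/O, orchestration,
  CLI.
- `docs/methods.md` — the model, parameter choices, and limitations.
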