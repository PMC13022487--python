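# protoseg

Unsupervised segmentation of high-dimensional plasma-proteomic cohorts,
with downstream disease-association analyses.

Population-scale affinity proteomics (Olink-style NPX panels) measures
thousands of plasma proteins per participant. Two features of these
matrices defeat naive clustering: *structured missingness* (panels measured
together are missing together, whole delivery batches drop out) and sheer
dimensionality. `protoseg` implements two complementary clustering paths
over a participants × proteins abundance matrix, plus the analyses that
turn the resulting clusters into disease biology, for epidemiologists and
computational biologists working with biobank-scale proteomics.

## The two clustering paths

**DIRAM** (dimensionality reduction with avoidance of missing values)
never imputes. Proteins are grouped by the Jaccard similarity of their
missing-value masks (single linkage at a threshold); dropping the few
incomplete rows inside each group yields complete subdatasets. Each
subdataset is embedded to 2-D with UMAP, clusters are detected with DBSCAN
(clusters outside a size window [100, 20 000] become noise), and clusters
from different subdatasets containing largely the same participants are
merged: for clusters C₁, C₂ over a shared universe of N participants, with
expected overlap E = |C₁||C₂|/N under independence and observed overlap O,
the pair is merged when (O − E)/min(|C₁|,|C₂|) > 0.4.

**DIRCOD** (dimensionality reduction with community detection) imputes
missing entries by nearest-neighbour averaging (k = 15), then alternates:
(1) Leiden community detection on a 15-nearest-neighbour participant graph
restricted to the current protein subset; (2) per (community, protein), a
two-sample Kolmogorov–Smirnov test on the *raw, non-imputed* values inside
vs outside the community, Bonferroni-corrected, keeping the proteins
significant in at least one community. After T = 20 iterations (no
convergence is assumed), participants whose community-assignment patterns
agree in ≥ 90% of iterations are grouped into final clusters.

## Downstream analyses

* **Abundance calls** — a protein is *high* in a cluster iff the cluster's
  25th percentile strictly exceeds the 75th percentile of everyone else
  (Q1ᵢₙ > Q3ₒᵤₜ); *low* is the mirror image. Conservative by design.
* **Cluster recreation** — pool the disease-associated clusters, take each
  signature protein's in-cluster percentile value as a population-wide
  cutoff, and report the odds ratio of disease in the selected population
  per percentile, with leave-one-out curves quantifying each protein's
  contribution.
* **Principal-axis gradient** — collapse the signature to the first
  principal axis fitted on the pooled clusters, bin the population into
  equal-size groups by axis coordinate, and regress per-bin disease
  prevalence on bin position (extreme bins excluded).
* **Differential correlation** — Δ = corr(within group) − corr(rest) on
  pairwise-complete non-imputed values, with the Bonferroni critical |r|
  for the relevant sample size.
* **Characterization** — per-cluster ICD-10 enrichment (Fisher exact,
  Bonferroni, Woolf CIs with Haldane–Anscombe zero-cell correction), age
  (Mann–Whitney) and sex (χ²) contrasts.

A built-in synthetic-cohort generator plants latent clusters (mean shifts
on protein subsets), block-structured missingness, cluster-dependent
disease odds and within-cluster coregulation, so the whole pipeline is
testable without access-restricted cohort data.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from protoseg import (SyntheticConfig, DiseaseSpec, generate_cohort, run_dircod,
                      call_abundance_all, common_signature, recreate,
                      disease_enrichment)

cfg = SyntheticConfig(
    n_participants=2000, n_proteins=60, n_clusters=3,
    shift_proteins_per_cluster=15, shift_magnitude=3.0,
    random_missing_fraction=0.05,
    disease_spec=[DiseaseSpec("K90", 0.05, [4.0, 1.0, 1.0])],
    seed=7,
)
matrix, phenotypes, truth = generate_cohort(cfg)

result = run_dircod(matrix, T=10, seed=7)
labels = result.assignment
print(labels.sizes())
# {'B3': 654, 'B2': 668, 'B1': 678}
true = [truth[p] for p in matrix.participant_ids]
print(adjusted_rand_score(true, list(labels.label_vector(matrix.participant_ids))))
# 1.0  -- the three planted clusters are recovered exactly

for r in disease_enrichment(labels, phenotypes, ["K90"]):
    print(r.cluster_id, round(r.odds.value, 2), r.p_bonferroni)
# B1 4.91 4.8e-22   <- the cluster carrying the planted 4x disease odds
# B2 0.35 1.9e-07
# B3 0.36 4.5e-07

members = labels.members("B1")
calls = call_abundance_all(matrix, {"B1": members})
sig = [(p, "high") for p in common_signature(calls, ["B1"], "high")[:4]]
curve = recreate(matrix, phenotypes, members, sig, "K90",
                 percentile_grid=[10, 25, 50])
for pt in curve.points:
    print(pt.percentile, pt.selected_n, round(pt.odds.value, 2))
# 10 356 2.65
# 25 159 2.55
# 50  30 4.60  -- stricter slicing concentrates the disease
```

The enrichment output reads: participants in cluster B1 have 4.9× the odds
of carrying code K90 relative to everyone else. The recreation curve shows
that thresholding the *whole* population on the cluster's own protein
signature re-selects a disease-enriched subpopulation — evidence the
signature, not the clustering artifact, carries the association.

A command-line interface mirrors the library
(`protoseg synth|missingness|diram|dircod|abundance|recreate|axis|diffcorr|characterize|run`);
`protoseg run --config run.yaml` executes a multi-stage pipeline with one
global seed, per-stage derived seeds, and a manifest of input/output
hashes.

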