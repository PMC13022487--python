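# Methods

This note records the models and procedures `protoseg` implements, the
parameters that matter, the numerical choices that were genuinely open,
and what the synthetic benchmarks do and do not establish.

## Data model

A cohort is a participants × proteins matrix of continuous abundances
(NPX-like, i.e. approximately normal on a log scale) with an explicit
boolean observation mask, plus a phenotype table with age (years), binary
sex, and a set of 3-character ICD-10 codes per participant. Missing cells
are stored as NaN and additionally tracked by the mask; every analysis
either excludes them (abundance, correlation, selection tests) or imputes
them explicitly (DIRCOD's community-detection step only). ICD-10 codes are
normalized by uppercasing and truncating to letter + two digits; coarser
user-supplied super-category groupings can be layered on top but none is
hard-coded, since no canonical grouping table exists at that level.

## Missingness grouping (DIRAM preprocessing)

Structured missingness in multiplex panels is block-shaped: proteins
measured on a common plate/panel are missing for a common participant set.
We group proteins whose *missing-entry sets* have Jaccard similarity ≥ a
threshold (default 0.5), with single-linkage transitivity; proteins with
no missing value form one shared complete group, all-missing proteins are
discarded and reported. Jaccard was chosen over correlating missingness
indicator columns because it is scale-free and exactly 1 for identical
masks, the case the block model predicts; the threshold and linkage are
exposed because the precise notion of "similar" masks is a modelling
choice, not a fact about the data. Within each group, participants with
any missing value on the group's proteins are dropped, giving a dense
complete subdataset. Completeness is asserted on every extraction. Groups
retaining fewer participants than the minimum admissible cluster size
(default 100) are flagged degenerate and skipped by DIRAM: they cannot
contribute an admissible cluster.

## DIRAM

Each complete subdataset is embedded to two dimensions with UMAP at
library defaults except the random seed. Because the embedding is a
stochastic optimisation, an optional audit re-embeds under several seeds,
density-clusters each embedding, and reports the distribution of pairwise
adjusted Rand indices; a median below 0.5 logs a warning. The audit is a
report, not an automatic rejection — judging whether a projection is
trapped in a bad optimum is left to the analyst.

Clusters are detected with DBSCAN. The reference configuration is
`eps = 0.1, min_samples = 10` with cluster sizes restricted to
[100, 20 000]; out-of-window clusters are relabeled noise. A fixed radius,
however, encodes a specific point density: the embedding of an n-times
smaller cohort is roughly √n-times sparser, and a radius tuned at one
scale shatters clusters at another (measured directly: on a 3 000 × 120
four-cluster benchmark, eps = 0.1 yields ARI 0.21 while any radius from
0.2 to 0.8 yields ARI 1.0). We therefore provide `eps="auto"`: twice the
median distance to the `min_samples`-th nearest neighbour, the classical
k-distance heuristic. At the benchmark scale this lands at ≈ 0.22 and
recovers the planted clusters exactly; it is the recommended setting for
cohorts far from the reference density.

Clusters found in different subdatasets are merged when they contain
largely the same participants. Over the shared universe (participants
retained by both subdatasets, size N), the expected overlap of C₁ and C₂
under independence is E = |C₁||C₂|/N; the merge score is
(O − E)/min(|C₁|, |C₂|) and pairs scoring above the margin (default 0.4)
merge, transitively via union–find. Min-normalization makes the score
0 in expectation for independent clusters and 1 − E/min for identical
ones; `union` and `geometric` denominators are available because the
"difference greater than 40%" rule admits several readings. A participant
claimed by several merged clusters is assigned to the one backed by the
most source clusters (ties by label order) so final labels are disjoint.

## DIRCOD

Missing entries are imputed as the mean of the protein over the k = 15
nearest participants that observed it; distances are Euclidean over all
proteins with mean-filled missing cells (distance computation only).
A protein observed in fewer than k participants is a hard error. On
rank-structured data this beats column-mean imputation (verified on
rank-1-plus-noise simulations), which is all it needs to do — imputed
values feed only the graph construction, never a reported statistic.

Each iteration builds a 15-nearest-neighbour participant graph on the
imputed matrix restricted to the current protein subset and partitions it
with Leiden (RB configuration, resolution 1.0, fixed seed). The resulting
communities are then contrasted on the raw matrix: per (community,
protein), a two-sample Kolmogorov–Smirnov test of observed values inside
vs outside, Bonferroni over all pairs tested; proteins significant in at
least one community survive to the next iteration. The exact KS null
distribution is used when the smaller sample is ≤ 250 (where the
asymptotic approximation is weakest and the exact computation cheap), the
asymptotic one otherwise. Pairs with fewer than 20 observed values on a
side are skipped. KS was chosen because the claim being tested is
"different distribution", not "different mean"; the raw-data validation
bounds any bias the imputation could introduce.

The iteration is run T = 20 times and is *not* assumed to converge; the
history is the output. Final clusters group participants with similar
patterns of community assignment: co-assignment similarity = fraction of
iterations sharing a community, link pairs at ≥ 0.9, take connected
components, relabel components smaller than the minimum size (default
100) as noise. Community labels are never matched across iterations —
only co-membership matters — which sidesteps the label-alignment problem
entirely. Exact pattern matching is available as threshold 1.0; the 0.9
default tolerates single-iteration label churn that exact matching would
amplify into cluster fragmentation.

## Abundance rule

A protein is *high* in a cluster iff the cluster's 25th percentile
strictly exceeds the 75th percentile of all other participants, *low* in
the mirror case, else no call. Percentiles are linear interpolation
between closest ranks — the convention is fixed and documented because
near-boundary verdicts depend on it. Ties at the boundary yield no call
(the rule is deliberately conservative), fewer than 20 observed values on
either side yields no call with a flag, and missing values are excluded,
never imputed. The rule is invariant to adding a constant to a protein
column and monotone under raising in-cluster values; both properties and
equivalence to a direct order-statistic implementation are tested.

Common signatures across a cluster set admit a tolerance: a protein may
miss the verdict in at most `tolerance` clusters (tolerance 1 feeds the
correlation analysis; tolerance 0 is the default).

## Cluster recreation

The disease-associated clusters are pooled; for each signature protein
the selection threshold at percentile q is the q-th percentile of the
protein's observed values *inside the pool*, applied to the whole
population (≥ for high-direction proteins, ≤ for low). Filtering is
conjunctive across proteins by default (a disjunctive mode exists behind
a flag): the odds-ratio curve then reflects progressively stricter
signatures. Participants missing a signature value cannot satisfy that
protein's filter and count as unselected; an alternative flag drops them
from the 2×2 table entirely. Note that under conjunction with many
mutually independent proteins the selected set shrinks geometrically with
signature size — with real (correlated) signatures the selection decays
much more slowly, so empty selections at high percentiles on synthetic
independent-noise data are expected, flagged, and not an error.

Odds ratios are (a·d)/(b·c) with a Woolf (log-OR normal) 95% CI and the
Haldane–Anscombe +0.5 correction when a cell is zero; an empty margin
makes the OR undefined and flagged, never silently zero. Leave-one-out
reruns the recreation once per omitted protein; since omission removes a
conjunctive constraint, every leave-one-out selection is a superset of
the full-signature selection (asserted at every percentile), and the
delta-OR curve measures the omitted protein's contribution.

## Principal-axis gradient

The signature submatrix is centered and (by default) standardized on the
pooled-cluster fitting population — the proteins are on different scales,
and standardization keeps a single high-variance protein from owning the
axis; a flag disables it. The axis is the leading eigenvector of the
fitting population's covariance, sign-fixed so the first signature
protein loads nonnegatively. The same transform is applied to the target
population; rows missing a signature value are excluded and logged.
Participants are binned into equal-size groups (sizes differ by at most
one; coordinate ties broken by participant ID for determinism) and
per-bin prevalence is regressed on the bin's mean coordinate by OLS,
excluding the first and last bins by default because extreme-bin
prevalences are the noisiest. The size-weighted mean of bin prevalences
equals the overall prevalence exactly — asserted, not approximated.
Default 20 bins.

## Differential correlation

Candidates (a common signature at tolerance ≤ 1) are first screened:
a protein is kept iff its |Pearson r| with some other candidate reaches
0.8, computed on pairwise-complete observations over the full population
(the screening population is configurable). Then A = correlations within
the group, B = correlations among everyone else, Δ = A − B, all Pearson
on pairwise-complete non-imputed values (Spearman behind a flag). Pairs
with fewer than 30 observations on either side, or involving a protein
constant on one side, are masked (NaN) and reported. The Bonferroni
critical correlation inverts the t-transform
t = r√((n−2)/(1−r²)): r* = t*/√(t*² + n − 2) with t* the two-sided
α/m critical value at n − 2 degrees of freedom; it is strictly decreasing
in n and increasing in m, and matches a permutation-null quantile within
Monte-Carlo error (tested at 10⁵ permutations).

## Characterization

Per (cluster, code): Fisher's exact test on the 2×2 membership × diagnosis
table, Bonferroni over all pairs tested in the call (one family per
analysis), OR with Woolf CI and Haldane–Anscombe correction for zero
cells — the p-value always uses the raw counts. Optional sex
stratification repeats the analysis within each sex. Demographics: per
cluster, Mann–Whitney U on age and χ² on sex composition against all
other participants, Bonferroni within each family, plus the minority-sex
fraction. The tests are conventional choices for these data types and are
deliberately pluggable; clusters under 10 members are skipped.

## Synthetic cohorts

The generator draws i.i.d. standard-normal baselines (the simplest model
consistent with log-scale NPX data) and plants, per configuration:

* **clusters** — multinomial membership with given proportions; cluster c
  adds `shift_magnitude` (SD units, default 3) to its own contiguous
  block of `shift_proteins_per_cluster` proteins;
* **block missingness** — each block masks a random disjoint protein
  subset for one shared random participant fraction, so masks are
  identical across the block's proteins; a batch dropout masks the
  trailing contiguous protein block for a participant fraction (a whole
  delivery batch failing);
* **disease** — per-participant Bernoulli with logistic odds:
  baseline-prevalence odds times a per-cluster multiplier (and optionally
  an age effect); the empirical OR of membership therefore targets the
  multiplier, which the tests verify by Monte Carlo;
* **coregulation** — inside one cluster, the trailing protein subset is
  rebuilt as xᵢ = √ρ·z + √(1−ρ)·eᵢ from a shared factor, giving exact
  pairwise correlation ρ;
* ages uniform on 40–70 years, sex balanced, both independent of cluster
  by default.

The same seed yields a bit-identical cohort. The default benchmark
configuration (n = 3 000, p = 120, 4 equal clusters, 3-SD shifts over 30
proteins each) makes clusters linearly separable with probability near 1
while keeping full pipeline runs under a minute each; the problem sizes
used throughout the tests and the acceptance script are stated there and
were chosen as the smallest at which the targeted effects are
unambiguous. What passing these benchmarks does *not* show: robustness to
heavy-tailed or skewed abundances, detection-limit censoring, plate
effects, correlated baseline structure between non-signature proteins, or
cluster shapes that are not mean shifts. The generator deliberately omits
assay chemistry; it emulates the statistical structure the algorithms
exploit, nothing more.

## Determinism and seeds

Every stochastic step (cohort draw, UMAP, Leiden, audit seeds) takes an
explicit seed. The pipeline runner derives per-stage seeds by CRC-hashing
(global seed, stage name), so stages are reproducible in isolation and
decorrelated from one another; two runs with the same config and seed
produce byte-identical data files (asserted in the tests). Output files
carry `#` provenance headers without timestamps for exactly this reason.

## Known limitations

* The merge rule's quadratic pairwise scan over clusters is fine for the
  dozens of clusters the method produces, not for thousands.
* Pattern assignment materializes an n × n co-assignment matrix; at
  biobank scale (n ≈ 5 × 10⁴) this needs ~20 GB and would want a sparse
  or chunked implementation.
* KNN imputation falls back to the column mean for a missing cell whose
  near neighbours all miss the same protein; with strongly block-missing
  data DIRCOD therefore leans toward column-mean behaviour exactly where
  the data are least informative (the raw-data validation step exists to
  bound the damage).
* The critical-correlation threshold assumes bivariate normality through
  the t-transform; the permutation cross-check covers the null but not
  robustness to heavy tails.
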