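# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic cohorts do and do
not emulate, and the numerical conventions that make every run
bit-reproducible.

## Differential expression and the core set

Each pairwise tissue contrast (NN-vs-PN, PN-vs-PP, NN-vs-PP) applies a
Welch unequal-variance *t*-test per gene with two-sided asymptotic *p*
(Welch–Satterthwaite degrees of freedom). The test family is a
deliberate choice: expression values are log2-scale and approximately
Gaussian per group, group variances are not assumed equal, and a
signal-to-noise alternative would only change the ranking, not the
selection logic. Tests are unpaired even for PN/PP, which come from the
same patients: the pipeline treats each contrast as a two-group
comparison; a paired mode would gain power but is not the default.

Selection composes three published filters in their strictest order:
keep genes with *p* < α (default 0.05) **and** BH *q* < FDR (default
0.05), then truncate to the `de_top_k` (default 5000) smallest *p*.
BH *q*-values use the step-up rule *q*₍ᵢ₎ = min₍ⱼ≥ᵢ₎ *p*₍ⱼ₎·m/j clipped
at 1; constant genes are excluded from testing and logged. Probe-level
matrices are collapsed to genes by arithmetic row averaging before or
after testing, at the caller's discretion; the probe→gene map is an
input, since annotation releases differ.

The **core set** is the probe-level intersection of the three pairwise
selections, with each gene's direction taken from the NN-vs-PP contrast.
Note a structural property of the three-way intersection at modest
effect sizes: a per-gene shift of ~0.5 noise-sd between NN and PN (the
emulated "non-lesional tissue is nearly normal" gradient) sits below the
BH step-up's detection cascade at m = 1000 and n ≈ 35 per group, so the
intersection is legitimately small in synthetic cohorts. The pipeline
therefore carries the **lesional signature** — the NN-vs-PP selected
set — as the working gene set for downstream supervised and unsupervised
stages; it contains every gene with lesional-specific behaviour,
including genes that differ *between* lesional subgroups and hence
cannot appear in all three contrasts. The core intersection is still
computed, reported and exported.

z-scores standardize each gene against the NN reference columns (sample
sd, n−1); PCA centers genes and projects samples onto the top
eigenvectors with a deterministic sign convention (largest-magnitude
loading positive); hierarchical ordering of genes uses complete linkage
on Euclidean distances (scipy's deterministic merge ordering).

## The tree ensemble

`GiniForestClassifier` is a from-scratch CART forest with fully
deterministic behaviour:

* **Subsampling.** Each tree trains on a stratified per-class fraction
  (default ⅔, drawn *without* replacement; `bootstrap=True` gives the
  classical per-class bootstrap). The literal-⅔ reading is used because
  the emulated protocol trains on two-thirds and tests on the remaining
  third; at 63.2% vs 66.7% in-bag the OOB estimates are practically
  indistinguishable.
* **Splitting.** At each node `mtry` features (default ⌊√p⌋, the
  classification convention) are drawn without replacement; candidate
  thresholds are midpoints of consecutive distinct sorted values; the
  split maximizing the Gini decrease
  G(parent) − (n_L·G_L + n_R·G_R)/n wins, ties resolved to the lowest
  feature index, then the lowest threshold. Trees grow to purity
  (`min_node_size=1`).
* **Randomness.** All per-tree randomness flows through splitmix64
  counters seeded from a `SeedSequence`, so fitted models, OOB votes and
  importances are bit-identical across runs and platforms and
  independent of execution order. The kernels are numba-compiled; a
  1000-tree forest on 108 × 1000 data fits in well under a second.
* **OOB evaluation.** Each sample is predicted by majority vote over the
  trees in which it was out-of-bag (ties to the lowest class index).
  With 1000 trees at ⅓ OOB probability, the chance a sample is never
  OOB is (2/3)¹⁰⁰⁰ ≈ 10⁻¹⁷⁶; coverage is asserted and any uncovered
  sample is excluded and reported.
* **Importances.** GI importance accumulates
  (n_node/n_inbag) × Gini decrease per split, averaged over trees; a
  single tree grown to purity on the full sample therefore satisfies the
  conservation identity Σ_f GI(f) = root impurity (tested). Per-class
  importance is per-class mean decrease in OOB accuracy — the quantity
  per-class importance conventionally reports — because Gini importance
  has no standard per-class decomposition; permutations are seeded per
  (tree, feature), and features a tree never uses contribute exactly 0.
* **Permutation null.** The max-T scheme permutes labels B times,
  refits, and records max_f GI_b(f); the empirical
  p(f) = (1 + #{b : max_b ≥ GI_obs(f)})/(B + 1) is familywise-adjusted
  and bounded away from 0 by the add-one convention. Under exchangeable
  null labels the top gene's p is uniform on its grid (checked by KS
  test in the acceptance suite).

## Unsupervised stratification of lesional samples

The stratifier follows the addcl-style recipe: a synthetic reference of
equal size is drawn from the real data's per-gene empirical marginals —
default `marginal_permutation`, which preserves each gene's value
multiset exactly; `marginal_resample` (with replacement) is available —
and a forest learns to separate real from synthetic. Only dependence
*between* genes distinguishes the two, so the real–real proximity block
measures how often two samples co-occur in leaves carved along genuine
co-variation. The dissimilarity is √(1 − proximity) by default
(Euclidean-friendlier for MDS; plain 1 − proximity is available and
induces the same pair ordering).

Two preprocessing steps precede the forest, both standard for subtype
discovery and both exposed as parameters:

* **Per-sample median centering** (`center="median"`). Whole-sample
  offsets — array effects, or the per-subject random effect the
  generator plants — are dependence shared by *all* genes; without
  centering the real-vs-synthetic forest learns that offset and
  proximity reflects per-sample level rather than subtype. Centering
  removes it exactly.
* **A most-variable-gene panel** (`panel_size=50`). Genes that separate
  tissue classes but are constant across the stratified samples carry no
  subtype information and dilute the proximity signal; the panel keeps
  the `panel_size` genes with the largest variance across the samples
  being clustered. Fifty genes ≈ twice the planted panel size leaves
  room for noise genes while keeping informative genes in the majority;
  `panel_size=None` disables the filter.

Classical MDS uses Torgerson double centering B = −½ J D² J with
coordinates from the non-negative top eigenpairs; negative-eigenvalue
mass (the non-Euclidean part of an RF dissimilarity) is logged, and the
embedding contract is distances, not coordinates. Partitioning is exact
k-medoids whenever the medoid search space C(n, k) ≤ 20 000 — which
covers both the oracle test sizes and the real use case (n = 37 lesional
samples, k = 2) — because plain BUILD+SWAP PAM provably sticks in swap-
local optima on a few percent of small instances; above that bound PAM
(BUILD + SWAP) runs, and above n = 200 the CLARA scheme (5 subsamples of
40 + 2k, best full-data cost). k = 2 is fixed by configuration; the
average silhouette width for k = 2…6 is reported so users can audit the
choice. Cluster PP01 is the cluster containing the lowest-index medoid —
arbitrary but deterministic.

Clinical association compares the two subgroups per covariate with the
**unpaired** Wilcoxon rank-sum test: the subgroups are disjoint patient
sets, so a signed-rank pairing is not applicable; the result object
flags the test used. The exact conditional null (midranks, full
enumeration) is used when the combined n ≤ 20, the normal approximation
with tie correction otherwise; missing values are dropped per variable
with counts reported.

## Networks and enrichment

Per subgroup, Pearson correlations over the working gene set define an
undirected graph keeping pairs with |r| ≥ `corr_threshold` (default
0.80; the sign is kept as an edge attribute, |r| is the weight, isolated
genes are dropped and counted). The threshold is configurable because no
single value suits all designs: planted between-subgroup co-variation in
the synthetic cohorts peaks near |r| ≈ 0.5, whereas 0.8 targets the
tight co-regulation scale of real arrays.

MCL runs on the |r|-weighted adjacency with unit self-loops: column
normalization, then alternately expansion (matrix power, default 2) and
inflation (entrywise power, default 2.0, re-normalized), pruning entries
below 10⁻⁵, stopping when the iterate changes by < 10⁻⁸ (cap 200
iterations, with a warning on non-convergence). Clusters are the
connected components of the converged non-zero structure — invariant to
node input order and unable to merge disconnected components.

Enrichment tests each cluster of at least
`min_cluster_size_for_enrichment` (default 9, i.e. more than 8 nodes)
against a GMT collection with the hypergeometric upper tail
P(X ≥ k), X ~ HG(N, K, n); the universe N defaults to 20 000
protein-coding genes but an explicit measured-gene universe can be
supplied. BH correction is applied within each cluster (a pooled mode
exists), and q ≥ p is enforced structurally.

## The synthetic cohort generator

`generate_cohort` simulates directly on the log2 scale:
x[g,s] = baseline[g] + subject[s] + classshift[g, class(s)] +
subgroupshift[g]·1{PP, PP02} + ε, with baseline ~ N(7, 1),
subject ~ N(0, 0.5) shared by a patient's PN and PP arrays,
ε ~ N(0, noise_sd = 1). The planted effects are **fixed magnitudes in
noise-sd units**: 150 DE genes shifted 0.5 sd in PN and 1.5 sd in PP
(same sign per gene, ~63% up), and 25 subgroup genes shifted 2.0 sd in
the lesional samples of the PP02 half of patients (random sign). Ages
are N(50, 5) plus a 10-year offset for PP02 patients; other clinical
covariates are left missing. With `noise_sd=0` the PP−PN difference per
gene equals the planted shift exactly (the paired-structure test).

What the generator does **not** emulate: probe-level structure and
cross-hybridization, batch effects, heavy-tailed or intensity-dependent
noise, correlated gene modules beyond the planted ones, within-subgroup
co-regulation (the subgroup shift is constant inside PP02, so planted
genes co-vary only *across* the two subgroups), and realistic clinical
covariate distributions. Passing tests therefore demonstrate that the
pipeline recovers planted structure under Gaussian noise at the study's
sample sizes — not that it would recover subtypes in any real cohort.

## Problem sizes used in the test suite

The acceptance checks sweep ten seeds at the full emulated design (108
samples × 1000 genes, 1000 trees). The permutation-null calibration uses
200 null runs at a reduced scale (40 samples × 200 genes, 100 trees,
B = 99), and the study-scale null uses B = 100 — sizes chosen to give
the KS uniformity check adequate resolution while keeping the whole
suite fast on one CPU. Oracle tests run at the exact sizes where brute
force is feasible (partitions of n ≤ 6, medoid sets for n ≤ 8,
hypergeometric universes N ≤ 12, single-tree root splits for n ≤ 8).

## Known limitations

* The three-way core intersection is near-empty at the default planted
  effect sizes (see above); downstream stages use the lesional
  signature.
* Gini importance mixes class-separation and subgroup-separation signal;
  in the four-class task the importance tails of strong class-DE genes
  and subgroup genes interleave, so a top-20 cut captures only about
  half the planted subgroup panel (an independent forest implementation
  reproduces this).
* Empirical p-values are lower-bounded at 1/(B+1); B must be chosen
  accordingly.
* The RF dissimilarity is generally non-Euclidean; MDS reports the
  negative eigenvalue mass rather than hiding it.
* CLARA subsampling trades optimality for speed above n = 200 samples;
  at the cohort sizes this package targets, the exact k-medoid search is
  always used.
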