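# psoristrat

Random-forest stratification of psoriasis skin transcriptomes.

Chronic plaque psoriasis presents clinically as one disease, but lesional
skin hides molecular sub-phenotypes with different pathway activity.
`psoristrat` implements, as a reusable and tested Python package, an
analysis pipeline for cohorts of normal (NN), psoriatic non-lesional (PN)
and psoriatic lesional (PP) skin expression profiles:

1. **Differential expression** — per-gene Welch *t*-tests for the three
   pairwise tissue contrasts, Benjamini–Hochberg FDR control
   (select *p* < α and *q* < FDR, truncate to the top-*k* smallest *p*),
   probe→gene averaging, the three-way *core* intersection, z-scores
   against the NN reference, PCA and hierarchical ordering.
2. **Supervised classification** — a deterministic CART ensemble
   (`GiniForestClassifier`): each of *T* trees is grown to purity on a
   stratified ⅔ subsample without replacement; splits maximize the Gini
   impurity decrease over `mtry = ⌊√p⌋` candidate genes; the held-out ⅓
   yields out-of-bag (OOB) accuracy, mean-decrease-in-Gini (GI) and
   per-class mean-decrease-in-accuracy importances.
3. **Unsupervised subgrouping** (`RandomForestStratifier`) — a synthetic
   reference cohort is drawn from each gene's empirical marginal, a forest
   learns real-vs-synthetic, and the real–real proximity *P*(i,j) =
   (#trees with i, j in one leaf)/*T* becomes the dissimilarity
   *d* = √(1 − *P*). Classical (Torgerson) MDS embeds the samples and
   exact k-medoid (PAM/CLARA) partitioning names the lesional subgroups
   PP01/PP02.
4. **Gene ranking under a permutation null** — labels are permuted *B*
   times, the forest refitted, and the maximum GI per permutation
   recorded; the max-T empirical *p* of gene *g* is
   (1 + #{b : max_b ≥ GI(g)}) / (B + 1).
5. **Subgroup characterization** — Wilcoxon rank-sum association with
   clinical covariates (PASI, BMI, age, age of onset, BSA), per-subgroup
   Pearson co-expression networks (|r| ≥ threshold), Markov clustering
   (MCL, expansion/inflation iteration) and hypergeometric pathway
   enrichment with BH correction per cluster.

Because the motivating patient cohorts are access-restricted, the package
ships a first-class synthetic cohort generator (`generate_cohort`) that
emulates the study design — 34 controls plus 37 patients contributing a
paired PN and PP sample (108 arrays), planted differential expression with
a ~63:37 up/down split, a planted two-way division of the lesional
samples, and an age offset between the planted subgroups — with a
`PlantedTruth` record so every stage can be scored against ground truth.

## Worked example

```python
from psoristrat import run_pipeline

res = run_pipeline(seed=1)
print("signature genes:", len(res["lesional_signature"]))
print("two-class OOB accuracy:", res["two_class_model"].oob_accuracy_)
print("four-class OOB accuracy:", round(res["four_class_model"].oob_accuracy_, 4))
print("subgroup ARI vs planted:", res["truth_report"]["ari"])
print(res["clinical"].table[["variable", "p_value"]])
```

prints

```
signature genes: 168
two-class OOB accuracy: 1.0
four-class OOB accuracy: 0.8704
subgroup ARI vs planted: 1.0
  variable   p_value
0      age  0.000026
```

Reading: the DE stage recovered a 168-gene lesional signature (of 175
planted signal genes among 1000); the PN-vs-PP forest separates lesional
from non-lesional tissue essentially perfectly out-of-bag, while the
four-class task (NN/PN/PP01/PP02) is harder at 87% — mirroring the
qualitative two-class vs four-class accuracy gap expected for this
design. The unsupervised stratifier recovered the planted patient split
exactly (adjusted Rand index 1.0), and the planted 10-year age offset
between subgroups is detected by the rank-sum test (p ≈ 2.6 × 10⁻⁵).

The same stages are scriptable from a shell:

```sh
psoristrat simulate --seed 2 --out out/
psoristrat de       --matrix out/matrix.gct --classes out/samples.tsv --out out/de
psoristrat classify --matrix out/matrix.gct --classes out/samples.tsv --trees 1000 --seed 2 --out out/cls
psoristrat stratify --matrix out/matrix.gct --pp-samples out/pp.txt --seed 2 --out out/strat
psoristrat network  --matrix out/matrix.gct --samples out/strat/partition.tsv --out out/net
psoristrat report   --seed 2 --out out/report
```

Inputs are GCT (#1.2) or plain TSV expression matrices, CLS or TSV class
labels and GMT gene-set collections; every run writes a JSON manifest
with the resolved configuration, seed and library versions.

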