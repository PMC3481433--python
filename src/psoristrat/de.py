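"""Pairwise differential expression and the core gene set.

The selection rule per comparison is the composition the study pipeline
applies: Welch two-sample t-test per feature, keep features with
p < alpha AND Benjamini-Hochberg q < fdr, truncate to the ``top_k``
smallest p-values. The core set is the probe-level intersection of the
three pairwise selections (NN-vs-PN, PN-vs-PP, NN-vs-PP), collapsed to
genes, with each gene's direction taken from the NN-vs-PP comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .io import ExpressionMatrix

log = logging.getLogger(__name__)


def welch_t_test(x, y):
    """Welch unequal-variance t-test of two samples.

    Returns ``(t, p, direction)``: t is the statistic of the x - y
    contrast (negative when y exceeds x), p the two-sided tail at
    Welch-Satterthwaite degrees of freedom, and direction =
    sign(mean(y) - mean(x)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            # identical constants: no evidence of difference
            return 0.0, 1.0, 0
        raise ValueError("degenerate variance: both groups constant")
    res = stats.ttest_ind(x, y, equal_var=False)
    direction = int(np.sign(y.mean() - x.mean()))
    return float(res.statistic), float(res.pvalue), direction


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_pairwise_de(matrix, classes, group_a, group_b, alpha=0.05, fdr=0.05,
                    top_k=5000):
    """Differential table and selected feature set for one comparison.

    ``classes`` is one label per sample (aligned to matrix columns).
    Constant features (zero variance in both groups) are excluded from
    testing and logged. Direction is the sign of mean(group_b) -
    mean(group_a).

    Returns ``(table, selected)``: a DataFrame indexed by feature with
    columns t_statistic / p_value / q_value / rank / direction, and the
    list of selected feature ids (p < alpha and q < fdr, truncated to the
    ``top_k`` smallest p).
    """
    classes = np.asarray(classes)
    if len(classes) != matrix.n_samples:
        raise ValueError("one class label per sample required")
    mask_a = classes == group_a
    mask_b = classes == group_b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError(f"groups {group_a}/{group_b} need >= 2 samples each")
    Xa = matrix.values[:, mask_a]
    Xb = matrix.values[:, mask_b]
    var_a = Xa.var(axis=1, ddof=1)
    var_b = Xb.var(axis=1, ddof=1)
    keep = (var_a > 0) | (var_b > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("%s vs %s: excluded %d constant feature(s)", group_a, group_b,
                 n_dropped)
    ids = [f for f, k in zip(matrix.feature_ids, keep) if k]
    res = stats.ttest_ind(Xb[keep].T, Xa[keep].T, equal_var=False)
    t = np.asarray(res.statistic)
    p = np.asarray(res.pvalue)
    direction = np.sign(Xb[keep].mean(axis=1) - Xa[keep].mean(axis=1)).astype(int)
    q = bh_fdr(p)
    rank = np.empty(len(p), dtype=int)
    rank[np.argsort(p, kind="stable")] = np.arange(1, len(p) + 1)
    table = pd.DataFrame({"t_statistic": t, "p_value": p, "q_value": q,
                          "rank": rank, "direction": direction}, index=ids)
    table.attrs["comparison"] = f"{group_a}_vs_{group_b}"
    passing = table[(table.p_value < alpha) & (table.q_value < fdr)]
    selected = list(passing.sort_values("p_value", kind="stable").index[:top_k])
    return table, selected


def collapse_probes(matrix, probe_to_gene):
    """Average probe rows mapping to the same gene.

    Probes absent from the map are dropped (count logged); gene order is
    the order of first appearance among mapped probes.
    """
    mapped = [pid for pid in matrix.feature_ids if pid in probe_to_gene]
    if not mapped:
        raise ValueError("probe_to_gene covers none of the matrix's probes")
    n_dropped = matrix.n_features - len(mapped)
    if n_dropped:
        log.info("collapse_probes: dropped %d unmapped probe(s)", n_dropped)
    pos = {pid: i for i, pid in enumerate(matrix.feature_ids)}
    gene_rows = {}
    gene_order = []
    for pid in mapped:
        gene = probe_to_gene[pid]
        if gene not in gene_rows:
            gene_rows[gene] = []
            gene_order.append(gene)
        gene_rows[gene].append(pos[pid])
    values = np.vstack([matrix.values[gene_rows[gene]].mean(axis=0)
                        for gene in gene_order])
    return ExpressionMatrix(values, gene_order, matrix.sample_ids,
                            feature_level="gene")


@dataclass
class CoreGeneSet:
    """Genes differentially expressed in all three pairwise comparisons."""

    genes: list
    directions: dict          # gene -> +1 (up vs NN) / -1 / 0
    source_probes: dict       # gene -> list of probe ids

    @property
    def n_up(self):
        return sum(1 for d in self.directions.values() if d > 0)

    @property
    def n_down(self):
        return sum(1 for d in self.directions.values() if d < 0)

    def __len__(self):
        return len(self.genes)


def intersect_core(selected_sets, nn_vs_pp_table, probe_to_gene=None):
    """Three-way intersection of selected probe sets, collapsed to genes.

    ``selected_sets`` are the three per-comparison selections
    (NN-vs-PN, PN-vs-PP, NN-vs-PP). Direction per gene comes from the
    NN-vs-PP table. Without a probe map, probes are taken to be genes.
    """
    if len(selected_sets) != 3:
        raise ValueError("exactly three selected sets expected")
    core_probes = set(selected_sets[0])
    for s in selected_sets[1:]:
        core_probes &= set(s)
    if not core_probes:
        warnings.warn("empty core: the three pairwise selections are disjoint")
    genes, directions, source = [], {}, {}
    # keep file/matrix order via the NN-vs-PP table index
    for probe in nn_vs_pp_table.index:
        if probe not in core_probes:
            continue
        gene = probe_to_gene.get(probe, probe) if probe_to_gene else probe
        if gene not in source:
            source[gene] = []
            genes.append(gene)
        source[gene].append(probe)
    for gene in genes:
        dirs = [int(nn_vs_pp_table.loc[p, "direction"]) for p in source[gene]]
        directions[gene] = int(np.sign(sum(dirs)))
    return CoreGeneSet(genes, directions, source)


def zscore_vs_reference(matrix, reference_sample_ids):
    """Standardize each gene against the control (NN) reference samples.

    z[g, s] = (x[g, s] - mean_ref[g]) / sd_ref[g], sample sd (ddof=1);
    reference columns are standardized too.
    """
    ref = list(reference_sample_ids)
    if len(ref) < 2:
        raise ValueError("need >= 2 reference samples")
    pos = {s: i for i, s in enumerate(matrix.sample_ids)}
    missing = [s for s in ref if s not in pos]
    if missing:
        raise KeyError(f"unknown reference sample ids: {missing}")
    ref_idx = [pos[s] for s in ref]
    mu = matrix.values[:, ref_idx].mean(axis=1)
    sd = matrix.values[:, ref_idx].std(axis=1, ddof=1)
    bad = [g for g, s in zip(matrix.feature_ids, sd) if s == 0]
    if bad:
        raise ValueError(f"zero reference sd for gene(s): {bad[:10]}")
    z = (matrix.values - mu[:, None]) / sd[:, None]
    return ExpressionMatrix(z, matrix.feature_ids, matrix.sample_ids,
                            matrix.feature_level)


@dataclass
class EmbeddingResult:
    """Low-dimensional sample coordinates with per-axis explained quantity."""

    coordinates: np.ndarray   # samples x dims
    explained: np.ndarray     # variance (PCA) or eigenvalue (MDS), non-increasing
    method: str
    sample_ids: list = None


def pca_embed(matrix, n_components=2):
    """Project samples onto the top principal axes of gene space.

    Genes are centered internally; the sign of each component is fixed so
    its largest-magnitude loading is positive (deterministic output).
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(matrix.n_features, matrix.n_samples):
        raise ValueError("n_components exceeds min(genes, samples)")
    X = matrix.values.T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1
    return EmbeddingResult(coords, pca.explained_variance_.copy(), "pca",
                           list(matrix.sample_ids))


def hclust_order(matrix):
    """Complete-linkage agglomerative clustering of rows (Euclidean).

    Returns ``(leaf_order, linkage_matrix)``; leaf_order is the
    dendrogram's left-to-right permutation of row ids.
    """
    if matrix.n_features < 2:
        raise ValueError("need >= 2 rows to cluster")
    Z = hierarchy.linkage(matrix.values, method="complete", metric="euclidean")
    leaves = hierarchy.leaves_list(Z)
    return [matrix.feature_ids[i] for i in leaves], Z
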