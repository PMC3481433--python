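"""Co-expression networks, Markov clustering and pathway enrichment.

Per subgroup: Pearson correlations over the core genes, an undirected
graph keeping gene pairs with |r| at or above a threshold (sign kept as
an edge attribute, |r| as the weight), Markov clustering (MCL) of the
weighted graph, and a hypergeometric over-representation test of each
sufficiently large cluster against a GMT gene-set collection, BH-corrected
within each cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr

log = logging.getLogger(__name__)


def pearson_matrix(X_subgroup, gene_ids=None):
    """Gene-gene Pearson correlations from a genes x samples block.

    Genes with zero variance are excluded with a warning (correlation
    undefined); requires >= 3 samples.
    """
    X = np.asarray(X_subgroup, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("need a genes x samples matrix with >= 3 samples")
    ids = list(gene_ids) if gene_ids is not None \
        else [f"g{i}" for i in range(X.shape[0])]
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(ids, keep) if not k]
        warnings.warn(f"excluded {len(dropped)} zero-variance gene(s): "
                      f"{dropped[:5]}")
    ids = [g for g, k in zip(ids, keep) if k]
    if len(ids) < 2:
        raise ValueError("need >= 2 non-constant genes for a correlation matrix")
    R = np.corrcoef(X[keep])
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=ids, columns=ids)


def build_coexpression_network(corr, threshold=0.80, subgroup=None):
    """Threshold a correlation matrix into an undirected gene graph.

    Edge (g, h) iff g != h and |r| >= threshold; edge weight is |r| with
    the sign retained as an attribute. Isolated genes are dropped (count
    logged). Node and edge counts are stored on the graph.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    ids = list(corr.index)
    R = corr.to_numpy()
    G = nx.Graph(threshold=threshold, subgroup=subgroup)
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = np.abs(R[iu, ju]) >= threshold
    for i, j in zip(iu[mask], ju[mask]):
        r = float(R[i, j])
        G.add_edge(ids[i], ids[j], weight=abs(r), sign=int(np.sign(r)), r=r)
    n_isolated = len(ids) - G.number_of_nodes()
    log.info("network (|r| >= %.2f): %d nodes, %d edges, %d isolated dropped",
             threshold, G.number_of_nodes(), G.number_of_edges(), n_isolated)
    G.graph["n_isolated_dropped"] = n_isolated
    return G


@dataclass
class GeneClusterSet:
    """Disjoint gene clusters from Markov clustering."""

    clusters: list                # list of lists of gene ids
    inflation: float
    expansion: int
    n_iterations: int
    converged: bool

    def __len__(self):
        return len(self.clusters)


def mcl_cluster(network, inflation=2.0, expansion=2, prune=1e-5, tol=1e-8,
                max_iterations=200):
    """Markov Cluster Algorithm on the weighted co-expression graph.

    The |r|-weighted adjacency gets unit self-loops, is column-normalized
    and iterated: expansion (matrix power) then inflation (entrywise
    power + renormalization), pruning entries below ``prune``. Clusters
    are the connected components of the converged non-zero structure,
    ordered by their lowest node index; node input order does not affect
    the result.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if expansion < 2 or int(expansion) != expansion:
        raise ValueError("expansion must be an integer >= 2")
    nodes = sorted(network.nodes())
    n = len(nodes)
    if n == 0:
        return GeneClusterSet([], inflation, expansion, 0, True)
    pos = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in network.edges(data=True):
        w = float(data.get("weight", 1.0))
        M[pos[u], pos[v]] = w
        M[pos[v], pos[u]] = w
    np.fill_diagonal(M, 1.0)
    M = M / M.sum(axis=0, keepdims=True)
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        M_new = np.linalg.matrix_power(M, int(expansion))
        M_new = M_new ** inflation
        M_new[M_new < prune] = 0.0
        colsum = M_new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M_new = M_new / colsum
        diff = np.max(np.abs(M_new - M))
        M = M_new
        if diff < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"MCL did not converge in {max_iterations} iterations; "
                      "clusters taken from the last iterate")
    support = nx.Graph()
    support.add_nodes_from(range(n))
    nz = np.argwhere((M > 0) | (M.T > 0))
    support.add_edges_from((int(i), int(j)) for i, j in nz if i != j)
    comps = [sorted(c) for c in nx.connected_components(support)]
    comps.sort(key=lambda c: c[0])
    clusters = [[nodes[i] for i in comp] for comp in comps]
    return GeneClusterSet(clusters, inflation, int(expansion), it, converged)


def enrich_hypergeometric(clusters, gene_sets, universe_size=20000,
                          min_cluster_size=9, universe_genes=None,
                          pooled_fdr=False):
    """Hypergeometric over-representation of gene sets in each cluster.

    p = P(X >= k) with X ~ Hypergeometric(N = universe, K = |set|,
    n = |cluster|). BH q-values are computed within each cluster by
    default (``pooled_fdr`` pools all rows). Clusters below
    ``min_cluster_size`` are skipped; a gene set with no members in the
    explicit universe (when given) is skipped with a warning.
    """
    if isinstance(clusters, GeneClusterSet):
        clusters = clusters.clusters
    sets = gene_sets.sets if hasattr(gene_sets, "sets") else {
        name: ("", frozenset(members)) for name, members in gene_sets.items()}
    universe = frozenset(universe_genes) if universe_genes is not None else None
    if universe is not None:
        universe_size = len(universe)
    rows = []
    for ci, cluster in enumerate(clusters):
        cset = frozenset(cluster)
        if universe is not None:
            cset = cset & universe
        n = len(cset)
        if n < min_cluster_size:
            continue
        if universe_size < n:
            raise ValueError("universe smaller than a tested cluster")
        for name, (_, members) in sets.items():
            mem = members & universe if universe is not None else members
            if not mem:
                warnings.warn(f"gene set {name!r} has no members in the "
                              "universe; skipped")
                continue
            K = len(mem)
            if universe_size < K:
                raise ValueError(f"universe smaller than gene set {name!r}")
            k = len(cset & mem)
            p = float(stats.hypergeom.sf(k - 1, universe_size, K, n))
            rows.append({"cluster": ci, "gene_set": name, "overlap": k,
                         "cluster_size": n, "set_size": K,
                         "universe": universe_size, "p_value": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if table.empty:
        table["q_value"] = []
        table["significant"] = []
        return table
    if pooled_fdr:
        table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    else:
        table["q_value"] = np.nan
        for ci in table["cluster"].unique():
            m = table["cluster"] == ci
            table.loc[m, "q_value"] = bh_fdr(table.loc[m, "p_value"].to_numpy())
    table["q_value"] = np.maximum(table["q_value"], table["p_value"])
    table["significant"] = table["q_value"] < 0.05
    return table.sort_values(["cluster", "p_value"],
                             kind="stable").reset_index(drop=True)
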