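"""Unsupervised random-forest stratification of lesional samples.

The procedure (the addcl-style RF clustering the study applies to its 37
lesional samples): build a synthetic reference cohort by sampling each
gene's empirical marginal independently, train the tree ensemble to tell
real from synthetic, read off the real-vs-real proximity matrix, turn it
into a dissimilarity (default ``sqrt(1 - prox)``), embed with classical
MDS for inspection and partition with k-medoids (PAM, CLARA subsampling
for large n). Subgroups are named PP01/PP02, PP01 being the cluster that
contains the lower-index medoid. Clinical covariates are compared
between subgroups with the unpaired Wilcoxon rank-sum test (the two
subgroups are disjoint patient sets, so a signed-rank pairing does not
apply; the output flags the test used).
"""

from __future__ import annotations

import itertools
import logging
from math import comb
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score
from sklearn.utils.validation import check_array, check_is_fitted

from .de import EmbeddingResult
from .forest import GiniForestClassifier

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# preprocessing for subtype discovery

def center_samples(X, statistic="median"):
    """Remove each sample's offset (row-wise center of a samples x genes X).

    Expression arrays and shared subject effects shift whole samples up or
    down across all genes; unsupervised proximity clustering would otherwise
    group samples by that offset instead of by subtype signal.
    """
    X = np.asarray(X, dtype=float)
    loc = np.median(X, axis=1, keepdims=True) if statistic == "median" \
        else X.mean(axis=1, keepdims=True)
    return X - loc


def select_variable_panel(X, n_genes=50):
    """Column indices of the ``n_genes`` most variable genes (sample sd).

    Subtype signal lives in genes that vary among the samples being
    stratified; genes that only separate tissue classes are constant here
    and merely dilute the proximity signal.
    """
    X = np.asarray(X, dtype=float)
    n_genes = min(n_genes, X.shape[1])
    v = X.var(axis=0, ddof=1)
    return np.sort(np.argsort(v, kind="stable")[::-1][:n_genes])


# ---------------------------------------------------------------------------
# synthetic reference + RF dissimilarity

def make_reference(X_real, mode="marginal_permutation", seed=0):
    """Reference data with each feature's marginal kept, joint structure broken.

    ``marginal_permutation`` independently permutes each feature's column
    of values (multiset exactly preserved); ``marginal_resample`` draws
    each feature's values with replacement.
    """
    X = np.asarray(X_real, dtype=float)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        if mode == "marginal_permutation":
            out[:, j] = X[rng.permutation(n), j]
        elif mode == "marginal_resample":
            out[:, j] = X[rng.integers(0, n, size=n), j]
        else:
            raise ValueError(f"unknown reference mode {mode!r}")
    return out


@dataclass
class DissimilarityMatrix:
    values: np.ndarray
    transform: str
    sample_ids: list = None

    def __post_init__(self):
        D = np.asarray(self.values, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("dissimilarity must be square")
        if not np.allclose(D, D.T):
            raise ValueError("dissimilarity must be symmetric")
        if np.any(np.abs(np.diag(D)) > 1e-12):
            raise ValueError("dissimilarity diagonal must be zero")
        self.values = D


def rf_dissimilarity(X_real, n_trees=1000, mode="marginal_permutation",
                     transform="sqrt_one_minus", mtry=None,
                     subsample_fraction=2.0 / 3.0, n_repeats=1, seed=0):
    """Sample dissimilarities from a real-vs-synthetic forest.

    Real samples are labelled 1, synthetic 2; proximities are restricted
    to the real-vs-real block and mapped through ``sqrt(1 - prox)``
    (default) or ``1 - prox``. ``n_repeats`` averages proximities over
    independently seeded forests for stability.
    """
    X = check_array(X_real, dtype=np.float64)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need >= 4 real samples")
    if transform not in ("sqrt_one_minus", "one_minus"):
        raise ValueError(f"unknown transform {transform!r}")
    ss = np.random.SeedSequence(seed)
    sub = ss.generate_state(2 * n_repeats, dtype=np.uint32)
    prox_sum = np.zeros((n, n))
    for r in range(n_repeats):
        X_syn = make_reference(X, mode=mode, seed=int(sub[2 * r]))
        stacked = np.vstack([X, X_syn])
        y = np.array([1] * n + [2] * n)
        forest = GiniForestClassifier(
            n_trees=n_trees, mtry=mtry, subsample_fraction=subsample_fraction,
            random_state=int(sub[2 * r + 1])).fit(stacked, y)
        if forest.oob_error_rate_ >= 0.5 and n_trees >= 50:
            log.info("rf_dissimilarity: forest barely separates real from "
                     "synthetic (OOB error %.2f); dissimilarities may be flat",
                     forest.oob_error_rate_)
        prox_sum += forest.proximity()[:n, :n]
    prox = prox_sum / n_repeats
    if transform == "sqrt_one_minus":
        D = np.sqrt(np.clip(1.0 - prox, 0.0, 1.0))
    else:
        D = np.clip(1.0 - prox, 0.0, 1.0)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(D, transform)


# ---------------------------------------------------------------------------
# classical (Torgerson) MDS

def classical_mds(D, n_dims=2):
    """Torgerson double-centering MDS of a dissimilarity matrix.

    B = -1/2 J D^2 J; coordinates come from the top non-negative
    eigenpairs, signs fixed so each axis's largest-magnitude coordinate
    is positive. Distances, not coordinates, are the contract: the
    embedding is unique only up to rotation/reflection. Negative
    eigenvalue mass (non-Euclidean part) is logged.
    """
    D = np.asarray(D, dtype=float)
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("D must be a square symmetric matrix")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    if np.any(D > 0) and w[0] <= 1e-12:
        raise ValueError("degenerate dissimilarity: no positive eigenvalue")
    neg_mass = float(-w[w < 0].sum())
    if neg_mass > 1e-10:
        log.info("classical_mds: negative eigenvalue mass %.3g "
                 "(non-Euclidean dissimilarity)", neg_mass)
    k = min(n_dims, n)
    wk = np.clip(w[:k], 0.0, None)
    coords = V[:, :k] * np.sqrt(wk)
    for j in range(k):
        col = coords[:, j]
        if np.any(col != 0) and col[np.argmax(np.abs(col))] < 0:
            coords[:, j] *= -1
    return EmbeddingResult(coords, wk, "classical_mds")


# ---------------------------------------------------------------------------
# PAM / CLARA k-medoids

@dataclass
class Partition:
    """Cluster assignment with medoids and silhouette summary."""

    labels: dict                  # sample id (or index) -> cluster label
    medoids: list
    k: int
    silhouette: float = np.nan
    silhouette_by_k: dict = field(default_factory=dict)
    cost: float = np.nan


def _assign_cost(D, medoids):
    d = D[:, medoids]
    nearest = np.argmin(d, axis=1)
    return d[np.arange(len(D)), nearest].sum(), np.asarray(medoids)[nearest]


def _pam_build(D, k):
    n = len(D)
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        best_gain, best_j = -np.inf, None
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(dmin - D[:, j], 0.0).sum()
            if gain > best_gain:
                best_gain, best_j = gain, j
        medoids.append(best_j)
    return sorted(medoids)

def _pam_swap(D, medoids):
    medoids = list(medoids)
    cost, _ = _assign_cost(D, medoids)
    improved = True
    while improved:
        improved = False
        for mi in range(len(medoids)):
            for h in range(len(D)):
                if h in medoids:
                    continue
                cand = medoids.copy()
                cand[mi] = h
                c, _ = _assign_cost(D, cand)
                if c < cost - 1e-12:
                    medoids, cost = cand, c
                    improved = True
    return sorted(medoids), cost


def pam_cluster(D, k, seed=0, clara_threshold=200, clara_draws=5,
                exact_limit=20000):
    """k-medoids partition of a dissimilarity matrix.

    When the medoid search space is small (``C(n, k) <= exact_limit``,
    which covers k = 2 up to n = 200) the globally optimal medoid set is
    found by enumeration; otherwise PAM (greedy BUILD seeding +
    SWAP passes) runs on the full matrix, and for n > ``clara_threshold``
    the CLARA scheme runs on ``clara_draws`` subsamples of size 40 + 2k,
    keeping the medoid set with the lowest full-data cost. Deterministic
    under the seed with lowest-index tie-breaking.
    """
    D = np.asarray(D, dtype=float)
    n = len(D)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if comb(n, k) <= exact_limit:
        best_cost, medoids = np.inf, None
        for med in itertools.combinations(range(n), k):
            c = D[:, med].min(axis=1).sum()
            if c < best_cost - 1e-12:
                best_cost, medoids = c, list(med)
    elif n <= clara_threshold:
        medoids = _pam_swap(D, _pam_build(D, k))[0]
    else:
        rng = np.random.default_rng(seed)
        best_cost, medoids = np.inf, None
        for _ in range(clara_draws):
            size = min(n, 40 + 2 * k)
            sub = np.sort(rng.choice(n, size=size, replace=False))
            Dsub = D[np.ix_(sub, sub)]
            med_sub = _pam_swap(Dsub, _pam_build(Dsub, k))[0]
            med_full = sorted(int(sub[m]) for m in med_sub)
            c, _ = _assign_cost(D, med_full)
            if c < best_cost:
                best_cost, medoids = c, med_full
    cost, nearest = _assign_cost(D, medoids)
    labels = {i: medoids.index(m) for i, m in enumerate(nearest)}
    # medoids belong to their own cluster by construction (d(m,m)=0)
    sil = np.nan
    lab_arr = np.array([labels[i] for i in range(n)])
    if 2 <= k < n and len(set(lab_arr)) > 1:
        sil = float(silhouette_score(D, lab_arr, metric="precomputed"))
    return Partition(labels, list(medoids), k, silhouette=sil, cost=float(cost))


# ---------------------------------------------------------------------------
# adjusted Rand index

def adjusted_rand_index(labels_a, labels_b):
    """Hubert-Arabie chance-corrected agreement between two partitions."""
    a = np.asarray(list(labels_a))
    b = np.asarray(list(labels_b))
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    if len(a) < 2:
        raise ValueError("need >= 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(cont, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    n = len(a)
    expected = sum_a * sum_b / comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# the stratifier estimator

class RandomForestStratifier(BaseEstimator, ClusterMixin):
    """Cluster samples by random-forest proximity to a marginal reference.

    Parameters mirror the pipeline config: ``k`` subgroups (default 2),
    ensemble size, reference mode, dissimilarity transform and the
    number of proximity-averaging repeats. ``fit(X)`` on a samples x
    genes matrix sets ``labels_`` (0-based; cluster 0 = "PP01", the
    cluster holding the lowest-index medoid), ``dissimilarity_``,
    ``medoids_``, ``embedding_`` (2-D classical MDS),
    ``silhouette_`` and an audit table ``silhouette_by_k_`` for
    k = 2..6.
    """

    def __init__(self, k=2, n_trees=1000, reference_mode="marginal_permutation",
                 transform="sqrt_one_minus", mtry=None,
                 subsample_fraction=2.0 / 3.0, n_repeats=1,
                 center="median", panel_size=50, random_state=0):
        self.k = k
        self.n_trees = n_trees
        self.reference_mode = reference_mode
        self.transform = transform
        self.mtry = mtry
        self.subsample_fraction = subsample_fraction
        self.n_repeats = n_repeats
        self.center = center
        self.panel_size = panel_size
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        n = X.shape[0]
        if n < 2 * self.k:
            raise ValueError(f"need >= {2 * self.k} samples for k={self.k}")
        if self.center is not None:
            X = center_samples(X, statistic=self.center)
        if self.panel_size is not None and self.panel_size < X.shape[1]:
            self.panel_indices_ = select_variable_panel(X, self.panel_size)
            X = X[:, self.panel_indices_]
        else:
            self.panel_indices_ = np.arange(X.shape[1])
        dis = rf_dissimilarity(
            X, n_trees=self.n_trees, mode=self.reference_mode,
            transform=self.transform, mtry=self.mtry,
            subsample_fraction=self.subsample_fraction,
            n_repeats=self.n_repeats, seed=self.random_state)
        part = pam_cluster(dis.values, self.k, seed=self.random_state)
        # relabel so cluster 0 contains the lowest-index medoid
        order = np.argsort(part.medoids)
        relabel = {int(old): int(new) for new, old in enumerate(order)}
        self.labels_ = np.array([relabel[part.labels[i]] for i in range(n)])
        self.medoids_ = [part.medoids[o] for o in order]
        self.dissimilarity_ = dis
        self.partition_ = Partition(
            {i: int(l) for i, l in enumerate(self.labels_)}, self.medoids_,
            self.k, silhouette=part.silhouette, cost=part.cost)
        self.embedding_ = classical_mds(dis.values, n_dims=2)
        self.silhouette_ = part.silhouette
        self.silhouette_by_k_ = {
            kk: pam_cluster(dis.values, kk, seed=self.random_state).silhouette
            for kk in range(2, min(7, n))}
        self.partition_.silhouette_by_k = self.silhouette_by_k_
        return self


def stratify_samples(X_pp, sample_ids=None, k=2, n_trees=1000,
                     reference_mode="marginal_permutation",
                     transform="sqrt_one_minus", n_repeats=1,
                     center="median", panel_size=50, seed=0):
    """Functional wrapper: returns ``(Partition, DissimilarityMatrix,
    EmbeddingResult)`` with PP01/PP02 labels keyed by sample id."""
    X = np.asarray(X_pp, dtype=float)
    ids = list(sample_ids) if sample_ids is not None else list(range(len(X)))
    model = RandomForestStratifier(
        k=k, n_trees=n_trees, reference_mode=reference_mode,
        transform=transform, n_repeats=n_repeats, center=center,
        panel_size=panel_size, random_state=seed).fit(X)
    labels = {ids[i]: f"PP{model.labels_[i] + 1:02d}" for i in range(len(ids))}
    part = Partition(labels, [ids[m] for m in model.medoids_], k,
                     silhouette=model.silhouette_,
                     silhouette_by_k=model.silhouette_by_k_,
                     cost=model.partition_.cost)
    dis = model.dissimilarity_
    dis.sample_ids = ids
    model.embedding_.sample_ids = ids
    return part, dis, model.embedding_


def classify_four_groups(X_all, four_class_labels, n_trees=1000, mtry=None,
                         subsample_fraction=2.0 / 3.0, top_m=43, seed=0,
                         feature_ids=None, per_class=True):
    """Supervised four-class forest (NN / PN / PP01 / PP02).

    Returns ``(model, importance_table, top_genes)``: the fitted
    :class:`GiniForestClassifier`, a table with Gini importance, global
    and per-class mean decrease in accuracy, and the ``top_m`` features
    by Gini importance (the circular-layout export).
    """
    X = check_array(X_all, dtype=np.float64)
    labels = np.asarray(four_class_labels)
    required = {"NN", "PN", "PP01", "PP02"}
    present = set(labels)
    if present != required:
        missing = sorted(required - present)
        extra = sorted(present - required)
        raise ValueError(f"four-class labels must be exactly {sorted(required)}"
                         f"; missing {missing}, unexpected {extra}")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 samples")
    model = GiniForestClassifier(
        n_trees=n_trees, mtry=mtry, subsample_fraction=subsample_fraction,
        random_state=seed).fit(X, labels)
    ids = list(feature_ids) if feature_ids is not None \
        else [f"f{i}" for i in range(X.shape[1])]
    table = pd.DataFrame({"gini_importance": model.feature_importances_}, index=ids)
    if per_class:
        g, pc = model.mda_importance()
        table["mda"] = g
        for ci, cls in enumerate(model.classes_):
            table[f"mda_{cls}"] = pc[:, ci]
    table = table.sort_values("gini_importance", ascending=False, kind="stable")
    top = table.head(top_m)
    return model, table, list(top.index)


# ---------------------------------------------------------------------------
# clinical association

def _exact_ranksum_p(values_a, values_b):
    """Exact two-sided rank-sum p via enumeration (midranks handle ties)."""
    combined = np.concatenate([values_a, values_b])
    ranks = stats.rankdata(combined)
    n1 = len(values_a)
    obs = ranks[:n1].sum()
    e = ranks.sum() * n1 / len(combined)
    dev = abs(obs - e)
    count = 0
    total = 0
    for subset in itertools.combinations(range(len(combined)), n1):
        total += 1
        if abs(ranks[list(subset)].sum() - e) >= dev - 1e-9:
            count += 1
    return count / total


@dataclass
class AssociationResult:
    table: pd.DataFrame
    test: str = "wilcoxon_rank_sum_unpaired"


def clinical_association(partition_labels, annotations, variables):
    """Compare clinical covariates between the two subgroups.

    ``partition_labels`` maps sample or subject ids to subgroup labels;
    ``annotations`` is the cohort's SampleAnnotation list. Per variable:
    missing values are dropped (counts reported), the exact rank-sum null
    is enumerated when the combined n is <= 20, otherwise the normal
    approximation with tie correction is used. Variables with fewer than
    2 non-missing values in a subgroup are skipped with a warning.
    """
    labels = dict(partition_labels)
    groups = sorted(set(labels.values()))
    if len(groups) != 2:
        raise ValueError("clinical association compares exactly 2 subgroups")
    by_sample = {}
    for a in annotations:
        for key in (a.sample_id, a.subject_id):
            if key in labels:
                by_sample.setdefault(labels[key], []).append(a)
                break
    rows = []
    for var in variables:
        vals = {}
        n_missing = 0
        for grp in groups:
            xs = []
            for a in by_sample.get(grp, []):
                v = a.clinical.get(var)
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    n_missing += 1
                else:
                    xs.append(float(v))
            vals[grp] = np.array(xs)
        if any(len(vals[g]) < 2 for g in groups):
            warnings.warn(f"variable {var!r}: a subgroup has < 2 non-missing "
                          "values; skipped")
            continue
        va, vb = vals[groups[0]], vals[groups[1]]
        u_stat = stats.mannwhitneyu(va, vb, alternative="two-sided",
                                    method="asymptotic").statistic
        if len(va) + len(vb) <= 20:
            p = _exact_ranksum_p(va, vb)
        else:
            p = float(stats.mannwhitneyu(va, vb, alternative="two-sided",
                                         method="asymptotic").pvalue)
        rows.append({"variable": var, "statistic": float(u_stat),
                     "p_value": float(min(p, 1.0)),
                     f"median_{groups[0]}": float(np.median(va)),
                     f"median_{groups[1]}": float(np.median(vb)),
                     f"n_{groups[0]}": len(va), f"n_{groups[1]}": len(vb),
                     "n_missing": n_missing})
    return AssociationResult(pd.DataFrame(rows))
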