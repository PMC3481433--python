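"""Deterministic CART/Gini classification-tree ensemble with OOB machinery.

The ensemble follows the random-forest recipe used for tissue-class
prediction in psoriasis stratification: each tree is grown to purity on a
stratified two-thirds subsample drawn without replacement (Breiman-style
bootstrap available behind ``bootstrap=True``), candidate splits are
midpoints between consecutive distinct values of ``mtry`` randomly drawn
features, and the best split maximizes the Gini-impurity decrease with
deterministic tie-breaking (lowest feature index, then lowest threshold).
The held-out third of each tree provides out-of-bag (OOB) error estimates,
mean-decrease-in-accuracy importances and sample proximities.

Fitted models are a pure function of ``(X, y, params, random_state)`` and
bit-identical across runs and platforms.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from . import _kernels


def _tree_seeds(random_state, n_trees):
    ss = np.random.SeedSequence(random_state)
    return ss.generate_state(n_trees, dtype=np.uint64)


def gini_impurity(class_counts):
    """Gini impurity 1 - sum_k (n_k/n)^2 of a count vector."""
    counts = np.asarray(class_counts, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("class_counts must be a non-empty 1-D vector")
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("all-zero class counts: impurity undefined")
    frac = counts / n
    return float(1.0 - np.sum(frac * frac))


class GiniForestClassifier(BaseEstimator, ClassifierMixin):
    """Ensemble of deterministic CART trees with Gini split criterion.

    Parameters
    ----------
    n_trees : int, default 1000
        Ensemble size.
    subsample_fraction : float, default 2/3
        Per-class fraction of samples drawn without replacement to grow
        each tree; the remainder is that tree's OOB set.
    mtry : int or None, default None
        Features drawn (without replacement) per node; ``None`` means
        ``floor(sqrt(n_features))``.
    min_node_size : int, default 1
        Nodes smaller than twice this are not split (1 = grow to purity).
    bootstrap : bool, default False
        Per-class bootstrap (sampling with replacement, n per class)
        instead of 2/3 subsampling.
    random_state : int, default 0

    Attributes
    ----------
    classes_ : ndarray of class labels.
    feature_importances_ : ndarray (n_features,)
        Mean decrease in Gini impurity (GI), averaged over trees; each
        split contributes ``(n_node/n_inbag) * impurity_decrease``.
    oob_votes_ : ndarray (n_samples, n_classes)
    oob_prediction_ : ndarray of labels; majority OOB vote, ties to the
        lowest class index.
    oob_error_rate_, oob_accuracy_ : float
    oob_confusion_ : ndarray (n_classes, n_classes), rows = true class.
    oob_covered_ : boolean mask of samples OOB in at least one tree.
    """

    def __init__(self, n_trees=1000, subsample_fraction=2.0 / 3.0, mtry=None,
                 min_node_size=1, bootstrap=False, random_state=0):
        self.n_trees = n_trees
        self.subsample_fraction = subsample_fraction
        self.mtry = mtry
        self.min_node_size = min_node_size
        self.bootstrap = bootstrap
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        if self.n_trees < 1:
            raise ValueError("n_trees must be a positive integer")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        counts = np.bincount(y_enc)
        if counts.min() < 2:
            small = self.classes_[counts < 2]
            raise ValueError(f"every class needs >= 2 samples; too small: {list(small)}")
        n, p = X.shape
        mtry = self.mtry if self.mtry is not None else max(1, int(np.floor(np.sqrt(p))))
        if not 1 <= mtry <= p:
            raise ValueError(f"mtry must be in [1, {p}]")
        self.mtry_ = int(mtry)
        self.n_features_in_ = p
        seeds = _tree_seeds(self.random_state, self.n_trees)
        (feat, thr, left, right, pred, n_nodes, inbag, gini_sum,
         oob_votes) = _kernels.fit_forest(
            np.ascontiguousarray(X), y_enc.astype(np.int64),
            len(self.classes_), int(self.n_trees),
            float(self.subsample_fraction), bool(self.bootstrap),
            self.mtry_, int(self.min_node_size), seeds)
        self._X_fit = X
        self._y_enc = y_enc
        self._trees = (feat, thr, left, right, pred, n_nodes)
        self._seeds = seeds
        self.inbag_counts_ = inbag
        self.feature_importances_ = gini_sum / self.n_trees
        self.oob_votes_ = oob_votes
        self.oob_covered_ = oob_votes.sum(axis=1) > 0
        if not self.oob_covered_.all():
            warnings.warn(f"{int((~self.oob_covered_).sum())} sample(s) never "
                          "out-of-bag; excluded from OOB estimates")
        pred_enc = oob_votes.argmax(axis=1)
        self.oob_prediction_ = self.classes_[pred_enc]
        cov = self.oob_covered_
        k = len(self.classes_)
        conf = np.zeros((k, k), dtype=np.int64)
        for t, q in zip(y_enc[cov], pred_enc[cov]):
            conf[t, q] += 1
        self.oob_confusion_ = conf
        self.oob_accuracy_ = float(np.mean(pred_enc[cov] == y_enc[cov]))
        self.oob_error_rate_ = 1.0 - self.oob_accuracy_
        return self

    # -- prediction & structure ------------------------------------------
    def predict(self, X):
        check_is_fitted(self, "_trees")
        X = check_array(X, dtype=np.float64)
        feat, thr, left, right, pred, _ = self._trees
        votes = _kernels.predict_votes(np.ascontiguousarray(X), feat, thr,
                                       left, right, pred, len(self.classes_))
        return self.classes_[votes.argmax(axis=1)]

    def apply(self, X):
        """Leaf-node index of each sample in each tree (n_trees x n)."""
        check_is_fitted(self, "_trees")
        X = check_array(X, dtype=np.float64)
        feat, thr, left, right, _, _ = self._trees
        return _kernels.apply_leaves(np.ascontiguousarray(X), feat, thr, left, right)

    def proximity(self, X=None, oob_only=False):
        """Pairwise proximity: fraction of trees putting i and j in one leaf.

        By default every sample is pushed down every tree; ``oob_only``
        restricts each pair to trees where both samples are out-of-bag
        (entries for pairs never jointly OOB come back NaN).
        """
        check_is_fitted(self, "_trees")
        if oob_only and X is not None:
            raise ValueError("oob_only proximity is defined on the training samples")
        Xq = self._X_fit if X is None else check_array(X, dtype=np.float64)
        leaves = self.apply(Xq)
        if oob_only:
            P = _kernels.proximity_oob(leaves, self.inbag_counts_)
            if np.isnan(P).any():
                warnings.warn("some pairs never jointly OOB; entries set to NaN")
            return P
        return _kernels.proximity_all(leaves)

    def mda_importance(self):
        """Mean decrease in OOB accuracy, global and per class.

        Returns ``(global_mda, per_class_mda)`` where the per-class matrix
        has one column per class: the drop in that class's OOB accuracy
        when the feature's OOB values are permuted (seeded per
        tree+feature), averaged over trees.
        """
        check_is_fitted(self, "_trees")
        feat, thr, left, right, pred, n_nodes = self._trees
        g, pc, ctc = _kernels.mda_importance(
            np.ascontiguousarray(self._X_fit), self._y_enc.astype(np.int64),
            len(self.classes_), feat, thr, left, right, pred, n_nodes,
            self.inbag_counts_, self._seeds)
        if (ctc == 0).any():
            empty = self.classes_[ctc == 0]
            warnings.warn(f"class(es) {list(empty)} had no OOB samples in any "
                          "tree; per-class column is zero")
        return g, pc


def fit_forest(X, y, n_trees=1000, subsample_fraction=2.0 / 3.0, mtry=None,
               min_node_size=1, bootstrap=False, random_state=0):
    """Functional wrapper around :class:`GiniForestClassifier`."""
    return GiniForestClassifier(
        n_trees=n_trees, subsample_fraction=subsample_fraction, mtry=mtry,
        min_node_size=min_node_size, bootstrap=bootstrap,
        random_state=random_state).fit(X, y)


def evaluate_oob(model):
    """OOB accuracy / error rate / confusion of a fitted forest."""
    check_is_fitted(model, "_trees")
    return {
        "accuracy": model.oob_accuracy_,
        "error_rate": model.oob_error_rate_,
        "confusion": model.oob_confusion_,
        "n_excluded": int((~model.oob_covered_).sum()),
    }


def gini_importance(model):
    """Mean-decrease-in-Gini importance vector of a fitted forest."""
    check_is_fitted(model, "_trees")
    return model.feature_importances_


def permutation_importance_null(X, y, n_permutations=1000, n_trees=1000,
                                subsample_fraction=2.0 / 3.0, mtry=None,
                                min_node_size=1, bootstrap=False,
                                random_state=0):
    """Familywise (max-T) empirical p-values for the Gini importances.

    The class labels are permuted ``n_permutations`` times; the forest is
    refitted on each permutation and the maximum Gini importance over all
    features recorded. The empirical p of feature f is
    ``(1 + #{b : max_b >= GI_obs(f)}) / (B + 1)`` — the add-one form keeps
    p in (0, 1].

    Returns ``(p_values, gi_observed, null_maxima)``.
    """
    X = check_array(X, dtype=np.float64)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = np.asarray(y)
    _, y_enc = np.unique(y, return_inverse=True)
    Xc = np.ascontiguousarray(X)
    n, p = Xc.shape
    mtry_ = mtry if mtry is not None else max(1, int(np.floor(np.sqrt(p))))
    ss = np.random.SeedSequence(random_state)
    rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))

    def _gi(labels):
        seeds = rng.integers(0, 2 ** 63, size=n_trees, dtype=np.uint64)
        out = _kernels.fit_forest(Xc, labels.astype(np.int64),
                                  int(y_enc.max()) + 1, int(n_trees),
                                  float(subsample_fraction), bool(bootstrap),
                                  int(mtry_), int(min_node_size), seeds)
        return out[7] / n_trees

    gi_obs = _gi(y_enc)
    maxima = np.empty(n_permutations)
    for b in range(n_permutations):
        maxima[b] = _gi(rng.permutation(y_enc)).max()
    exceed = (maxima[None, :] >= gi_obs[:, None]).sum(axis=1)
    p_values = (1.0 + exceed) / (n_permutations + 1.0)
    return p_values, gi_obs, maxima
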