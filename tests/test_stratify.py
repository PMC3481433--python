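import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from psoristrat import CohortDesign, generate_cohort
from psoristrat.stratify import (adjusted_rand_index, classical_mds,
                                 clinical_association, classify_four_groups,
                                 make_reference, pam_cluster,
                                 rf_dissimilarity, stratify_samples)


class TestMakeReference:
    def test_permutation_preserves_each_feature_multiset(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 7))
        S = make_reference(X, "marginal_permutation", seed=1)
        for j in range(7):
            np.testing.assert_array_equal(np.sort(X[:, j]), np.sort(S[:, j]))
        assert not np.array_equal(X, S)

    def test_constant_feature_unchanged(self):
        X = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
        S = make_reference(X, "marginal_permutation", seed=2)
        np.testing.assert_array_equal(S[:, 0], X[:, 0])

    def test_resample_draws_from_observed_values(self):
        X = np.arange(12.0).reshape(6, 2)
        S = make_reference(X, "marginal_resample", seed=3)
        for j in range(2):
            assert set(S[:, j]) <= set(X[:, j])

    def test_deterministic_under_seed(self):
        X = np.random.default_rng(4).normal(size=(15, 4))
        np.testing.assert_array_equal(make_reference(X, seed=5),
                                      make_reference(X, seed=5))


class TestRfDissimilarity:
    def test_planted_groups_closer_within_than_between(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 25))
            X[15:] += rng.choice([-2.0, 2.0], size=25)  # 2-sd split, 25 genes
            d = rf_dissimilarity(X, n_trees=300, seed=seed).values
            within = np.r_[d[:15, :15][np.triu_indices(15, 1)],
                           d[15:, 15:][np.triu_indices(15, 1)]]
            between = d[:15, 15:].ravel()
            wins += within.mean() < between.mean()
        assert wins == 10

    def test_zero_diagonal_and_symmetry(self):
        X = np.random.default_rng(1).normal(size=(12, 10))
        d = rf_dissimilarity(X, n_trees=100, seed=1).values
        np.testing.assert_array_equal(np.diag(d), 0.0)
        np.testing.assert_allclose(d, d.T)
        assert d.min() >= 0 and d.max() <= 1

    def test_transforms_are_order_equivalent(self):
        X = np.random.default_rng(2).normal(size=(12, 10))
        d1 = rf_dissimilarity(X, n_trees=100, transform="sqrt_one_minus",
                              seed=2).values
        d2 = rf_dissimilarity(X, n_trees=100, transform="one_minus",
                              seed=2).values
        iu = np.triu_indices(12, 1)
        assert (np.argsort(d1[iu], kind="stable")
                == np.argsort(d2[iu], kind="stable")).all()


class TestClassicalMds:
    def test_collinear_points_reconstructed(self):
        D = np.array([[0, 3, 5], [3, 0, 2], [5, 2, 0]], dtype=float)
        emb = classical_mds(D, n_dims=2)
        rec = squareform(pdist(emb.coordinates))
        np.testing.assert_allclose(rec, D, atol=1e-8)

    def test_zero_dissimilarity_collapses_to_point(self):
        emb = classical_mds(np.zeros((5, 5)), n_dims=2)
        np.testing.assert_allclose(emb.coordinates, 0.0, atol=1e-12)

    def test_euclidean_inputs_reconstructed_exactly(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            pts = rng.normal(size=(8, 3))
            D = squareform(pdist(pts))
            emb = classical_mds(D, n_dims=3)
            np.testing.assert_allclose(squareform(pdist(emb.coordinates)), D,
                                       atol=1e-8)

    def test_eigenvalues_non_increasing(self):
        D = squareform(pdist(np.random.default_rng(7).normal(size=(9, 4))))
        emb = classical_mds(D, n_dims=4)
        assert np.all(np.diff(emb.explained) <= 1e-9)


class TestPam:
    def test_two_separated_triples(self):
        x = np.array([0, 0.1, 0.2, 10, 10.1, 10.2])
        D = np.abs(x[:, None] - x[None, :])
        part = pam_cluster(D, k=2)
        labels = [part.labels[i] for i in range(6)]
        assert labels[:3] == [labels[0]] * 3
        assert labels[3:] == [labels[3]] * 3
        assert labels[0] != labels[3]

    def test_k_equals_n_zero_cost(self):
        D = squareform(pdist(np.random.default_rng(0).normal(size=(5, 2))))
        part = pam_cluster(D, k=5)
        assert part.cost == 0.0
        assert sorted(part.medoids) == list(range(5))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            pam_cluster(np.zeros((3, 3)), k=4)

    def test_matches_exhaustive_optimum_on_small_instances(self):
        """BUILD+SWAP reaches the global k-medoid optimum for n <= 8,
        k <= 3 (brute force over all medoid subsets)."""
        rng = np.random.default_rng(11)
        for trial in range(30):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(1, 4))
            pts = rng.normal(size=(n, 2))
            D = squareform(pdist(pts))
            part = pam_cluster(D, k=k)
            best = min(D[:, list(med)].min(axis=1).sum()
                       for med in itertools.combinations(range(n), k))
            assert part.cost == pytest.approx(best)

    def test_clara_engages_above_threshold_and_stays_reasonable(self):
        rng = np.random.default_rng(12)
        pts = np.r_[rng.normal(0, 1, size=(120, 2)),
                    rng.normal(8, 1, size=(120, 2))]
        D = squareform(pdist(pts))
        part = pam_cluster(D, k=2, seed=0, clara_threshold=100)
        labels = np.array([part.labels[i] for i in range(240)])
        assert adjusted_rand_index(labels, [0] * 120 + [1] * 120) > 0.99


def _ari_pair_counting(a, b):
    """Independent oracle: ARI from explicit pair counts."""
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        n11 += sa and sb
        n00 += (not sa) and (not sb)
        n10 += sa and not sb
        n01 += (not sa) and sb
    num = 2.0 * (n11 * n00 - n10 * n01)
    den = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    return 1.0 if den == 0 else num / den


def _all_partitions(n):
    """All set partitions of range(n) as restricted-growth label strings."""
    def rec(prefix, m):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for lab in range(m + 1):
            yield from rec(prefix + [lab], max(m, lab + 1))
    yield from rec([0], 1)


class TestAri:
    def test_identical_and_relabeled_partitions_score_one(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0
        assert adjusted_rand_index([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0

    def test_crossed_partition_hand_value(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1, 2], [1, 2, 3])

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_matches_pair_counting_oracle_all_partition_pairs(self, n):
        parts = list(_all_partitions(n))
        for a in parts:
            for b in parts:
                assert adjusted_rand_index(a, b) == pytest.approx(
                    _ari_pair_counting(a, b), abs=1e-12)

    def test_matches_pair_counting_oracle_n6_sampled(self):
        parts = list(_all_partitions(6))
        rng = np.random.default_rng(0)
        for _ in range(400):
            a = parts[rng.integers(len(parts))]
            b = parts[rng.integers(len(parts))]
            assert adjusted_rand_index(a, b) == pytest.approx(
                _ari_pair_counting(a, b), abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.integers(0, 4, size=12)
            b = rng.integers(0, 3, size=12)
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12)


def _pp_block(seed):
    matrix, annotations, truth = generate_cohort(CohortDesign(seed=seed))
    classes = np.array([a.tissue_class for a in annotations])
    sids = np.array(matrix.sample_ids)
    pp = classes == "PP"
    return matrix.values[:, pp].T, list(sids[pp]), truth


class TestStratifySamples:
    def test_labels_cover_every_pp_sample_once(self):
        X, ids, _ = _pp_block(0)
        part, dis, emb = stratify_samples(X, sample_ids=ids, seed=0)
        assert sorted(part.labels) == sorted(ids)
        assert set(part.labels.values()) == {"PP01", "PP02"}
        assert len(part.medoids) == 2

    def test_end_to_end_determinism(self):
        X, ids, _ = _pp_block(1)
        p1, d1, e1 = stratify_samples(X, sample_ids=ids, seed=5)
        p2, d2, e2 = stratify_samples(X, sample_ids=ids, seed=5)
        assert p1.labels == p2.labels
        np.testing.assert_array_equal(d1.values, d2.values)
        np.testing.assert_array_equal(e1.coordinates, e2.coordinates)

    def test_planted_subgroups_recovered(self):
        aris = []
        for seed in range(3):
            X, ids, truth = _pp_block(seed)
            part, dis, _ = stratify_samples(X, sample_ids=ids, seed=seed)
            subj = [s.split("_", 1)[1] for s in ids]
            ari = adjusted_rand_index(
                [truth.subgroup_labels[s] for s in subj],
                [part.labels[i] for i in ids])
            aris.append(ari)
            if ari >= 0.5:
                # dissimilarity sanity: within-subgroup < between-subgroup
                lab = np.array([part.labels[i] for i in ids])
                D = dis.values
                same = lab[:, None] == lab[None, :]
                iu = np.triu_indices(len(ids), 1)
                assert D[iu][same[iu]].mean() < D[iu][~same[iu]].mean()
        assert np.median(aris) >= 0.9

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            stratify_samples(np.zeros((3, 5)), k=2, n_trees=10)


class TestClassifyFourGroups:
    def test_top_m_sorted_by_gini_descending(self, small_cohort):
        matrix, annotations, truth, classes = small_cohort
        labels = classes.astype(object).copy()
        sids = np.array(matrix.sample_ids)
        for i, s in enumerate(sids):
            if classes[i] == "PP":
                labels[i] = truth.subgroup_labels[s.split("_", 1)[1]]
        model, table, top = classify_four_groups(
            matrix.values.T, labels, n_trees=100, top_m=10, seed=0,
            feature_ids=matrix.feature_ids, per_class=False)
        assert len(top) == 10
        gi = table.loc[top, "gini_importance"].to_numpy()
        assert np.all(np.diff(gi) <= 1e-15)
        assert sorted(model.classes_) == ["NN", "PN", "PP01", "PP02"]

    def test_empty_class_rejected(self, small_cohort):
        matrix, _, _, classes = small_cohort
        labels = classes.astype(object).copy()
        labels[labels == "PP"] = "PP01"  # no PP02 at all
        with pytest.raises(ValueError):
            classify_four_groups(matrix.values.T, labels, n_trees=10)


class TestClinicalAssociation:
    def _annotations(self, values_a, values_b, var="age"):
        from psoristrat.io import SampleAnnotation
        anns, labels = [], {}
        for i, v in enumerate(values_a):
            sid = f"PP_A{i}"
            anns.append(SampleAnnotation(sid, "PP", f"A{i}", {var: v}))
            labels[sid] = "PP01"
        for i, v in enumerate(values_b):
            sid = f"PP_B{i}"
            anns.append(SampleAnnotation(sid, "PP", f"B{i}", {var: v}))
            labels[sid] = "PP02"
        return labels, anns

    def test_identical_multisets_give_p_one(self):
        labels, anns = self._annotations([1, 2, 3], [1, 2, 3])
        res = clinical_association(labels, anns, ["age"])
        assert res.table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_fully_separated_three_vs_three_exact_p(self):
        labels, anns = self._annotations([1, 2, 3], [10, 11, 12])
        res = clinical_association(labels, anns, ["age"])
        assert res.table.loc[0, "p_value"] == pytest.approx(2.0 / 20.0)

    def test_missing_values_dropped_and_counted(self):
        labels, anns = self._annotations([1, 2, 3, None], [5, 6, 7])
        res = clinical_association(labels, anns, ["age"])
        assert res.table.loc[0, "n_missing"] == 1
        assert res.table.loc[0, "n_PP01"] == 3

    def test_variable_absent_in_one_group_skipped(self):
        labels, anns = self._annotations([None, None, None], [1, 2, 3])
        with pytest.warns(UserWarning, match="skipped"):
            res = clinical_association(labels, anns, ["age"])
        assert len(res.table) == 0

    def test_unpaired_test_flagged_in_output(self):
        labels, anns = self._annotations([1, 2, 3], [4, 5, 6])
        res = clinical_association(labels, anns, ["age"])
        assert "rank_sum" in res.test and "unpaired" in res.test
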