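"""Canberra distances, Ward clustering, ordination, polydomain score."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import silhouette_score

import calstores as cs
from conftest import random_matrix

count_vectors = st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=12)


class TestCanberra:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ([1, 2], [1, 2], 0.0),
            ([1, 2], [3, 2], 0.5),  # 2/4 + 0
            ([0, 1], [1, 0], 2.0),  # 1 + 1
            ([0, 0], [0, 0], 0.0),  # 0/0 terms contribute nothing
            ([2, 0, 3], [2, 0, 1], 0.5),
        ],
    )
    def test_direct_evaluation(self, u, v, expected):
        assert cs.canberra(u, v) == pytest.approx(expected)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            cs.canberra([1, 2], [1, 2, 3])

    @given(u=count_vectors, v=count_vectors)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetry_and_bounds(self, u, v):
        n = min(len(u), len(v))
        u, v = u[:n], v[:n]
        d = cs.canberra(u, v)
        assert d == pytest.approx(cs.canberra(v, u))
        # each summand lies in [0, 1], so d <= vector length
        assert 0.0 <= d <= n + 1e-12

    @given(
        data=st.lists(
            st.tuples(*[st.integers(0, 30)] * 6), min_size=3, max_size=3
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_triangle_inequality(self, data):
        u, v, w = (np.array(x) for x in data)
        assert cs.canberra(u, w) <= cs.canberra(u, v) + cs.canberra(v, w) + 1e-9


class TestPairwiseDistances:
    def test_single_row_is_zero_matrix(self):
        m = cs.ParalogCountMatrix(["a"], ["f", "g"], np.array([[1, 2]]))
        D = cs.pairwise_distances(m, axis="organisms")
        assert D.n == 1 and D.D[0, 0] == 0.0

    def test_matches_scalar_canberra_both_axes(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 3, 2)
        for axis, vecs, labels in [
            ("organisms", m.organism_vectors(), m.organisms),
            ("families", m.family_vectors(), m.families),
        ]:
            D = cs.pairwise_distances(m, axis=axis)
            assert D.labels == labels
            for i in range(len(vecs)):
                for j in range(len(vecs)):
                    assert D.D[i, j] == pytest.approx(cs.canberra(vecs[i], vecs[j]))

    def test_brute_force_oracle_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            m = random_matrix(rng, 10, 5)
            D = cs.pairwise_distances(m, axis="organisms").D
            rows = m.organism_vectors()
            oracle = np.array([[cs.canberra(a, b) for b in rows] for a in rows])
            np.testing.assert_allclose(D, oracle, atol=1e-12)


class TestWardClustering:
    def test_two_labels_single_merge(self):
        m = cs.ParalogCountMatrix(["a", "b"], ["f"], np.array([[0], [5]]))
        dend = cs.ward_cluster(cs.pairwise_distances(m))
        assert dend.linkage.shape == (1, 4)
        assert set(dend.linkage[0, :2].astype(int)) == {0, 1}

    def test_n_below_two_errors(self):
        D = cs.DistanceMatrix(("a",), np.zeros((1, 1)))
        with pytest.raises(ValueError):
            cs.ward_cluster(D)

    @pytest.mark.parametrize("variant", ["ward_d2", "ward_d"])
    def test_two_separated_pairs_merge_first(self, variant):
        # two tight pairs far apart: the first two merges must join the pairs
        counts = np.array([[10, 0], [11, 0], [0, 10], [0, 11]])
        m = cs.ParalogCountMatrix(["a1", "a2", "b1", "b2"], ["f", "g"], counts)
        dend = cs.ward_cluster(cs.pairwise_distances(m), variant=variant)
        first_two = {frozenset(dend.linkage[i, :2].astype(int)) for i in range(2)}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_monotone_heights_and_merge_count(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 12, 4)
        dend = cs.ward_cluster(cs.pairwise_distances(m))
        assert dend.linkage.shape[0] == 11
        assert np.all(np.diff(dend.heights) >= -1e-12)

    def test_newick_export_contains_all_labels(self):
        rng = np.random.default_rng(6)
        m = random_matrix(rng, 6, 3)
        nwk = cs.ward_cluster(cs.pairwise_distances(m)).to_newick()
        assert nwk.endswith(";")
        for org in m.organisms:
            assert org in nwk


class TestCutDendrogram:
    @pytest.fixture
    def dend(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, 10, 4)
        return cs.ward_cluster(cs.pairwise_distances(m))

    def test_extreme_cuts(self, dend):
        n = len(dend.labels)
        singletons = cs.cut_dendrogram(dend, n)
        assert len(set(singletons.values())) == n
        lumped = cs.cut_dendrogram(dend, 1)
        assert set(lumped.values()) == {0}

    def test_intermediate_cut_has_exactly_k(self, dend):
        for k in (2, 3, 5):
            assert len(set(cs.cut_dendrogram(dend, k).values())) == k

    def test_impossible_k_errors(self, dend):
        with pytest.raises(ValueError):
            cs.cut_dendrogram(dend, 0)
        with pytest.raises(ValueError):
            cs.cut_dendrogram(dend, len(dend.labels) + 1)


class TestPCA:
    def test_single_varying_column_explains_everything(self):
        counts = np.array([[0, 3, 7], [0, 3, 1], [0, 3, 4], [0, 3, 9]])
        m = cs.ParalogCountMatrix(["a", "b", "c", "d"], ["f", "g", "h"], counts)
        res = cs.pca(m)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)
        assert res.variables == ("h",)  # zero-variance columns dropped

    def test_all_constant_errors(self):
        m = cs.ParalogCountMatrix(["a", "b"], ["f"], np.array([[2], [2]]))
        with pytest.raises(ValueError, match="zero variance"):
            cs.pca(m)

    def test_scores_centered_and_variance_fractions_valid(self, planted):
        m, _, _ = planted
        res = cs.pca(m)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-9)
        evf = res.explained_variance_fraction
        assert np.all(evf >= 0) and np.all(np.diff(evf) <= 1e-12)
        assert evf.sum() <= 1.0 + 1e-9

    def test_planted_clades_separate_in_pc_space(self, planted):
        m, _, gt = planted
        res = cs.pca(m)
        labels = [gt.clade_of[o] for o in m.organisms]
        assert silhouette_score(res.scores[:, :2], labels) > 0

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        m = random_matrix(rng, 8, 5)
        perm = rng.permutation(8)
        mp = cs.ParalogCountMatrix(
            [m.organisms[i] for i in perm], m.families, m.counts[perm, :]
        )
        s1 = cs.pca(m).scores
        s2 = cs.pca(mp).scores
        # same scores up to row order and per-component sign
        for comp in range(s1.shape[1]):
            direct = np.allclose(s1[perm, comp], s2[:, comp], atol=1e-8)
            flipped = np.allclose(s1[perm, comp], -s2[:, comp], atol=1e-8)
            assert direct or flipped


class TestLDA:
    def test_planted_clades_classified(self, planted):
        m, ca, gt = planted
        res = cs.lda(m, ca, shrinkage=0.1)
        nonrep = [i for i, o in enumerate(m.organisms) if o not in ca.representatives]
        correct = sum(
            res.predicted_clades[i] == gt.clade_of[m.organisms[i]] for i in nonrep
        )
        assert correct / len(nonrep) >= 0.90

    def test_representatives_classified_consistently(self, planted):
        m, ca, gt = planted
        res = cs.lda(m, ca)
        rep_idx = [i for i, o in enumerate(m.organisms) if o in ca.representatives]
        assert all(
            res.predicted_clades[i] == gt.clade_of[m.organisms[i]] for i in rep_idx
        )

    def test_too_few_groups_or_members_error(self, planted):
        m, _, _ = planted
        one_group = cs.CladeAnnotation(
            {o: "only" for o in m.organisms[:4]}, frozenset(m.organisms[:4])
        )
        with pytest.raises(ValueError, match="2 prior groups"):
            cs.lda(m, one_group)
        lonely = cs.CladeAnnotation(
            {m.organisms[0]: "a", m.organisms[1]: "a", m.organisms[2]: "b"},
            frozenset(m.organisms[:3]),
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            cs.lda(m, lonely)

    def test_identical_groups_degenerate_but_defined(self):
        # both prior groups contain the same three complement vectors, so
        # there is no between-group signal to discriminate on
        block = np.array([[1, 2, 0], [3, 1, 2], [2, 2, 1]])
        counts = np.vstack([block, block])
        m = cs.ParalogCountMatrix([f"o{i}" for i in range(6)], ["f", "g", "h"], counts)
        ca = cs.CladeAnnotation(
            {f"o{i}": ("a" if i < 3 else "b") for i in range(6)},
            frozenset(f"o{i}" for i in range(6)),
        )
        res = cs.lda(m, ca)  # must not crash; classification is chance-level
        assert set(res.predicted_clades) <= {"a", "b"}


class TestPolydomain:
    def test_hand_evaluated_two_by_two(self, tiny_matrix):
        res = cs.polydomain(tiny_matrix)
        np.testing.assert_allclose(res.f, [np.log2(4 / 6), np.log2(2 / 6)])
        # centered f: +0.5 / -0.5 exactly; PD = counts @ centered f
        np.testing.assert_allclose(res.f - res.f_bar, [0.5, -0.5])
        np.testing.assert_allclose(res.PD, [1.5, -0.5])

    def test_uniform_counts_give_zero_scores(self):
        m = cs.ParalogCountMatrix(["a", "b", "c"], ["f", "g"], np.full((3, 2), 7))
        np.testing.assert_allclose(cs.polydomain(m).PD, 0.0, atol=1e-12)

    def test_doubling_counts_doubles_pd(self):
        rng = np.random.default_rng(13)
        m = random_matrix(rng, 6, 4, high=9)
        m2 = cs.ParalogCountMatrix(m.organisms, m.families, m.counts * 2)
        r1, r2 = cs.polydomain(m), cs.polydomain(m2)
        np.testing.assert_allclose(r1.f, r2.f, atol=1e-12)
        np.testing.assert_allclose(r2.PD, 2 * r1.PD, atol=1e-9)

    def test_fractions_normalize_and_center(self):
        rng = np.random.default_rng(14)
        m = random_matrix(rng, 7, 5, high=12)
        res = cs.polydomain(m)
        assert np.sum(2.0 ** res.f) == pytest.approx(1.0)
        assert np.mean(res.f - res.f_bar) == pytest.approx(0.0, abs=1e-12)

    def test_shift_invariance_of_pd(self):
        # PD depends on f only through f - f_bar: shifting f by a constant
        # must leave PD unchanged (recomputed through the shifted path).
        rng = np.random.default_rng(15)
        m = random_matrix(rng, 5, 4, high=9)
        res = cs.polydomain(m)
        shift = 3.7
        f_shifted = res.f + shift
        pd_shifted = m.counts.astype(float) @ (f_shifted - f_shifted.mean())
        np.testing.assert_allclose(pd_shifted, res.PD, atol=1e-9)

    def test_zero_total_family_dropped(self):
        m = cs.ParalogCountMatrix(["a", "b"], ["f", "dead"], np.array([[2, 0], [1, 0]]))
        res = cs.polydomain(m)
        assert res.families == ("f",)

    def test_all_zero_matrix_errors(self):
        m = cs.ParalogCountMatrix(["a"], ["f"], np.array([[0]]))
        with pytest.raises(ValueError, match="all-zero"):
            cs.polydomain(m)


class TestPolydomainHistogram:
    def test_counts_conserved_and_zero_case(self, tiny_matrix):
        res = cs.polydomain(tiny_matrix)
        counts, edges = cs.polydomain_histogram(res, bins=5)
        assert counts.sum() == 2
        zero = cs.PolydomainResult(("a", "b"), ("f",), np.array([0.0]), 0.0, np.zeros(2))
        counts0, _ = cs.polydomain_histogram(zero, bins=4)
        assert (counts0 > 0).sum() == 1

    def test_empty_subset_errors(self, tiny_matrix):
        res = cs.polydomain(tiny_matrix)
        with pytest.raises(ValueError, match="empty"):
            cs.polydomain_histogram(res, subset=[])

    def test_signed_log_scale_preserves_sign_and_order(self):
        x = np.array([-100.0, -1.0, 0.0, 1.0, 100.0])
        y = cs.signed_log10(x)
        assert np.all(np.sign(y) == np.sign(x))
        assert np.all(np.diff(y) > 0)

    def test_expanded_clade_occupies_top_bins(self, planted):
        m, _, gt = planted
        # plant an extra strong amplification on top of clade1's block
        boost = m.counts.copy()
        rows = [i for i, o in enumerate(m.organisms) if gt.clade_of[o] == "clade1"]
        boost[rows, :7] *= 10
        res = cs.polydomain(cs.ParalogCountMatrix(m.organisms, m.families, boost))
        counts, edges = cs.polydomain_histogram(res, bins=10)
        top = {o for o, v in zip(res.organisms, res.PD) if v >= edges[-3]}
        assert top and all(gt.clade_of[o] == "clade1" for o in top)
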