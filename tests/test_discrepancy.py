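import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tmbcat.discrepancy import (
    DiscrepancyError,
    anova_distance,
    rank_distance,
    similarity_distance,
    similarity_matrix,
)


class TestAnovaDistance:
    def test_hand_computed_value(self):
        """Two groups {0.2,0.4} vs {0.6,0.8}: SS_b=0.16, SS_w=0.04, D=8."""
        res = anova_distance([0.2, 0.4, 0.6, 0.8], [1, 1, 2, 2])
        assert res.D == pytest.approx(8.0, abs=1e-12)
        assert res.df == (1, 2)

    def test_null_geometry(self):
        res = anova_distance([0.3, 0.5, 0.3, 0.5], [1, 1, 2, 2])
        assert res.D == pytest.approx(0.0, abs=1e-15)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_within_variance_flagged(self):
        res = anova_distance([0.2, 0.2, 0.8, 0.8], [1, 1, 2, 2])
        assert np.isinf(res.D) and res.p_value == 0.0 and res.note

    def test_single_group_rejected(self):
        with pytest.raises(DiscrepancyError):
            anova_distance([0.1, 0.2, 0.3], [1, 1, 1])

    def test_matches_scipy_oneway(self, rng):
        for _ in range(100):
            n = int(rng.integers(12, 60))
            k1 = int(rng.integers(2, 5))
            labels = rng.integers(1, k1 + 1, n)
            while len(np.unique(labels)) < k1:
                labels = rng.integers(1, k1 + 1, n)
            p = rng.random(n)
            res = anova_distance(p, labels)
            groups = [p[labels == g] for g in np.unique(labels)]
            F, pv = stats.f_oneway(*groups)
            assert res.D == pytest.approx(F, abs=1e-10)
            assert res.p_value == pytest.approx(pv, abs=1e-10)


class TestRankDistance:
    def test_hand_computed_value(self):
        """Ranks 1,2,4,3 -> rank sums (3,7) -> D = 0.6*29 - 15 = 2.4."""
        with pytest.warns(UserWarning, match="5 observations"):
            res = rank_distance([0.1, 0.2, 0.9, 0.8], [1, 1, 2, 2])
        assert res.D == pytest.approx(2.4, abs=1e-12)
        assert res.df == (1,)

    def test_full_ties_collapse(self):
        with pytest.warns(UserWarning):
            res = rank_distance([0.5] * 6, [1, 1, 1, 2, 2, 2])
        assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_kruskal_without_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(14, 60))
            labels = rng.integers(1, 4, n)
            while len(np.unique(labels)) < 3:
                labels = rng.integers(1, 4, n)
            p = rng.permutation(np.linspace(0.01, 0.99, n))  # no ties
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = rank_distance(p, labels, tie_correction=True)
            groups = [p[labels == g] for g in np.unique(labels)]
            H, pv = stats.kruskal(*groups)
            assert res.D == pytest.approx(H, abs=1e-10)
            assert res.p_value == pytest.approx(pv, abs=1e-10)

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_monotone_transform(self, data):
        """Rank statistics depend only on orderings."""
        n = data.draw(st.integers(12, 30))
        ints = data.draw(
            st.lists(st.integers(0, 10**6), min_size=n, max_size=n, unique=True)
        )
        p = np.asarray(ints, dtype=float) * 1e-6
        labels = np.asarray([1 + i % 2 for i in range(n)])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d1 = rank_distance(p, labels).D
            d2 = rank_distance(np.exp(5 * p) + p**3, labels).D
        assert d1 == pytest.approx(d2, abs=1e-10)


class TestSimilarityMatrix:
    def test_identity_covariance_reduces_to_euclidean(self, rng):
        X = rng.random((10, 2))
        M = similarity_matrix(X, metric="mahalanobis", V=np.eye(2))
        E = similarity_matrix(X, metric="euclidean")
        np.testing.assert_allclose(M, E, atol=1e-12)

    def test_duplicate_patients_zero_distance(self):
        X = np.array([[0.2, 0.4], [0.2, 0.4], [0.8, 0.1]])
        D = similarity_matrix(X)
        assert D[0, 1] == 0.0 and D[0, 2] > 0

    def test_mahalanobis_matches_whitening_oracle(self, rng):
        X = rng.random((25, 2))
        V = np.cov(X, rowvar=False)
        D = similarity_matrix(X, metric="mahalanobis", V=V)
        L = np.linalg.cholesky(np.linalg.inv(V))
        W = X @ L  # whiten, then plain euclidean
        E = similarity_matrix(W, metric="euclidean")
        np.testing.assert_allclose(D, E, atol=1e-12)

    def test_singular_covariance_rejected(self):
        X = np.array([[0.1, 0.2], [0.2, 0.4], [0.3, 0.6], [0.4, 0.8]])
        with pytest.raises(DiscrepancyError, match="singular|positive"):
            similarity_matrix(X, metric="mahalanobis", V=np.ones((2, 2)))


class TestSimilarityDistance:
    def test_hand_computed_maximal_separation(self):
        """{0.1,0.2 | 0.9,1.0}: r_w=1.5, r_b=4.5 -> D = 3/3 = 1."""
        D = similarity_matrix(np.array([0.1, 0.2, 0.9, 1.0]))
        res = similarity_distance(D, [1, 1, 2, 2], n_perm=99, seed=0)
        assert res.D == pytest.approx(1.0, abs=1e-12)

    def test_constant_distances_give_zero(self):
        D = np.ones((6, 6)) - np.eye(6)
        res = similarity_distance(D, [1, 1, 1, 2, 2, 2], n_perm=99, seed=0)
        assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_all_singletons_rejected(self):
        D = similarity_matrix(np.array([0.1, 0.4, 0.7, 0.9]))
        with pytest.raises(DiscrepancyError, match="within-group"):
            similarity_distance(D, [1, 2, 3, 4], n_perm=9)

    def test_matches_skbio_anosim_statistic(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim

        for _ in range(20):
            n = int(rng.integers(8, 24))
            X = rng.random((n, 2))
            labels = rng.integers(1, 3, n)
            while len(np.unique(labels)) < 2 or min(
                (labels == g).sum() for g in (1, 2)
            ) < 2:
                labels = rng.integers(1, 3, n)
            D = similarity_matrix(X)
            ours = similarity_distance(D, labels, n_perm=9, seed=1).D
            dm = skbio.DistanceMatrix(D)
            theirs = anosim(dm, [str(g) for g in labels], permutations=9)["test statistic"]
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_seeded_permutation_p_reproducible(self, rng):
        X = rng.random(16)
        D = similarity_matrix(X)
        labels = [1] * 8 + [2] * 8
        r1 = similarity_distance(D, labels, n_perm=499, seed=7)
        r2 = similarity_distance(D, labels, n_perm=499, seed=7)
        assert r1.p_value == r2.p_value

    def test_bounds_and_relabeling_invariance(self, rng):
        for _ in range(25):
            n = int(rng.integers(8, 30))
            X = rng.random(n)
            labels = rng.integers(1, 4, n)
            while min((labels == g).sum() for g in np.unique(labels)) < 2:
                labels = rng.integers(1, 4, n)
            D = similarity_matrix(X)
            res = similarity_distance(D, labels, n_perm=9, seed=3)
            assert -1.0 <= res.D <= 1.0
            relabeled = np.select(
                [labels == 1, labels == 2, labels == 3], [9, 4, 1], labels
            )
            res2 = similarity_distance(D, relabeled, n_perm=9, seed=3)
            assert res2.D == pytest.approx(res.D, abs=1e-12)


class TestCommonInvariances:
    def test_patient_order_invariance(self, rng):
        """All three statistics ignore the ordering of patients."""
        n = 24
        p = rng.random(n)
        labels = np.repeat([1, 2, 3], 8)
        perm = rng.permutation(n)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert anova_distance(p, labels).D == pytest.approx(
                anova_distance(p[perm], labels[perm]).D, abs=1e-10
            )
            assert rank_distance(p, labels).D == pytest.approx(
                rank_distance(p[perm], labels[perm]).D, abs=1e-10
            )
        d1 = similarity_distance(similarity_matrix(p), labels, n_perm=9, seed=5).D
        d2 = similarity_distance(
            similarity_matrix(p[perm]), labels[perm], n_perm=9, seed=5
        ).D
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_similarity_invariant_under_positive_affine(self, rng):
        p = rng.random(20)
        labels = np.repeat([1, 2], 10)
        d1 = similarity_distance(similarity_matrix(p), labels, n_perm=9, seed=5).D
        d2 = similarity_distance(
            similarity_matrix(3.5 * p + 1.2), labels, n_perm=9, seed=5
        ).D
        assert d1 == pytest.approx(d2, abs=1e-12)
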