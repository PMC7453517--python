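"""Wealth index, quintiles and weighted fractional ranks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.decomposition import PCA

from cidecomp.wealth import (WealthIndex, fractional_rank, rank_households,
                             wealth_quintiles)


def _weighted_corr_pc1_oracle(A, w):
    """Independent longhand oracle: first eigenvector of the weighted
    correlation matrix, computed with explicit loops."""
    A = np.asarray(A, dtype=float)
    n, k = A.shape
    W = w.sum()
    mean = np.array([sum(w[i] * A[i, j] for i in range(n)) / W for j in range(k)])
    sd = np.array([np.sqrt(sum(w[i] * (A[i, j] - mean[j]) ** 2 for i in range(n)) / W)
                   for j in range(k)])
    Z = (A - mean) / sd
    C = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            C[a, b] = sum(w[i] * Z[i, a] * Z[i, b] for i in range(n)) / W
    evals, evecs = np.linalg.eigh(C)
    return Z @ evecs[:, -1]


class TestWealthIndex:
    def test_scores_match_eigendecomposition_oracle(self, rng):
        A = rng.binomial(1, [0.3, 0.5, 0.7], size=(40, 3)).astype(float)
        w = rng.uniform(0.5, 1.5, 40)
        score = WealthIndex().fit(A, sample_weight=w).transform(A)
        oracle = _weighted_corr_pc1_oracle(A, w)
        if np.dot(score, oracle) < 0:
            oracle = -oracle
        np.testing.assert_allclose(score, oracle, atol=1e-10)

    def test_toy_4x3_matches_oracle(self):
        A = np.array([[0, 0, 1], [0, 1, 1], [1, 1, 0], [1, 1, 1]], dtype=float)
        w = np.array([1.0, 2.0, 1.0, 0.5])
        score = WealthIndex().fit(A, sample_weight=w).transform(A)
        oracle = _weighted_corr_pc1_oracle(A, w)
        if np.dot(score, oracle) < 0:
            oracle = -oracle
        np.testing.assert_allclose(score, oracle, atol=1e-10)

    def test_unweighted_matches_sklearn_pca_direction(self, rng):
        A = rng.normal(size=(60, 4))
        score = WealthIndex(weighted=False).fit(A).transform(A)
        Z = (A - A.mean(0)) / A.std(0)
        ref = PCA(n_components=1).fit_transform(Z).ravel()
        corr = np.corrcoef(score, ref)[0, 1]
        assert abs(abs(corr) - 1.0) < 1e-10

    def test_duplicated_informative_column_gives_that_column(self):
        x = np.array([0.0, 1, 0, 1, 1, 0])
        A = np.column_stack([x, x, x])
        score = WealthIndex().fit(A).transform(A)
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(score / np.abs(score).max(), z / np.abs(z).max(), atol=1e-10)

    def test_orientation_flip_negates_scores(self, rng):
        rich = rng.binomial(1, 0.5, 50).astype(float)
        A = pd.DataFrame({"rich": rich, "also_rich": rich, "poor": 1 - rich,
                          "noise": rng.binomial(1, 0.5, 50).astype(float)})
        s_rich = WealthIndex(orient_by="rich").fit(A).transform(A)
        s_poor = WealthIndex(orient_by="poor").fit(A).transform(A)
        np.testing.assert_allclose(s_rich, -s_poor, atol=1e-10)

    def test_constant_column_dropped_with_warning(self, rng):
        A = np.column_stack([rng.binomial(1, 0.5, 30), np.ones(30), rng.binomial(1, 0.4, 30)])
        with pytest.warns(UserWarning, match="constant"):
            idx = WealthIndex().fit(A)
        assert idx.dropped_ == [1]

    def test_all_constant_errors(self):
        with pytest.raises(ValueError, match="nonzero variance"):
            WealthIndex().fit(np.ones((10, 3)))


class TestFractionalRank:
    def test_equal_weights_four_distinct(self):
        r = fractional_rank([10.0, 20, 30, 40])
        np.testing.assert_allclose(r, [0.125, 0.375, 0.625, 0.875])

    def test_unequal_weights_two_rows(self):
        r = fractional_rank([1.0, 2.0], weights=[1.0, 3.0])
        np.testing.assert_allclose(r, [0.125, 0.625])

    def test_all_tied_gives_half(self):
        np.testing.assert_allclose(fractional_rank([3.0, 3, 3]), [0.5, 0.5, 0.5])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fractional_rank([])

    @given(st.lists(st.tuples(st.integers(-5, 5), st.floats(0.1, 10)), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=60)
    def test_weighted_mean_is_half_and_monotone_invariant(self, rows):
        score = np.array([s for s, _ in rows], dtype=float)
        w = np.array([wt for _, wt in rows])
        r = fractional_rank(score, w)
        assert abs(np.average(r, weights=w) - 0.5) < 1e-12
        # strictly monotone transform of the score leaves the ranks unchanged
        np.testing.assert_allclose(fractional_rank(score ** 3, w), r, atol=1e-12)
        # ranks non-decreasing in score
        order = np.argsort(score)
        assert np.all(np.diff(r[order]) >= -1e-12)


class TestQuintiles:
    def test_balanced_ten_rows(self):
        q = wealth_quintiles(np.arange(10.0))
        np.testing.assert_array_equal(q, [1, 1, 2, 2, 3, 3, 4, 4, 5, 5])

    def test_monotone_relabeling_invariance(self, rng):
        s = rng.normal(size=50)
        w = rng.uniform(0.5, 2, 50)
        np.testing.assert_array_equal(wealth_quintiles(s, w), wealth_quintiles(np.exp(s), w))

    def test_concentrated_weight_follows_cumulative_rule(self):
        s = np.arange(5.0)
        w = np.array([10.0, 1, 1, 1, 1])
        # direct cumulative-weight evaluation: cut at ceil(5 * cumw / W)
        cum = np.cumsum(w) / w.sum()
        expected = np.ceil(5 * cum - 1e-9).astype(int)
        np.testing.assert_array_equal(wealth_quintiles(s, w), expected)

    def test_quintile_weight_shares_near_fifth(self, medium_wave):
        # tied scores move as blocks, so shares deviate from 0.2 by at most
        # the largest tie group's weight share
        ranking = rank_households(medium_wave.assets, medium_wave.weights)
        w = pd.Series(medium_wave.weights)
        tie_tol = w.groupby(pd.Series(ranking.score)).sum().max() / w.sum()
        for q in range(1, 6):
            share = w[ranking.quintile == q].sum() / w.sum()
            assert abs(share - 0.2) < tie_tol + 1e-9

    def test_quintile_weight_shares_exact_bound_on_distinct_scores(self, rng):
        s = rng.normal(size=1000)  # continuous, ties have probability zero
        w = rng.uniform(0.5, 1.5, 1000)
        q = wealth_quintiles(s, w)
        for k in range(1, 6):
            share = w[q == k].sum() / w.sum()
            assert abs(share - 0.2) < w.max() / w.sum() + 1e-9


def test_rank_households_accepts_precomputed_score(rng):
    score = rng.normal(size=30)
    w = rng.uniform(0.5, 1.5, 30)
    ranking = rank_households(None, w, score=score)
    np.testing.assert_allclose(ranking.rank, fractional_rank(score, w))
    assert abs(np.average(ranking.rank, weights=w) - 0.5) < 1e-12
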