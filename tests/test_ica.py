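"""Core decomposition machinery: whitening, Infomax, stability, matching."""

import itertools

import numpy as np
import pytest

from rsnfuse.ica import (
    InfomaxParams,
    amari_index,
    icasso,
    infomax,
    match_components,
    pca_reduce,
)


class TestPcaReduce:
    def test_exact_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10, 3)) @ rng.standard_normal((3, 200))
        wh, Z = pca_reduce(X, 3)
        assert np.abs(wh.reconstruct(Z) - X).max() < 1e-8

    def test_full_k_retains_all_variance(self):
        X = np.random.default_rng(1).standard_normal((12, 40))
        wh, _ = pca_reduce(X, 12)
        assert wh.retained_variance_fraction == pytest.approx(1.0, abs=1e-12)

    def test_retained_variance_matches_eigendecomposition(self):
        # independent oracle: eigen-decompose the row covariance directly
        X = np.random.default_rng(2).standard_normal((50, 20))
        Xc = X - X.mean(axis=1, keepdims=True)
        evals = np.sort(np.linalg.eigvalsh(Xc @ Xc.T / 20))[::-1]
        wh, _ = pca_reduce(X, 5)
        assert wh.retained_variance_fraction == pytest.approx(
            evals[:5].sum() / evals.sum(), rel=1e-10
        )

    def test_whitened_rows_are_uncorrelated_unit_variance(self):
        X = np.random.default_rng(3).standard_normal((30, 500))
        _, Z = pca_reduce(X, 8)
        C = Z @ Z.T / Z.shape[1]
        assert np.abs(C - np.eye(8)).max() < 1e-6

    def test_reducing_dewhitening_inverse_pair(self):
        X = np.random.default_rng(4).standard_normal((20, 100))
        wh, _ = pca_reduce(X, 6)
        assert np.abs(wh.reducing @ wh.dewhitening - np.eye(6)).max() < 1e-8
        assert np.all(np.diff(wh.eigenvalues) <= 1e-12)

    def test_k_beyond_rank_raises_with_rank_named(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((10, 2)) @ rng.standard_normal((2, 50))
        with pytest.raises(ValueError, match="rank"):
            pca_reduce(X, 5)

    def test_nonfinite_rejected(self):
        X = np.ones((4, 4))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            pca_reduce(X, 2)


class TestInfomax:
    def test_identity_mixing_recovers_sources(self):
        rng = np.random.default_rng(6)
        S = rng.laplace(size=(3, 4000))
        S = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
        res = infomax(S, seed=0)
        _, _, r = match_components(res.sources, S)
        assert np.all(r >= 0.99)

    def test_random_mixing_low_amari_index(self, laplace_mixture):
        A, S, X = laplace_mixture
        wh, Z = pca_reduce(X, 3)
        res = infomax(Z, seed=1, whitening=wh)
        assert amari_index(res.unmixing @ (wh.reducing @ A)) < 0.05

    def test_equal_seed_bitwise_identical(self, laplace_mixture):
        _, _, X = laplace_mixture
        wh, Z = pca_reduce(X, 3)
        r1 = infomax(Z, seed=7, whitening=wh)
        r2 = infomax(Z, seed=7, whitening=wh)
        assert np.array_equal(r1.unmixing, r2.unmixing)
        assert np.array_equal(r1.sources, r2.sources)

    def test_unmixing_reproduces_sources_exactly(self, laplace_mixture):
        _, _, X = laplace_mixture
        wh, Z = pca_reduce(X, 3)
        res = infomax(Z, seed=2, whitening=wh)
        assert np.abs(res.unmixing @ Z - res.sources).max() < 1e-8

    def test_sign_convention_largest_element_positive(self, laplace_mixture):
        _, _, X = laplace_mixture
        wh, Z = pca_reduce(X, 3)
        res = infomax(Z, seed=3, whitening=wh)
        peaks = res.sources[np.arange(3), np.argmax(np.abs(res.sources), axis=1)]
        assert np.all(peaks > 0)

    def test_divergence_raises_actionable_error(self, laplace_mixture):
        _, _, X = laplace_mixture
        wh, Z = pca_reduce(X, 3)
        with pytest.raises(FloatingPointError, match="learning rate"):
            infomax(Z, params=InfomaxParams(learning_rate=50.0), seed=0)


class TestAmariIndex:
    def test_identity_is_zero(self):
        assert amari_index(np.eye(4)) == 0.0

    def test_scaled_permutation_is_zero(self):
        P = np.zeros((3, 3))
        P[0, 2], P[1, 0], P[2, 1] = 2.0, -0.5, 7.0
        assert amari_index(P) == pytest.approx(0.0, abs=1e-12)

    def test_all_ones_matrix_is_maximal(self):
        assert amari_index(np.ones((2, 2))) == pytest.approx(1.0)

    def test_zero_row_rejected(self):
        P = np.eye(3)
        P[1] = 0.0
        with pytest.raises(ValueError):
            amari_index(P)

    @pytest.mark.parametrize("seed", range(5))
    def test_global_scale_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.standard_normal((4, 4))
        perm = rng.permutation(4)
        assert amari_index(3.7 * P[perm]) == pytest.approx(amari_index(P), rel=1e-9)


class TestMatchComponents:
    def test_self_match_is_identity(self):
        S = np.random.default_rng(8).standard_normal((4, 100))
        perm, signs, r = match_components(S, S)
        assert np.array_equal(perm, np.arange(4))
        assert np.all(signs == 1.0)
        assert np.allclose(r, 1.0)

    def test_recovers_permutation_and_negation(self):
        S = np.random.default_rng(9).standard_normal((4, 100))
        p = np.array([2, 0, 3, 1])
        flip = np.array([1.0, -1.0, -1.0, 1.0])
        S_est = flip[:, None] * S[p]
        perm, signs, r = match_components(S_est, S)
        assert np.allclose(r, 1.0)
        for i in range(4):
            assert np.allclose(signs[i] * S_est[perm[i]], S[i])

    def test_assignment_equals_exhaustive_search(self):
        # brute-force oracle over all 4! permutations of |corr| totals
        S_true = np.random.default_rng(10).standard_normal((4, 60))
        S_est = np.random.default_rng(11).standard_normal((4, 60))
        R = np.abs(np.corrcoef(S_true, S_est)[:4, 4:])
        best = max(
            (sum(R[i, p[i]] for i in range(4)), p)
            for p in itertools.permutations(range(4))
        )
        perm, _, r = match_components(S_est, S_true)
        assert r.sum() == pytest.approx(best[0], rel=1e-12)

    def test_zero_variance_component_rejected(self):
        S = np.random.default_rng(12).standard_normal((3, 50))
        bad = S.copy()
        bad[1] = 1.0
        with pytest.raises(ValueError):
            match_components(bad, S)


class TestIcasso:
    def test_identical_seeds_give_near_perfect_iq(self, laplace_mixture):
        _, _, X = laplace_mixture
        st = icasso(X, 3, n_runs=4, seeds=[5, 5, 5, 5])
        assert np.all(st.iq_per_component > 0.9)

    def test_strong_sources_are_stable(self, laplace_mixture):
        _, _, X = laplace_mixture
        st = icasso(X, 3, n_runs=5)
        assert st.iq_per_component.mean() > 0.9
        assert np.all(st.iq_per_component <= 1.0) and np.all(st.iq_per_component >= -1.0)

    def test_noise_degrades_stability(self, laplace_mixture):
        _, _, X = laplace_mixture
        st_clean = icasso(X, 3, n_runs=4)
        noisy = np.random.default_rng(13).standard_normal((6, 5000)) * 5.0 + X
        st_noisy = icasso(noisy, 3, n_runs=4)
        assert st_noisy.iq_per_component.mean() < st_clean.iq_per_component.mean()

    def test_requires_at_least_two_runs(self, laplace_mixture):
        _, _, X = laplace_mixture
        with pytest.raises(ValueError):
            icasso(X, 3, n_runs=1)
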