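import numpy as np
import pytest

from cardiocode.containers import FilterBank, SegmentEnsemble
from cardiocode.ica import (
    IcaConvergenceError,
    decoding_filters,
    fastica,
    match_filters,
    pca_filters,
    symmetric_orthogonalize,
)
from cardiocode.characterize import analytic_envelope
from cardiocode.preprocess import whiten
from cardiocode.synthetic import gen_excitations, gen_gabor_bank, synthesize_observations


class TestSymmetricOrthogonalize:
    def test_orthonormal_input_is_fixed_point(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        np.testing.assert_allclose(symmetric_orthogonalize(q), q, atol=1e-12)

    def test_output_rows_orthonormal(self, rng):
        W = rng.standard_normal((4, 7))
        out = symmetric_orthogonalize(W)
        np.testing.assert_allclose(out @ out.T, np.eye(4), atol=1e-10)

    def test_row_span_preserved(self, rng):
        W = rng.standard_normal((3, 8))
        out = symmetric_orthogonalize(W)
        # projections onto the two row spans must agree
        P_in = W.T @ np.linalg.solve(W @ W.T, W)
        P_out = out.T @ out
        assert np.max(np.abs(P_in - P_out)) < 1e-8

    def test_rank_deficient_raises(self):
        W = np.ones((3, 5))
        with pytest.raises(ValueError, match="rank"):
            symmetric_orthogonalize(W)


class TestFastICA:
    def test_recovers_laplacian_mixture(self, rng):
        """Two Laplacian sources: W V A must be a signed permutation."""
        S = rng.laplace(size=(2, 20_000))
        A = rng.standard_normal((2, 2))
        X = A @ S
        Z, wh = whiten(SegmentEnsemble(data=X), n_components=2)
        um = fastica(Z, seed=0)
        G = um.W @ wh.matrix @ A  # estimated unmixing composed with truth mixing
        G = G / np.max(np.abs(G), axis=1, keepdims=True)
        for row in np.abs(G):
            assert np.sort(row)[-1] > 0.95
            assert np.sort(row)[-2] < 0.05

    def test_rows_orthonormal(self, tiny_ensemble):
        Z, _ = whiten(tiny_ensemble, n_components=8)
        um = fastica(Z, seed=1)
        np.testing.assert_allclose(um.W @ um.W.T, np.eye(8), atol=1e-8)

    def test_unwhitened_input_rejected(self, rng):
        X = rng.standard_normal((4, 2000)) * np.array([[5.0], [1.0], [1.0], [1.0]])
        with pytest.raises(ValueError, match="whiten"):
            fastica(X)

    def test_gaussian_input_does_not_converge(self, rng):
        Z, _ = whiten(SegmentEnsemble(data=rng.standard_normal((8, 8000))), n_components=8)
        with pytest.raises(IcaConvergenceError) as exc:
            fastica(Z, seed=0, max_iter=300)
        assert len(exc.value.deltas) == 300

    def test_deterministic_given_seed(self, tiny_ensemble):
        Z, _ = whiten(tiny_ensemble, n_components=8)
        a = fastica(Z, seed=3)
        b = fastica(Z, seed=3)
        np.testing.assert_array_equal(a.W, b.W)

    def test_cube_nonlinearity_also_recovers(self, tiny_ensemble, tiny_bank):
        Z, wh = whiten(tiny_ensemble, n_components=8)
        um = fastica(Z, nonlinearity="cube", seed=4, max_iter=3000)
        est = decoding_filters(um, wh)
        mr = match_filters(est, tiny_bank, max_lag=16)
        assert mr.median_correlation > 0.9


class TestDecodingFilters:
    def test_recovery_against_ground_truth(self, learned_bank, tiny_bank):
        mr = match_filters(learned_bank, tiny_bank, max_lag=16)
        assert mr.fraction_above(0.9) >= 0.9

    def test_normalize_flag(self, tiny_ensemble):
        Z, wh = whiten(tiny_ensemble, n_components=8)
        um = fastica(Z, seed=5)
        bank = decoding_filters(um, wh, normalize=True)
        np.testing.assert_allclose(bank.norms(), 1.0, atol=1e-12)

    def test_mixing_times_pseudoinverse_is_identity(self, tiny_ensemble):
        Z, wh = whiten(tiny_ensemble, n_components=8)
        um = fastica(Z, seed=5)
        A = decoding_filters(um, wh, normalize=False).filters.T
        P = A @ np.linalg.pinv(A)
        # projection onto the retained 8-dim subspace, idempotent
        np.testing.assert_allclose(P @ P, P, atol=1e-8)
        assert abs(np.trace(P) - 8) < 1e-6

    def test_matches_sklearn_fastica(self, tiny_ensemble):
        """Independent implementation cross-check on identical whitened data."""
        sklearn_decomp = pytest.importorskip("sklearn.decomposition")
        Z, wh = whiten(tiny_ensemble, n_components=8)
        um = fastica(Z, seed=6, max_iter=3000)
        ours = decoding_filters(um, wh, normalize=True)

        est = sklearn_decomp.FastICA(
            whiten=False, fun="logcosh", random_state=0, max_iter=3000
        )
        est.fit(Z.T)
        A_sk = wh.dewhitening @ est.components_.T  # their unmixing is orthogonal too
        theirs = FilterBank(filters=A_sk.T).normalize()
        mr = match_filters(ours, theirs, max_lag=0)
        assert mr.median_correlation > 0.99


class TestPcaFilters:
    def test_orthogonal_and_sorted(self, tiny_ensemble):
        bank = pca_filters(tiny_ensemble, n=6)
        G = bank.filters @ bank.filters.T
        np.testing.assert_allclose(G, np.eye(6), atol=1e-10)
        assert np.all(np.diff(bank.eigenvalues) <= 1e-12)

    def test_pca_filters_less_time_localized_than_ica(self, tiny_ensemble, learned_bank):
        """PCA mixes the localized generators into global filters."""

        def rms_spread(h):
            e2 = analytic_envelope(h) ** 2
            t = np.arange(e2.size)
            w = e2 / e2.sum()
            mu = (t * w).sum()
            return np.sqrt(((t - mu) ** 2 * w).sum())

        pca = pca_filters(tiny_ensemble, n=8)
        s_pca = np.mean([rms_spread(h) for h in pca.filters])
        s_ica = np.mean([rms_spread(h) for h in learned_bank.filters])
        assert s_pca / s_ica > 1.0


class TestMatchFilters:
    def test_identical_banks(self, tiny_bank):
        mr = match_filters(tiny_bank, tiny_bank)
        np.testing.assert_allclose(mr.correlations, 1.0, atol=1e-9)
        np.testing.assert_array_equal(mr.permutation, np.arange(tiny_bank.n_filters))

    def test_sign_invariant(self, tiny_bank):
        negated = FilterBank(filters=-tiny_bank.filters)
        mr = match_filters(negated, tiny_bank)
        np.testing.assert_allclose(mr.correlations, 1.0, atol=1e-9)
        assert np.all(mr.signs == -1)

    def test_known_permutation_recovered(self, tiny_bank, rng):
        perm = rng.permutation(tiny_bank.n_filters)
        shuffled = FilterBank(filters=tiny_bank.filters[perm])
        mr = match_filters(shuffled, tiny_bank)
        # truth j should map to the shuffled position holding filter j
        np.testing.assert_array_equal(mr.permutation, np.argsort(perm)[np.arange(len(perm))])

    def test_fewer_estimates_rejected(self, tiny_bank):
        small = FilterBank(filters=tiny_bank.filters[:4])
        with pytest.raises(ValueError, match="at least"):
            match_filters(small, tiny_bank)


class TestIdentifiabilityScaling:
    def test_recovery_improves_with_windows(self):
        M, N = 16, 64
        truth = gen_gabor_bank(M, N, freq_lo=2.0 / N, seed=20)
        medians = []
        for P in (500, 2000, 8000):
            exc = gen_excitations(M, N, P, seed=21)
            ens = synthesize_observations(truth, exc)
            Z, wh = whiten(ens, n_components=M)
            um = fastica(Z, seed=22, max_iter=3000)
            mr = match_filters(decoding_filters(um, wh), truth, max_lag=16)
            medians.append(mr.median_correlation)
        assert medians[0] < medians[1] < medians[2]

    def test_seed_invariance_of_learned_subspace(self, tiny_ensemble):
        Z, wh = whiten(tiny_ensemble, n_components=8)
        bank1 = decoding_filters(fastica(Z, seed=31, max_iter=3000), wh)
        bank2 = decoding_filters(fastica(Z, seed=32, max_iter=3000), wh)
        mr = match_filters(bank1, bank2, max_lag=5)
        assert mr.median_correlation > 0.9
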