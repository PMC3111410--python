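import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats

from cardiocode.containers import FilterBank
from cardiocode.synthetic import (
    BANDS,
    ExcitationSet,
    gen_excitations,
    gen_gabor_bank,
    gen_rr_series,
    gen_stimulus,
    gen_subband_sparse_dataset,
    simulate_response,
    subband_filter_sos,
    synthesize_observations,
)


class TestExcitations:
    def test_one_impulse_per_source_and_no_overlap(self):
        exc = gen_excitations(2, 8, 50, seed=0)
        dense = exc.to_dense()
        # exactly one nonzero entry per source per window
        assert np.all(np.count_nonzero(dense, axis=2) == 1)
        for p in range(exc.n_windows):
            assert np.unique(exc.positions[p]).size == exc.n_sources

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            gen_excitations(10, 8, 5, seed=0)

    def test_overlapping_positions_rejected_by_container(self):
        with pytest.raises(ValueError, match="overlap"):
            ExcitationSet(
                positions=np.array([[3, 3]]), amplitudes=np.ones((1, 2)), window_len=8
            )

    def test_source_rows_uncorrelated(self):
        exc = gen_excitations(2, 16, 10_000, seed=1)
        r = np.corrcoef(exc.amplitudes[:, 0], exc.amplitudes[:, 1])[0, 1]
        assert abs(r) < 0.05

    def test_source_rows_low_mutual_information(self):
        """Binned MI between two excitation amplitude rows is ~0 nats."""
        exc = gen_excitations(2, 16, 20_000, seed=2)
        a, b = exc.amplitudes[:, 0], exc.amplitudes[:, 1]
        edges_a = np.quantile(a, np.linspace(0, 1, 9))
        edges_b = np.quantile(b, np.linspace(0, 1, 9))
        joint, _, _ = np.histogram2d(a, b, bins=[edges_a, edges_b])
        p = joint / joint.sum()
        pa, pb = p.sum(axis=1), p.sum(axis=0)
        nz = p > 0
        mi = np.sum(p[nz] * np.log(p[nz] / np.outer(pa, pb)[nz]))
        assert mi < 0.01

    def test_jitter_preserves_distinctness(self):
        exc = gen_excitations(6, 64, 300, seed=3, arrival_jitter=3)
        for p in range(exc.n_windows):
            assert np.unique(exc.positions[p]).size == 6

    def test_reproducible(self):
        a = gen_excitations(4, 32, 100, seed=5)
        b = gen_excitations(4, 32, 100, seed=5)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.amplitudes, b.amplitudes)


class TestGaborBank:
    def test_unit_norms(self):
        bank = gen_gabor_bank(12, 128, seed=0)
        np.testing.assert_allclose(bank.norms(), 1.0, atol=1e-12)

    def test_nyquist_violation(self):
        with pytest.raises(ValueError, match="Nyquist"):
            gen_gabor_bank(4, 64, freq_lo=0.1, freq_hi=0.6)

    def test_spectral_peaks_log_spaced(self):
        n, N = 10, 256
        bank = gen_gabor_bank(n, N, freq_lo=0.05, freq_hi=0.4, seed=1)
        expected = np.geomspace(0.05, 0.4, n)
        nfft = 4096
        freqs = np.fft.rfftfreq(nfft)
        peaks = [
            freqs[np.argmax(np.abs(np.fft.rfft(h, nfft)) ** 2)] for h in bank.filters
        ]
        # within one raw-window frequency bin of the design frequency
        np.testing.assert_allclose(peaks, expected, atol=1.0 / N)


class TestSynthesizeObservations:
    def test_single_impulse_is_delayed_filter(self, tiny_bank):
        t0 = 5
        exc = ExcitationSet(
            positions=np.array([[t0]]), amplitudes=np.array([[1.0]]), window_len=64
        )
        one = FilterBank(filters=tiny_bank.filters[:1])
        ens = synthesize_observations(one, exc)
        expected = np.zeros(64)
        expected[t0:] = one.filters[0][: 64 - t0]
        expected -= expected.mean()
        np.testing.assert_allclose(ens.data[:, 0], expected, atol=1e-12)

    def test_superposition_is_linear(self, tiny_bank):
        two = FilterBank(filters=tiny_bank.filters[:2])
        exc_a = ExcitationSet(np.array([[3, 10]]), np.array([[1.5, 0.0]]), 64)
        exc_b = ExcitationSet(np.array([[3, 10]]), np.array([[0.0, -2.0]]), 64)
        exc_ab = ExcitationSet(np.array([[3, 10]]), np.array([[1.5, -2.0]]), 64)
        sum_ab = (
            synthesize_observations(two, exc_a).data + synthesize_observations(two, exc_b).data
        )
        np.testing.assert_allclose(
            synthesize_observations(two, exc_ab).data, sum_ab, atol=1e-12
        )

    def test_covariance_rank_bounded_by_sources(self, tiny_bank, tiny_ensemble):
        cov = np.cov(tiny_ensemble.data)
        evals = np.linalg.eigvalsh(cov)
        assert np.count_nonzero(evals > 1e-10 * evals.max()) <= tiny_bank.n_filters

    def test_shape_mismatch(self, tiny_bank):
        exc = gen_excitations(4, 32, 10, seed=0)
        with pytest.raises(ValueError, match="filters|length"):
            synthesize_observations(tiny_bank, exc)


class TestSubbandSparse:
    def test_generator_half_power_width(self):
        """The band generator's PSD has a -3 dB width of the design value."""
        sos = subband_filter_sos(0.25, 0.05)
        w, h = sps.sosfreqz(sos, worN=8192, fs=1.0)
        p = np.abs(h) ** 2
        above = w[p >= p.max() / 2]
        assert abs((above.max() - above.min()) - 0.05) < 0.005

    def test_band_supports_cover_range(self):
        bw, lo, hi = 0.05, 0.01, 0.5
        n_bands = int(round((hi - lo) / bw))
        centers = np.linspace(lo + bw / 2, hi - bw / 2, n_bands)
        assert centers[0] - bw / 2 <= lo + 1e-12
        assert centers[-1] + bw / 2 >= hi - 1e-12

    def test_band_source_is_super_gaussian(self):
        """A sparse series through one band generator keeps positive excess kurtosis."""
        rng = np.random.default_rng(0)
        n = 100_000
        src = np.where(rng.random(n) < 1 / 256, rng.laplace(size=n), 0.0)
        out = sps.sosfilt(subband_filter_sos(0.2, 0.05), src)
        assert stats.kurtosis(out) > 0

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="Nyquist|outside|0.5"):
            gen_subband_sparse_dataset(freq_lo=0.3, freq_hi=0.6, n_windows=4, window_len=64)

    def test_windows_centered(self):
        ens = gen_subband_sparse_dataset(n_windows=8, window_len=64, seed=0)
        np.testing.assert_allclose(ens.data.mean(axis=0), 0.0, atol=1e-12)


class TestRRSeriesGenerator:
    def test_clean_series_has_no_outliers(self):
        rr = gen_rr_series(3000, artifact_rate=0.0, seed=1)
        med = np.median(rr.intervals)
        assert np.all(np.abs(rr.intervals - med) < 0.5 * med)

    def test_mean_matches(self):
        rr = gen_rr_series(10_000, mean_rr=0.8, seed=2)
        se = rr.intervals.std() / np.sqrt(len(rr))
        assert abs(rr.intervals.mean() - 0.8) < 3 * se

    def test_welch_band_powers_proportional(self):
        targets = (0.002, 0.001, 0.0005)
        rr = gen_rr_series(2**16, band_powers=targets, seed=5)
        x = rr.intervals - rr.intervals.mean()
        f, p = sps.welch(x, fs=1.0, nperseg=4096)
        for (lo, hi), target in zip(BANDS.values(), targets):
            sel = (f > lo) & (f <= hi)
            measured = np.trapezoid(p[sel], f[sel])
            assert abs(measured - target) < 0.2 * target

    def test_hf_only_power_concentrates(self):
        rr = gen_rr_series(2**14, band_powers=(0.0, 0.0, 0.001), seed=6)
        x = rr.intervals - rr.intervals.mean()
        f, p = sps.welch(x, fs=1.0, nperseg=2048)
        total = np.trapezoid(p, f)
        hf = np.trapezoid(p[(f >= 0.15) & (f <= 0.5)], f[(f >= 0.15) & (f <= 0.5)])
        assert hf / total >= 0.8

    def test_artifact_rate_injects_outliers(self):
        rr = gen_rr_series(5000, artifact_rate=0.02, seed=7)
        med = np.median(rr.intervals)
        n_out = np.count_nonzero(np.abs(rr.intervals - med) > 0.4 * med)
        assert 50 <= n_out <= 150  # ~2% of 5000


class TestStimulus:
    def test_psd_flat_to_corner(self):
        stim = gen_stimulus(30_000.0, seed=4)
        f, p = sps.welch(stim.values, fs=stim.rate_hz, nperseg=512)
        sel = (f > 0) & (f < 0.5)
        assert 10 * np.log10(p[sel].max() / p[sel].min()) < 3.0

    def test_marginal_gaussian(self):
        stim = gen_stimulus(30_000.0, seed=4)
        sub = stim.values[::8][:10_000]  # decorrelate before an iid normality test
        assert stats.normaltest(sub).pvalue > 0.01

    def test_resample_to_1hz(self):
        stim = gen_stimulus(600.0, seed=1)
        assert stim.resample(1.0).values.size == 600


class TestSimulateResponse:
    def test_noiseless_response_is_convolution(self):
        stim = gen_stimulus(500.0, rate_hz=1.0, flat_to_hz=0.4, seed=0)
        h = np.exp(-np.arange(20) / 4.0)
        resp = simulate_response(stim, h, scale=1.0, noise_db=np.inf, baseline_bpm=200.0)
        clean = np.convolve(stim.values, h)[: stim.values.size]
        np.testing.assert_allclose(resp.values - 200.0, clean, atol=1e-9)

    def test_zero_scale_leaves_baseline_noise(self):
        stim = gen_stimulus(500.0, rate_hz=1.0, flat_to_hz=0.4, seed=0)
        h = np.ones(5)
        resp = simulate_response(stim, h, scale=0.0, noise_db=20.0, baseline_bpm=200.0, seed=1)
        # fluctuation is pure noise at unit reference power / 100
        assert abs(np.mean(resp.values) - 200.0) < 0.5

    def test_realized_snr(self):
        stim = gen_stimulus(10_000.0, rate_hz=1.0, flat_to_hz=0.4, seed=7)
        h = np.exp(-np.arange(30) / 5.0)
        resp = simulate_response(stim, h, scale=2.0, noise_db=10.0, baseline_bpm=240.0, seed=8)
        clean = 2.0 * np.convolve(stim.values, h)[: stim.values.size]
        noise = resp.values - 240.0 - clean
        realized = 10 * np.log10(np.mean(clean**2) / np.mean(noise**2))
        assert abs(realized - 10.0) < 0.5
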