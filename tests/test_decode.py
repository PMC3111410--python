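import numpy as np
import pytest

from cardiocode.containers import FilterBank, HeartRateSignal, RRSeries
from cardiocode.decode import (
    SNR_CAP_DB,
    accuracy,
    best_filter,
    fit_scale,
    heart_rate,
    interpolate_filter,
    snr_db,
)
from cardiocode.synthetic import gen_gabor_bank, gen_stimulus, simulate_response


class TestHeartRate:
    @pytest.mark.parametrize("rr_s,bpm", [(1.0, 60.0), (0.5, 120.0)])
    def test_rate_arithmetic(self, rr_s, bpm):
        hr = heart_rate(RRSeries(intervals=[rr_s] * 10))
        np.testing.assert_allclose(hr.values, bpm)

    def test_constant_series_resampled_constant(self):
        hr = heart_rate(RRSeries(intervals=[0.8] * 100), resample_hz=1.0)
        np.testing.assert_allclose(hr.values, 75.0)
        assert hr.rate_hz == 1.0


class TestInterpolateFilter:
    def test_identity_mapping(self, rng):
        h = rng.standard_normal(64)
        np.testing.assert_allclose(interpolate_filter(h, 1.0, 1.0), h, atol=1e-9)

    def test_duration_scales_with_mean_rr(self, rng):
        h = rng.standard_normal(64)
        assert interpolate_filter(h, 1.0, 0.5).size == 32

    def test_spectral_peak_maps_to_hz(self):
        t = np.arange(256)
        f_beat, mean_rr = 0.2, 0.8
        h = np.exp(-((t - 128) ** 2) / (2 * 20.0**2)) * np.cos(2 * np.pi * f_beat * t)
        out = interpolate_filter(h, 2.0, mean_rr)  # 2 Hz grid, 0.8 s beats
        nfft = 8192
        freqs = np.fft.rfftfreq(nfft, d=1 / 2.0)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(out, nfft)) ** 2)]
        assert abs(peak - f_beat / mean_rr) < 1.0 / 256

    def test_energy_preserved(self, rng):
        h = rng.standard_normal(128)
        out = interpolate_filter(h, 4.0, 0.9)
        e_in = np.sum(h**2) * 0.9
        e_out = np.sum(out**2) * 0.25
        assert abs(e_out - e_in) < 0.01 * e_in


class TestFitScale:
    def test_doubled_target(self, rng):
        r = rng.standard_normal(100)
        assert fit_scale(r, 2.0 * r) == pytest.approx(2.0)

    def test_orthogonal_target(self):
        r = np.array([1.0, 0.0, -1.0, 0.0])
        t = np.array([0.0, 1.0, 0.0, -1.0])
        assert fit_scale(r, t) == pytest.approx(0.0)

    def test_least_squares_optimality(self, rng):
        r = rng.standard_normal(200)
        t = rng.standard_normal(200)
        a = fit_scale(r, t)
        best = np.linalg.norm(t - a * r)
        for c in a + rng.uniform(-1, 1, 100):
            assert best <= np.linalg.norm(t - c * r) + 1e-12

    def test_zero_energy_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_scale(np.zeros(10), np.ones(10))


class TestSnrDb:
    def test_perfect_estimate_capped(self, rng):
        x = rng.standard_normal(600)
        windows, overall = snr_db(x, x, window_s=270.0)
        assert overall == SNR_CAP_DB
        assert np.all(windows == SNR_CAP_DB)

    def test_zero_estimate_gives_zero_db(self, rng):
        x = rng.standard_normal(600)
        _, overall = snr_db(x, np.zeros_like(x))
        assert overall == pytest.approx(0.0)

    def test_independent_noise_pair_near_zero(self, rng):
        t = rng.standard_normal(10_000)
        e = t - rng.standard_normal(10_000)  # residual is independent unit noise
        _, overall = snr_db(t, e)
        assert abs(overall) < 0.5

    def test_window_count(self, rng):
        x = rng.standard_normal(1000)
        windows, _ = snr_db(x, 0.5 * x, window_s=270.0, step_s=1.0)
        assert windows.size == 1000 - 270 + 1

    def test_too_short_rejected(self, rng):
        x = rng.standard_normal(100)
        with pytest.raises(ValueError, match="window"):
            snr_db(x, x, window_s=270.0)


class TestAccuracy:
    def test_low_snr_limit_is_chance(self):
        assert accuracy(-100.0) == pytest.approx(50.0, abs=0.1)

    def test_high_snr_limit_is_certainty(self):
        assert accuracy(40.0) == pytest.approx(100.0, abs=1e-6)

    def test_strictly_increasing(self):
        assert accuracy(10.0) < accuracy(14.0)

    def test_custom_mapping(self):
        assert accuracy(10.0, mapping=lambda s: 42.0) == 42.0


@pytest.fixture(scope="module")
def setup():
    bank = gen_gabor_bank(8, 64, freq_lo=2.0 / 64, seed=3)
    stim = gen_stimulus(1800.0, rate_hz=1.0, flat_to_hz=0.4, seed=4)
    return bank, stim


class TestBestFilter:

    def test_noiseless_self_consistency(self, setup):
        bank, stim = setup
        k = 5
        h = interpolate_filter(bank.filters[k], 1.0, 1.0)
        target = simulate_response(stim, h, scale=4.0, noise_db=np.inf, seed=0)
        fit = best_filter(stim, target, bank, mean_rr=1.0)
        assert fit.filter_index == k
        assert fit.snr_overall_db > 60.0
        assert fit.scale == pytest.approx(4.0, rel=1e-6)

    def test_tie_break_lowest_index(self, setup):
        bank, stim = setup
        dup = FilterBank(filters=np.vstack([bank.filters[2], bank.filters[2]]))
        h = interpolate_filter(bank.filters[2], 1.0, 1.0)
        target = simulate_response(stim, h, scale=2.0, noise_db=np.inf, seed=0)
        fit = best_filter(stim, target, dup, mean_rr=1.0)
        assert fit.filter_index == 0

    def test_known_noise_level_recovered(self, setup):
        bank, stim = setup
        h = interpolate_filter(bank.filters[1], 1.0, 1.0)
        target = simulate_response(stim, h, scale=3.0, noise_db=10.0, seed=7)
        fit = best_filter(stim, target, bank, mean_rr=1.0)
        assert abs(fit.snr_overall_db - 10.0) < 1.5

    def test_empty_bank_rejected(self, setup):
        _, stim = setup
        target = HeartRateSignal(values=200 + np.zeros(1800) + 1.0, rate_hz=1.0)
        with pytest.raises(ValueError, match="empty|usable"):
            best_filter(stim, target, FilterBank(filters=np.empty((0, 8))), mean_rr=1.0)
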