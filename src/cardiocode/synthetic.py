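"""Synthetic inputs with the statistical structure the analysis assumes.

The pipeline's generative picture is a bank of FIR filters excited by
sparse (Dirac-like) neuroregulatory impulses whose superposition is the
observable heartbeat-interval fluctuation. This module generates every
input the stages need:

* sparse point-process excitations (:func:`gen_excitations`),
* ground-truth Gabor filter banks (:func:`gen_gabor_bank`),
* observation ensembles mixing the two (:func:`synthesize_observations`),
* the sub-band sparse bias-test dataset (:func:`gen_subband_sparse_dataset`),
* RR-like series with VLF/LF/HF band structure (:func:`gen_rr_series`),
* band-limited Gaussian stimuli and noisy filtered heart-rate responses
  (:func:`gen_stimulus`, :func:`simulate_response`).

Frequencies are expressed in cycles/beat for beat-indexed signals (the
sample axis counts beats, so Nyquist is 0.5 cycles/beat) and in Hz for
time-indexed signals. Every generator takes an explicit seed and is
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .containers import FilterBank, HeartRateSignal, RRSeries, SegmentEnsemble, Stimulus
from .preprocess import segment

__all__ = [
    "ExcitationSet",
    "gen_excitations",
    "gen_gabor_bank",
    "synthesize_observations",
    "gen_subband_sparse_dataset",
    "gen_rr_series",
    "gen_stimulus",
    "simulate_response",
    "BANDS",
]

#: Canonical heartbeat-interval spectral bands in cycles/beat.
BANDS = {"VLF": (0.00, 0.03), "LF": (0.03, 0.15), "HF": (0.15, 0.5)}


@dataclass
class ExcitationSet:
    """Sparse Dirac excitations: one impulse per source per window.

    ``positions[p, i]`` is the integer arrival time of source ``i`` in
    window ``p``; ``amplitudes[p, i]`` the impulse amplitude. Within each
    window the arrival times of distinct sources are distinct
    (non-overlap), which is what renders the filter outputs statistically
    independent in the generative model.
    """

    positions: np.ndarray   # (P, M) ints
    amplitudes: np.ndarray  # (P, M) floats
    window_len: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.positions.shape != self.amplitudes.shape or self.positions.ndim != 2:
            raise ValueError("positions and amplitudes must share shape (P, M)")
        if self.positions.min(initial=0) < 0 or self.positions.max(initial=0) >= self.window_len:
            raise ValueError("impulse positions must lie inside the window")
        for p in range(self.positions.shape[0]):
            row = self.positions[p]
            if np.unique(row).size != row.size:
                raise ValueError(f"window {p}: impulse positions overlap")

    @property
    def n_windows(self) -> int:
        return self.positions.shape[0]

    @property
    def n_sources(self) -> int:
        return self.positions.shape[1]

    def to_dense(self) -> np.ndarray:
        """Dense (P, M, N) impulse array (zeros except one entry per source)."""
        P, M = self.positions.shape
        dense = np.zeros((P, M, self.window_len))
        p_idx = np.repeat(np.arange(P), M)
        m_idx = np.tile(np.arange(M), P)
        dense[p_idx, m_idx, self.positions.ravel()] = self.amplitudes.ravel()
        return dense

    def source_matrix(self) -> np.ndarray:
        """Amplitude matrix (M, P): the latent source value per window."""
        return self.amplitudes.T.copy()


def gen_excitations(
    n_sources: int,
    window_len: int,
    n_windows: int,
    seed: int,
    arrival_jitter: int = 0,
    max_position: Optional[int] = None,
) -> ExcitationSet:
    """Draw sparse Dirac excitations with non-overlapping arrival times.

    Each source fires exactly once per window. Arrival times are drawn
    uniformly without replacement (guaranteeing non-overlap) from
    ``[0, max_position]``; by default each source keeps a characteristic
    arrival time across windows, jittered per window by up to
    ``arrival_jitter`` samples. A stable arrival time is what lets the
    window ensemble be framed as an *instantaneous* mixture (constant
    mixing matrix) — the regime where fixed-point ICA identifies the
    filters; nonzero jitter probes robustness to timing variability.

    ``max_position`` defaults to the smallest range that can host all
    sources (padded to an eighth of the window), keeping impulses early
    so the filters' responses fit inside the observation window instead
    of being truncated at its end.

    Amplitudes follow a Laplace law (heavy-tailed, zero-mean), the
    sparsity structure the learning stage exploits.
    """
    if n_sources > window_len:
        raise ValueError(
            f"cannot place {n_sources} non-overlapping impulses in a "
            f"window of {window_len} samples"
        )
    if max_position is None:
        max_position = min(window_len - 1, max(n_sources - 1, window_len // 8))
    if max_position >= window_len or max_position < n_sources - 1:
        raise ValueError("max_position must allow n_sources distinct positions in-window")
    rng = np.random.default_rng(seed)

    base = rng.choice(max_position + 1, size=n_sources, replace=False)
    positions = np.tile(base, (n_windows, 1))
    if arrival_jitter > 0:
        for p in range(n_windows):
            for _ in range(100):
                jit = rng.integers(-arrival_jitter, arrival_jitter + 1, size=n_sources)
                cand = np.clip(base + jit, 0, max_position)
                if np.unique(cand).size == n_sources:
                    positions[p] = cand
                    break
            else:  # pragma: no cover - vanishingly unlikely for sane jitter
                positions[p] = base

    amplitudes = rng.laplace(loc=0.0, scale=1.0, size=(n_windows, n_sources))
    return ExcitationSet(positions=positions, amplitudes=amplitudes, window_len=window_len)


def gen_gabor_bank(
    n_filters: int,
    window_len: int,
    freq_lo: float = 0.01,
    freq_hi: float = 0.5,
    seed: int = 0,
) -> FilterBank:
    """Unit-norm Gabor atoms with log-spaced frequencies.

    Frequencies are log-spaced in ``[freq_lo, freq_hi]``; envelope centers
    are spread across the middle of the window with a seeded offset, and
    envelope widths scale inversely with frequency (capped so the atom
    support fits the window).
    """
    if not (0 < freq_lo < freq_hi):
        raise ValueError("need 0 < freq_lo < freq_hi")
    if freq_hi > 0.5:
        raise ValueError(f"freq_hi={freq_hi} exceeds the Nyquist limit of 0.5 cycles/sample")
    rng = np.random.default_rng(seed)

    freqs = np.geomspace(freq_lo, freq_hi, n_filters)
    t = np.arange(window_len)
    filters = np.empty((n_filters, window_len))
    # envelope centered mid-window +/- a seeded spread so atoms tile time
    centers = window_len * (0.25 + 0.35 * rng.random(n_filters))
    for i, f in enumerate(freqs):
        # a few cycles under the envelope, capped so the support fits the window
        width = min(window_len / 8.0, max(3.0, 1.5 / f))
        phase = rng.uniform(-math.pi, math.pi)
        atom = np.exp(-0.5 * ((t - centers[i]) / width) ** 2) * np.cos(
            2 * math.pi * f * (t - centers[i]) + phase
        )
        norm = np.linalg.norm(atom)
        if norm == 0:  # pragma: no cover
            raise RuntimeError("degenerate Gabor atom")
        filters[i] = atom / norm
    return FilterBank(filters=filters, provenance="gabor", normalized=True)


def synthesize_observations(bank: FilterBank, excitations: ExcitationSet) -> SegmentEnsemble:
    """Mix Dirac excitations through a filter bank into observation windows.

    Each window is the superposition over sources of the filter's impulse
    response delayed to the source's arrival time, with truncated linear
    convolution (samples shifted past the window end are dropped — no
    wrap-around). Windows are centered afterwards, matching the
    zero-mean contract of :class:`SegmentEnsemble`.
    """
    if bank.n_filters != excitations.n_sources:
        raise ValueError(
            f"bank has {bank.n_filters} filters but excitations have "
            f"{excitations.n_sources} sources"
        )
    if bank.length != excitations.window_len:
        raise ValueError(
            f"bank length {bank.length} != excitation window {excitations.window_len}"
        )
    N = bank.length
    P = excitations.n_windows
    X = np.zeros((N, P))
    for i in range(bank.n_filters):
        h = bank.filters[i]
        pos_i = excitations.positions[:, i]
        amp_i = excitations.amplitudes[:, i]
        for shift in np.unique(pos_i):
            mask = pos_i == shift
            shifted = np.zeros(N)
            shifted[shift:] = h[: N - shift]
            X[:, mask] += np.outer(shifted, amp_i[mask])
    offsets = X.mean(axis=0)
    X -= offsets[None, :]
    return SegmentEnsemble(data=X, offsets=offsets, label="synthesized")


def subband_filter_sos(center: float, band_width: float, order: int = 2) -> np.ndarray:
    """Second-order-sections bandpass generator for one sub-band.

    Butterworth design whose passband edges sit at ``center +/- band_width/2``;
    at the edges the amplitude response is -3 dB, i.e. the *power* response
    is half its peak, so the generator's -3 dB (half-power) bandwidth is
    ``band_width`` by construction. Edges are clipped to (0, 0.5).
    """
    lo = center - band_width / 2.0
    hi = center + band_width / 2.0
    lo = max(lo, 1e-3)
    hi = min(hi, 0.499)
    if not lo < hi:
        raise ValueError(f"degenerate band [{lo}, {hi}] for center {center}")
    return sps.butter(order, [lo, hi], btype="bandpass", output="sos", fs=1.0)


def gen_subband_sparse_dataset(
    n_bands: Optional[int] = None,
    band_width: float = 0.05,
    freq_lo: float = 0.01,
    freq_hi: float = 0.5,
    n_windows: int = 4096,
    window_len: int = 256,
    seed: int = 0,
    activation_prob: Optional[float] = None,
    spectral_exponent: float = 0.0,
    order: int = 2,
) -> SegmentEnsemble:
    """Sparse sub-band-modulated ensemble (the bias-test dataset).

    ``n_bands`` independent sparse heavy-tailed source series (Bernoulli
    gating at ``activation_prob``, default one event per window on
    average, with Laplace amplitudes) are each passed through a
    Butterworth bandpass generator of -3 dB (half-power) width
    ``band_width``. By default the bands tile ``[freq_lo, freq_hi]``
    contiguously (``n_bands = round((freq_hi - freq_lo) / band_width)``,
    ten bands for the defaults), i.e. the band *supports* cover the
    range; passing ``n_bands`` explicitly spaces the centers so the
    outermost band edges still stay inside ``[freq_lo, freq_hi]``. Edges
    falling outside (0, 0.5) are clipped. The superposition is segmented
    into centered ``window_len``-sample windows.

    A nonzero ``spectral_exponent`` g weights each band's amplitude by
    ``center**(-g/2)``, giving the ensemble a ``1/f**g`` population
    spectrum — the input for power-law recovery experiments.
    """
    if not (0 < freq_lo < freq_hi <= 0.5):
        raise ValueError("need 0 < freq_lo < freq_hi <= 0.5 (cycles/beat)")
    if freq_lo + band_width / 2.0 <= 0 or freq_lo + band_width / 2.0 > 0.5:
        raise ValueError("lowest band extends outside (0, 0.5]")
    if freq_hi - band_width / 2.0 > 0.5:
        raise ValueError("highest band extends past the Nyquist frequency")
    if n_bands is None:
        n_bands = max(1, int(round((freq_hi - freq_lo) / band_width)))
    if activation_prob is None:
        activation_prob = 1.0 / window_len
    if not 0 < activation_prob <= 1:
        raise ValueError("activation_prob must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    n_samples = n_windows * window_len
    c_lo = freq_lo + band_width / 2.0
    c_hi = freq_hi - band_width / 2.0
    if n_bands == 1:
        centers = np.array([(c_lo + c_hi) / 2.0])
    else:
        centers = np.linspace(c_lo, c_hi, n_bands)
    x = np.zeros(n_samples)
    for c in centers:
        sos = subband_filter_sos(c, band_width, order=order)
        events = rng.random(n_samples) < activation_prob
        amps = rng.laplace(0.0, 1.0, size=n_samples)
        source = np.where(events, amps, 0.0)
        gain = c ** (-spectral_exponent / 2.0) if spectral_exponent != 0.0 else 1.0
        x += gain * sps.sosfilt(sos, source)
    ens = segment(x, window_len=window_len)
    ens.label = "subband-sparse"
    return ens


def _band_limited_gaussian(
    n: int, f_lo: float, f_hi: float, variance: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean Gaussian series with power confined to [f_lo, f_hi] cycles/sample."""
    if variance == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    spec[~mask] = 0.0
    out = np.fft.irfft(spec, n=n)
    sd = out.std()
    if sd == 0:  # pragma: no cover - only for pathological tiny n
        return out
    return out * (math.sqrt(variance) / sd)


def gen_rr_series(
    n_beats: int,
    mean_rr: float = 0.9,
    band_powers: Sequence[float] = (0.0016, 0.0012, 0.0008),
    artifact_rate: float = 0.0,
    seed: int = 0,
) -> RRSeries:
    """RR-like series: mean + three band-limited Gaussian processes + artifacts.

    ``band_powers`` are the variances (s^2) of the VLF (0.00-0.03), LF
    (0.03-0.15) and HF (0.15-0.5 cycles/beat) components. Artifacts are
    ectopic-like: randomly chosen intervals halved or doubled at rate
    ``artifact_rate``. Defaults give a resting-adult-like series
    (mean RR 0.9 s, total variability ~60 ms SD, VLF-dominated spectrum).
    """
    if mean_rr <= 0:
        raise ValueError("mean_rr must be positive")
    if not 0 <= artifact_rate < 1:
        raise ValueError("artifact_rate must lie in [0, 1)")
    if len(band_powers) != 3:
        raise ValueError("band_powers must give (VLF, LF, HF) variances")
    rng = np.random.default_rng(seed)

    x = np.full(n_beats, float(mean_rr))
    for (f_lo, f_hi), power in zip(BANDS.values(), band_powers):
        x += _band_limited_gaussian(n_beats, max(f_lo, 1.0 / n_beats), f_hi, power, rng)
    # keep intervals physiological/positive even for generous band powers
    x = np.clip(x, 0.2 * mean_rr, None)

    if artifact_rate > 0:
        hits = rng.random(n_beats) < artifact_rate
        factor = np.where(rng.random(n_beats) < 0.5, 0.5, 2.0)
        x = np.where(hits, x * factor, x)
    return RRSeries(intervals=x, label="synthetic-rr")


def gen_stimulus(
    duration_s: float,
    flat_to_hz: float = 0.5,
    rate_hz: float = 4.0,
    seed: int = 0,
) -> Stimulus:
    """Band-limited Gaussian white-noise stimulus.

    Gaussian signal whose power spectrum is flat up to ``flat_to_hz`` and
    rolls off smoothly above (Gaussian roll-off reaching 1/10 amplitude
    ~0.3 Hz past the corner), emulating a nerve-stimulation voltage
    drawn from band-limited white noise. Use :meth:`Stimulus.resample`
    for 1 Hz copies.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if flat_to_hz >= rate_hz / 2:
        raise ValueError("flat_to_hz must be below the Nyquist frequency")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    # amplitude gain exp(-((f-f0)/sigma)^2), chosen so gain(f0 + 0.3 Hz) = 1/10
    rolloff_sigma = 0.3 / math.sqrt(math.log(10.0))
    gain = np.where(
        freqs <= flat_to_hz,
        1.0,
        np.exp(-(((freqs - flat_to_hz) / rolloff_sigma) ** 2)),
    )
    shaped = np.fft.irfft(spec * gain, n=n)
    shaped /= shaped.std()
    return Stimulus(values=shaped, rate_hz=rate_hz, label="bandlimited-gaussian")


def simulate_response(
    stimulus: Stimulus,
    filter_coeffs: np.ndarray,
    scale: float = 1.0,
    noise_db: float = np.inf,
    baseline_bpm: float = 240.0,
    seed: int = 0,
) -> HeartRateSignal:
    """Heart-rate response: scaled stimulus*filter + baseline + noise.

    The clean response is the causal convolution of the stimulus with
    ``filter_coeffs`` (sampled at the stimulus rate), scaled by
    ``scale``; Gaussian noise is added at ``noise_db`` signal-to-noise
    (dB, power ratio of clean fluctuation to noise). ``baseline_bpm``
    defaults to a rabbit-like resting rate.
    """
    h = np.asarray(filter_coeffs, dtype=float)
    if h.ndim != 1:
        raise ValueError("filter_coeffs must be 1-D")
    if h.size >= stimulus.values.size:
        raise ValueError("filter must be shorter than the stimulus")
    rng = np.random.default_rng(seed)

    clean = scale * sps.fftconvolve(stimulus.values, h, mode="full")[: stimulus.values.size]
    if np.isinf(noise_db):
        noise = np.zeros_like(clean)
    else:
        p_clean = float(np.mean(clean**2))
        if p_clean == 0:
            p_clean = 1.0  # scale=0: unit-variance noise floor
        noise_sd = math.sqrt(p_clean / 10 ** (noise_db / 10.0))
        noise = rng.normal(0.0, noise_sd, size=clean.size)
    values = baseline_bpm + clean + noise
    values = np.clip(values, 1e-6, None)  # heart rate stays positive
    return HeartRateSignal(values=values, rate_hz=stimulus.rate_hz, label="simulated-response")
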