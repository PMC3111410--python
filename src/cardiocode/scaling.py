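"""Population spectrum and 1/f power-law analysis of a filter bank.

Healthy heartbeat-interval fluctuations carry a power-law (1/f-like)
amplitude spectrum. If the learned decoding population tiles frequency
with powers matching the data it was learned from, the average response
of the bank to spectrally white noise inherits that falloff. This module
computes the bank's mean power spectrum, its Monte-Carlo white-noise
response, and the slope of a binned log-log fit over a stated frequency
range (excluding the low end, where the finite analysis window precludes
reliable filter estimation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, periodogram

from .containers import FilterBank

__all__ = ["PowerLawFit", "mean_bank_spectrum", "white_noise_response", "loglog_slope"]


@dataclass
class PowerLawFit:
    """Result of an OLS fit of binned log-power against log-frequency."""

    slope: float
    intercept: float
    f_lo: float
    f_hi: float
    n_bins: int
    bin_freqs: np.ndarray    # per-bin mean log10 frequency (as frequency)
    bin_powers: np.ndarray   # per-bin mean log10 power (as power)
    r_squared: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq": self.bin_freqs, "power": self.bin_powers})


def mean_bank_spectrum(
    bank: FilterBank, zero_pad: int = 4096, normalize: bool = True
) -> Tuple[np.ndarray, np.ndarray]:
    """Average power spectrum of a bank on a common frequency grid.

    Each filter's PSD is the squared magnitude of its zero-padded FFT;
    with ``normalize=True`` every PSD is scaled to unit total power
    before averaging so each filter contributes equally, regardless of
    its norm. Returns ``(freqs, mean_psd)``.
    """
    if bank.n_filters == 0:
        raise ValueError("bank is empty")
    freqs = np.fft.rfftfreq(zero_pad, d=1.0)
    psds = np.abs(np.fft.rfft(bank.filters, zero_pad, axis=1)) ** 2
    if normalize:
        totals = psds.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValueError("bank contains an all-zero filter")
        psds = psds / totals
    return freqs, psds.mean(axis=0)


def white_noise_response(
    bank: FilterBank,
    n_reps: int = 200,
    segment_len: int = 1024,
    seed: int = 0,
    bartlett_segments: int = 4,
    window: str = "hann",
) -> Tuple[np.ndarray, np.ndarray]:
    """Average PSD of the bank's response to unit-variance white noise.

    For each repetition a fresh Gaussian white series is convolved with
    every filter; the steady-state part of each response (the leading
    filter-length transient is dropped) is split into
    ``bartlett_segments`` non-overlapping segments whose periodograms
    are averaged (Bartlett estimate), then accumulated over filters and
    repetitions. By the convolution theorem the expectation is
    ``|H_i(f)|^2`` averaged over filters — so a bank whose unnormalized
    filter powers follow a power law responds to white noise with the
    same power law. Returns ``(freqs, mean_response_psd)``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if segment_len < bartlett_segments * 2:
        raise ValueError("segment_len too short for the Bartlett segmentation")
    rng = np.random.default_rng(seed)
    sub_len = segment_len // bartlett_segments
    accum = None
    for _ in range(n_reps):
        noise = rng.standard_normal(segment_len + bank.length - 1)
        responses = fftconvolve(noise[None, :], bank.filters, mode="full", axes=1)
        steady = responses[:, bank.length - 1 : bank.length - 1 + sub_len * bartlett_segments]
        segs = steady.reshape(bank.n_filters * bartlett_segments, sub_len)
        # the hann default tames leakage from spectral peaks into low-power
        # bins; boxcar has lower variance when leakage is not a concern
        freqs, psd = periodogram(segs, fs=1.0, window=window, axis=1)
        mean_psd = psd.mean(axis=0)
        accum = mean_psd if accum is None else accum + mean_psd
    return freqs, accum / n_reps


def loglog_slope(
    freqs: np.ndarray,
    psd: np.ndarray,
    f_lo: float = 0.005,
    f_hi: float = 0.4,
    n_bins: int = 20,
) -> PowerLawFit:
    """Binned log-log slope of a power spectrum.

    Frequencies in ``[f_lo, f_hi]`` are grouped into ``n_bins``
    log-spaced bins; within each bin the mean of ``log10 f`` and
    ``log10 P`` is taken, and an ordinary least-squares line is fitted
    through the bin means. Its slope is the power-law exponent (a
    ``1/f**g`` spectrum gives slope ``-g``).
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if not (0 < f_lo < f_hi <= 0.5):
        raise ValueError("need 0 < f_lo < f_hi <= 0.5")
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    if np.any(psd[sel] <= 0):
        raise ValueError("psd must be strictly positive on the fit range")

    edges = np.geomspace(f_lo, f_hi, n_bins + 1)
    log_f, log_p = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (freqs >= lo) & (freqs < hi)
        m |= (freqs == f_hi) & (hi == edges[-1])
        if not np.any(m):
            raise ValueError(
                f"empty log bin [{lo:.4g}, {hi:.4g}); use fewer bins or a "
                "denser frequency grid"
            )
        log_f.append(np.mean(np.log10(freqs[m])))
        log_p.append(np.mean(np.log10(psd[m])))
    log_f = np.asarray(log_f)
    log_p = np.asarray(log_p)

    slope, intercept = np.polyfit(log_f, log_p, 1)
    pred = slope * log_f + intercept
    ss_res = float(np.sum((log_p - pred) ** 2))
    ss_tot = float(np.sum((log_p - log_p.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    return PowerLawFit(
        slope=float(slope),
        intercept=float(intercept),
        f_lo=f_lo,
        f_hi=f_hi,
        n_bins=n_bins,
        bin_freqs=10.0**log_f,
        bin_powers=10.0**log_p,
        r_squared=r2,
    )
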