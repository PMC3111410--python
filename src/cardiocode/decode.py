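"""Decoding: reproduce a heart-rate response to a stimulus with one filter.

Given a time-varying stimulus and the observed heart-rate response, the
decoding comparison searches the learned filter bank for the member
whose (scaled) convolution with the stimulus best reproduces the
response:

    y_hat = a * (u conv h_k),   e = y - y_hat

with the scale ``a`` solved by least squares (the learning stage is
blind to scale) and ``k`` chosen to minimize the squared error. Fit
quality is quantified as a signal-to-noise ratio in dB over sliding
windows, and mapped to a percent reconstruction accuracy through a
psychophysics-style error-function law.

Filters learned on beat-indexed windows live on a beat axis; they are
mapped to seconds through the mean RR interval and resampled to the
working rate (default 1 Hz) before convolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.signal import fftconvolve, resample
from scipy.special import erf

from .containers import FilterBank, HeartRateSignal, RRSeries, Stimulus

__all__ = [
    "DecodingFit",
    "heart_rate",
    "interpolate_filter",
    "fit_scale",
    "best_filter",
    "snr_db",
    "accuracy",
]

#: SNR cap substituted for an exactly zero residual.
SNR_CAP_DB = 300.0


@dataclass
class DecodingFit:
    """Outcome of the best-filter search for one stimulus/response pair."""

    filter_index: int
    scale: float
    estimate: np.ndarray        # y_hat, beats/min fluctuation around baseline
    residual: np.ndarray
    snr_windows_db: np.ndarray  # sliding-window SNR series
    snr_overall_db: float
    accuracy_pct: float

    def __post_init__(self) -> None:
        if not 0 < self.accuracy_pct <= 100:
            raise ValueError("accuracy must lie in (0, 100]")


def heart_rate(rr: RRSeries, resample_hz: Optional[float] = None) -> HeartRateSignal:
    """Instantaneous heart rate, HR = 60 / RR, in beats/min.

    Without ``resample_hz`` the rate is returned at the (non-uniform)
    beat times re-labelled on their own axis; with it, the rate is
    linearly interpolated onto a uniform grid.
    """
    rates = 60.0 / rr.intervals
    times = rr.beat_times()
    if resample_hz is None:
        # HeartRateSignal is uniform by contract; report at the mean beat rate
        mean_dt = float(np.mean(rr.intervals))
        return HeartRateSignal(values=rates, rate_hz=1.0 / mean_dt, label=rr.label)
    t_grid = np.arange(times[0], times[-1], 1.0 / resample_hz)
    vals = np.interp(t_grid, times, rates)
    return HeartRateSignal(values=vals, rate_hz=resample_hz, label=rr.label)


def interpolate_filter(
    filter_coeffs: np.ndarray,
    target_rate_hz: float = 1.0,
    mean_rr: float = 1.0,
) -> np.ndarray:
    """Map a beat-indexed filter to seconds and resample (band-limited).

    The beat axis is scaled by ``mean_rr`` seconds per beat, so the
    filter spans ``N * mean_rr`` seconds, then Fourier resampling
    produces ``round(N * mean_rr * target_rate_hz)`` samples. A spectral
    peak at ``f`` cycles/beat maps to ``f / mean_rr`` Hz. Continuous-time
    energy (sum h^2 dt) is preserved up to interpolation error.
    """
    if target_rate_hz <= 0 or mean_rr <= 0:
        raise ValueError("target_rate_hz and mean_rr must be positive")
    h = np.asarray(filter_coeffs, dtype=float)
    if h.ndim != 1:
        raise ValueError("filter must be 1-D")
    n_out = int(round(h.size * mean_rr * target_rate_hz))
    if n_out < 2:
        raise ValueError("filter too short at the requested rate")
    if n_out == h.size:
        return h.copy()
    return resample(h, n_out)


def fit_scale(response: np.ndarray, target: np.ndarray) -> float:
    """Least-squares scale: a = <target, response> / <response, response>."""
    response = np.asarray(response, dtype=float)
    target = np.asarray(target, dtype=float)
    if response.shape != target.shape:
        raise ValueError("response and target must have equal length")
    energy = float(response @ response)
    if energy == 0:
        raise ValueError("response has zero energy; cannot fit a scale")
    return float(target @ response) / energy


def snr_db(
    target: np.ndarray,
    estimate: np.ndarray,
    window_s: float = 270.0,
    step_s: float = 1.0,
    rate_hz: float = 1.0,
) -> Tuple[np.ndarray, float]:
    """Sliding-window and overall SNR between a target and its estimate.

    SNR(dB) = 10 log10(P_target / P_residual) with the residual
    ``target - estimate``; windows of ``window_s`` seconds slide by
    ``step_s`` (tail windows shorter than ``window_s`` are dropped). An
    exactly zero residual is reported as the documented cap rather than
    infinity. Returns ``(window_snrs, overall_snr)``.
    """
    target = np.asarray(target, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if target.shape != estimate.shape:
        raise ValueError("target and estimate must have equal length")
    win = int(round(window_s * rate_hz))
    step = max(1, int(round(step_s * rate_hz)))
    if target.size < win:
        raise ValueError("signals shorter than one SNR window")

    residual = target - estimate

    def _snr(t_seg, r_seg) -> float:
        p_t = float(np.mean(t_seg**2))
        p_r = float(np.mean(r_seg**2))
        if p_r == 0:
            return SNR_CAP_DB
        if p_t == 0:
            return -SNR_CAP_DB
        return min(10.0 * math.log10(p_t / p_r), SNR_CAP_DB)

    starts = range(0, target.size - win + 1, step)
    window_snrs = np.array([_snr(target[s : s + win], residual[s : s + win]) for s in starts])
    overall = _snr(target, residual)
    return window_snrs, overall


def accuracy(
    snr_value_db: float,
    mapping: Optional[Callable[[float], float]] = None,
) -> float:
    """Percent reconstruction accuracy from an SNR in dB.

    Default mapping is the two-alternative psychophysics percent-correct
    law ``100 * Phi(sqrt(SNR_linear) / sqrt(2))`` (Phi the standard
    normal CDF, implemented with the error function): chance (50%) at
    vanishing SNR, approaching 100% at high SNR, strictly increasing. A
    custom ``mapping`` from linear SNR to percent may be supplied.
    """
    if not np.isfinite(snr_value_db):
        raise ValueError("SNR must be finite (the cap stands in for infinity)")
    snr_linear = 10.0 ** (snr_value_db / 10.0)
    if mapping is not None:
        return float(mapping(snr_linear))
    return float(50.0 * (1.0 + erf(math.sqrt(snr_linear) / 2.0)))


def best_filter(
    stimulus: Stimulus,
    target: HeartRateSignal,
    bank: FilterBank,
    mean_rr: float = 1.0,
    window_s: float = 270.0,
) -> DecodingFit:
    """Select the filter and scale minimizing the reconstruction error.

    Both signals must share the sampling rate (resample the stimulus
    first if needed). The target's mean (baseline rate) is removed; each
    bank filter is interpolated to the working rate via ``mean_rr``,
    convolved causally with the stimulus, scaled by its least-squares
    coefficient, and scored by squared error. Ties go to the lowest
    filter index.
    """
    if bank.n_filters == 0:
        raise ValueError("bank is empty")
    if abs(stimulus.rate_hz - target.rate_hz) > 1e-9:
        raise ValueError(
            f"stimulus rate {stimulus.rate_hz} Hz != target rate {target.rate_hz} Hz"
        )
    u = stimulus.values
    y = target.values - float(np.mean(target.values))
    L = min(u.size, y.size)
    u, y = u[:L], y[:L]

    best: Optional[Tuple[float, int, float, np.ndarray]] = None
    for k in range(bank.n_filters):
        h = interpolate_filter(bank.filters[k], target.rate_hz, mean_rr)
        if h.size >= L:
            continue
        resp = fftconvolve(u, h, mode="full")[:L]
        energy = float(resp @ resp)
        if energy == 0:
            continue
        a = float(y @ resp) / energy
        err = float(np.sum((y - a * resp) ** 2))
        if best is None or err < best[0] - 1e-12 * max(1.0, best[0]):
            best = (err, k, a, a * resp)
    if best is None:
        raise ValueError("no usable filter in the bank (all empty or too long)")

    _, k, a, estimate = best
    residual = y - estimate
    window_snrs, overall = snr_db(y, estimate, window_s=window_s, rate_hz=target.rate_hz)
    return DecodingFit(
        filter_index=k,
        scale=a,
        estimate=estimate,
        residual=residual,
        snr_windows_db=window_snrs,
        snr_overall_db=overall,
        accuracy_pct=accuracy(min(overall, SNR_CAP_DB)),
    )
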