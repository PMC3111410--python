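"""Per-filter spectral and temporal properties.

Each decoding filter is summarized by the descriptors used throughout the
analysis:

* **center frequency** — location of the power-spectrum maximum;
* **-3 dB bandwidth** — width of the contiguous half-power region around
  that maximum, measured on a zero-padded FFT grid;
* **Q factor** — center frequency / bandwidth (sharpness);
* **damping ratio** — 1 / (2 Q), the second-order-system time-response
  measure (ζ < 1: underdamped / oscillatory);
* **envelope width** — duration of the analytic (Hilbert) envelope's
  region within 3 dB of its energy peak, in samples (beats);
* **localized** — whether the spectral power is concentrated in a single
  peak; filters failing this are excluded from population summaries.

:func:`tf_tile` produces the time-frequency tile of a localized filter —
the extent of the analytic-signal spectrogram above a fraction of its
peak — used to draw the population's joint time-frequency tiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.signal import hilbert, spectrogram

from .containers import FilterBank

__all__ = [
    "FilterProperties",
    "TFTile",
    "analytic_envelope",
    "characterize",
    "characterize_bank",
    "is_localized",
    "tf_tile",
]

DEFAULT_ZERO_PAD = 4096
HALF_POWER = 10 ** (-3.0 / 10.0)  # -3 dB as a power (energy) ratio


@dataclass
class FilterProperties:
    """Descriptors of one filter. Frequencies in cycles/beat, widths in beats."""

    center_freq: float
    bandwidth_3db: float
    q_factor: float
    damping_ratio: float
    envelope_width: float
    localized: bool

    def __post_init__(self) -> None:
        if self.bandwidth_3db > 0:
            assert abs(self.q_factor - self.center_freq / self.bandwidth_3db) < 1e-9
            assert abs(self.damping_ratio - 1.0 / (2.0 * self.q_factor)) < 1e-9


@dataclass
class TFTile:
    """Time/frequency extents of a filter's spectrogram above an energy fraction."""

    time_lo: float
    time_hi: float
    freq_lo: float
    freq_hi: float
    energy_frac: float

    def __post_init__(self) -> None:
        if not (0 <= self.freq_lo <= self.freq_hi <= 0.5 + 1e-12):
            raise ValueError("frequency extent must lie within [0, 0.5]")
        if self.time_lo > self.time_hi:
            raise ValueError("time extent inverted")

    @property
    def time_extent(self) -> float:
        return self.time_hi - self.time_lo

    @property
    def freq_extent(self) -> float:
        return self.freq_hi - self.freq_lo


def analytic_envelope(filter_coeffs: np.ndarray) -> np.ndarray:
    """Amplitude envelope: modulus of the analytic signal (Hilbert transform)."""
    h = np.asarray(filter_coeffs, dtype=float)
    if h.ndim != 1 or h.size < 4:
        raise ValueError("filter must be 1-D with length >= 4")
    return np.abs(hilbert(h))


def _power_spectrum(h: np.ndarray, zero_pad: int) -> Tuple[np.ndarray, np.ndarray]:
    psd = np.abs(np.fft.rfft(h, zero_pad)) ** 2
    freqs = np.fft.rfftfreq(zero_pad, d=1.0)
    return freqs, psd


def _half_power_region(psd: np.ndarray, peak: int) -> Tuple[int, int]:
    """Contiguous index region around ``peak`` with psd >= half the peak value."""
    half = psd[peak] / 2.0
    lo = peak
    while lo > 0 and psd[lo - 1] >= half:
        lo -= 1
    hi = peak
    while hi < psd.size - 1 and psd[hi + 1] >= half:
        hi += 1
    return lo, hi


def is_localized(
    filter_coeffs: np.ndarray,
    concentration_threshold: float = 0.8,
    zero_pad: int = DEFAULT_ZERO_PAD,
) -> bool:
    """True iff the spectral power is concentrated in a single peak.

    The contiguous half-power region around the global PSD maximum must
    hold at least ``concentration_threshold`` of the total power carried
    by *all* samples above the half-maximum level. Multi-modal spectra
    (two well-separated peaks) and flat spectra both fail.
    """
    h = np.asarray(filter_coeffs, dtype=float)
    freqs, psd = _power_spectrum(h, zero_pad)
    peak = int(np.argmax(psd))
    if psd[peak] == 0:
        return False
    lo, hi = _half_power_region(psd, peak)
    half = psd[peak] / 2.0
    above = psd >= half
    total_above = psd[above].sum()
    in_region = psd[lo : hi + 1].sum()
    return bool(in_region >= concentration_threshold * total_above)


def characterize(
    filter_coeffs: np.ndarray,
    zero_pad: int = DEFAULT_ZERO_PAD,
    concentration_threshold: float = 0.8,
) -> FilterProperties:
    """Compute the spectral/temporal descriptors of one filter.

    The PSD is the squared magnitude of the zero-padded FFT (padding
    interpolates the spectrum so the half-power width is resolved well
    below the raw 1/N grid). Envelope width is the contiguous region of
    the squared analytic envelope within 3 dB of its peak.
    """
    h = np.asarray(filter_coeffs, dtype=float)
    if h.ndim != 1:
        raise ValueError("filter must be 1-D")
    if np.all(h == 0):
        raise ValueError("cannot characterize an all-zero filter")
    if zero_pad < h.size:
        raise ValueError("zero_pad must be >= filter length")

    freqs, psd = _power_spectrum(h, zero_pad)
    peak = int(np.argmax(psd))
    lo, hi = _half_power_region(psd, peak)
    center = float(freqs[peak])
    bandwidth = float(freqs[hi] - freqs[lo])
    if bandwidth == 0:  # pathological single-bin peak at max padding
        bandwidth = float(freqs[1] - freqs[0])
    q = center / bandwidth
    zeta = 1.0 / (2.0 * q) if q != 0 else np.inf

    env2 = analytic_envelope(h) ** 2
    env_peak = int(np.argmax(env2))
    thr = env2[env_peak] * HALF_POWER
    e_lo = env_peak
    while e_lo > 0 and env2[e_lo - 1] >= thr:
        e_lo -= 1
    e_hi = env_peak
    while e_hi < env2.size - 1 and env2[e_hi + 1] >= thr:
        e_hi += 1
    envelope_width = float(e_hi - e_lo + 1)

    return FilterProperties(
        center_freq=center,
        bandwidth_3db=bandwidth,
        q_factor=q,
        damping_ratio=zeta,
        envelope_width=envelope_width,
        localized=is_localized(h, concentration_threshold, zero_pad),
    )


def characterize_bank(
    bank: FilterBank,
    zero_pad: int = DEFAULT_ZERO_PAD,
    concentration_threshold: float = 0.8,
) -> pd.DataFrame:
    """Characterize every filter; one row per filter.

    Columns: ``index, center_freq, bandwidth_3db, q_factor,
    damping_ratio, envelope_width, localized``.
    """
    rows = []
    for i in range(bank.n_filters):
        p = characterize(bank.filters[i], zero_pad, concentration_threshold)
        rows.append(
            {
                "index": i,
                "center_freq": p.center_freq,
                "bandwidth_3db": p.bandwidth_3db,
                "q_factor": p.q_factor,
                "damping_ratio": p.damping_ratio,
                "envelope_width": p.envelope_width,
                "localized": p.localized,
            }
        )
    return pd.DataFrame(rows)


def tf_tile(
    filter_coeffs: np.ndarray,
    energy_frac: float = 0.95,
    zero_pad: int = 512,
) -> TFTile:
    """Time-frequency tile: spectrogram extent above ``energy_frac`` of peak.

    A short-time spectrogram of the analytic signal (window length N/8,
    75% overlap, zero-padded) is thresholded at ``energy_frac`` times its
    maximum; the tile is the bounding box (in samples and cycles/beat) of
    the cells above threshold. Only defined for spectrally localized
    filters; others raise with advice to exclude them.
    """
    h = np.asarray(filter_coeffs, dtype=float)
    if not is_localized(h):
        raise ValueError(
            "filter is not spectrally localized; exclude it from the "
            "time-frequency tiling analysis"
        )
    if not 0 < energy_frac <= 1:
        raise ValueError("energy_frac must lie in (0, 1]")

    analytic = hilbert(h)
    nperseg = max(8, h.size // 8)
    freqs, times, S = spectrogram(
        analytic,
        fs=1.0,
        window="hann",
        nperseg=nperseg,
        noverlap=(3 * nperseg) // 4,
        nfft=max(zero_pad, nperseg),
        mode="magnitude",
        return_onesided=False,
    )
    # analytic signal: keep the positive-frequency half-plane
    pos = (freqs >= 0) & (freqs <= 0.5)
    freqs, S = freqs[pos], S[pos] ** 2

    mask = S >= energy_frac * S.max()
    f_idx, t_idx = np.nonzero(mask)
    return TFTile(
        time_lo=float(times[t_idx.min()]),
        time_hi=float(times[t_idx.max()]),
        freq_lo=float(freqs[f_idx.min()]),
        freq_hi=float(freqs[f_idx.max()]),
        energy_frac=energy_frac,
    )
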