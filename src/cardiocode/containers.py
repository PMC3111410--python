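"""Shared data containers for the heartbeat-interval coding pipeline.

The pipeline passes a small set of typed containers between stages:

* :class:`RRSeries` — an ordered sequence of heartbeat (RR) intervals.
* :class:`SegmentEnsemble` — the matrix of fixed-length, zero-mean
  interval windows that feeds whitening and ICA.
* :class:`FilterBank` — a population of FIR decoding filters (learned,
  PCA-derived, or synthetic ground truth), one filter per row.
* :class:`Stimulus` / :class:`HeartRateSignal` — uniformly sampled
  stimulus and heart-rate traces used by the decoding stage.

All containers are plain dataclasses over NumPy arrays and round-trip
through simple whitespace-delimited text files, so every artifact of a
run can be inspected and versioned as text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "RRSeries",
    "SegmentEnsemble",
    "FilterBank",
    "Stimulus",
    "HeartRateSignal",
]


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class RRSeries:
    """Ordered heartbeat intervals in seconds, with optional beat times.

    Parameters
    ----------
    intervals
        RR intervals in seconds; all strictly positive.
    times
        Optional beat times in seconds, strictly increasing and consistent
        with the cumulative sum of ``intervals`` (within tolerance).
    label
        Free-form provenance tag (e.g. a subject or generator name).
    """

    intervals: np.ndarray
    times: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.intervals = _as_float_array(self.intervals, "intervals", 1)
        if np.any(self.intervals <= 0):
            bad = int(np.argmax(self.intervals <= 0))
            raise ValueError(
                f"RR intervals must be strictly positive; first offending "
                f"index {bad} has value {self.intervals[bad]!r}"
            )
        if self.times is not None:
            self.times = _as_float_array(self.times, "times", 1)
            if self.times.shape != self.intervals.shape:
                raise ValueError("times and intervals must have equal length")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("beat times must be strictly increasing")
            implied = self.times[0] + np.cumsum(self.intervals) - self.intervals[0]
            # times[k] should track times[0] + sum of intervals (1..k)
            drift = np.max(np.abs((self.times - self.times[0]) - (implied - implied[0])))
            if drift > 0.5 * float(np.median(self.intervals)):
                raise ValueError(
                    "beat times inconsistent with cumulative intervals "
                    f"(max drift {drift:.3g} s)"
                )

    def __len__(self) -> int:
        return self.intervals.size

    def beat_times(self) -> np.ndarray:
        """Beat times in seconds; cumulative intervals if not supplied."""
        if self.times is not None:
            return self.times
        return np.cumsum(self.intervals)

    def mean_rr(self) -> float:
        return float(np.mean(self.intervals))

    # -- text I/O ---------------------------------------------------------

    def to_text(self, path, format: str = "intervals") -> None:
        """Write as plain text: one interval per line, or ``time_s interval_s``."""
        path = Path(path)
        if format == "intervals":
            data = self.intervals[:, None]
            header = "interval_s"
        elif format == "time_interval":
            data = np.column_stack([self.beat_times(), self.intervals])
            header = "time_s interval_s"
        else:
            raise ValueError(f"unknown RR text format: {format!r}")
        np.savetxt(path, data, fmt="%.9g", header=header)

    @classmethod
    def from_text(cls, path, format: str = "intervals") -> "RRSeries":
        from .preprocess import read_rr  # single authoritative reader

        return read_rr(path, format=format)


@dataclass
class SegmentEnsemble:
    """Matrix of zero-mean, fixed-length interval windows.

    ``data`` has shape ``(window_len, n_windows)`` — one window per column,
    matching the observation matrix consumed by whitening/ICA. ``offsets``
    stores each window's removed mean so segmentation is lossless.
    """

    data: np.ndarray
    offsets: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.data = _as_float_array(self.data, "data", 2)
        if self.offsets is not None:
            self.offsets = _as_float_array(self.offsets, "offsets", 1)
            if self.offsets.size != self.data.shape[1]:
                raise ValueError("offsets must have one entry per window")

    @property
    def window_len(self) -> int:
        return self.data.shape[0]

    @property
    def n_windows(self) -> int:
        return self.data.shape[1]

    def to_text(self, path) -> None:
        np.savetxt(
            Path(path),
            self.data.T,
            fmt="%.9g",
            header=f"segment ensemble: {self.n_windows} windows x {self.window_len} samples"
            " (one window per line)",
        )

    @classmethod
    def from_text(cls, path) -> "SegmentEnsemble":
        raw = np.loadtxt(Path(path), ndmin=2)
        return cls(data=raw.T)


@dataclass
class FilterBank:
    """A population of FIR filters, one filter per row of ``filters``.

    Attributes
    ----------
    filters
        Coefficient matrix of shape ``(n_filters, length)``.
    provenance
        Where the bank came from: ``"ica"``, ``"pca"``, ``"gabor"``,
        ``"subband"`` or similar.
    normalized
        True if every row has unit Euclidean norm.
    sample_unit
        Label for the sample axis (``"beats"`` for beat-indexed filters).
    eigenvalues
        Optional per-filter variances (attached by PCA).
    """

    filters: np.ndarray
    provenance: str = "unknown"
    normalized: bool = False
    sample_unit: str = "beats"
    eigenvalues: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.filters = _as_float_array(self.filters, "filters", 2)
        if self.normalized:
            norms = np.linalg.norm(self.filters, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-8):
                raise ValueError("bank flagged normalized but row norms are not 1")

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]

    @property
    def length(self) -> int:
        return self.filters.shape[1]

    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.filters, axis=1)

    def normalize(self) -> "FilterBank":
        """Return a copy with unit-norm rows (zero rows rejected)."""
        norms = self.norms()
        if np.any(norms == 0):
            raise ValueError("cannot normalize a bank containing an all-zero filter")
        return FilterBank(
            filters=self.filters / norms[:, None],
            provenance=self.provenance,
            normalized=True,
            sample_unit=self.sample_unit,
            eigenvalues=self.eigenvalues,
        )

    def __getitem__(self, i: int) -> np.ndarray:
        return self.filters[i]

    # -- text I/O ---------------------------------------------------------

    def to_text(self, path) -> None:
        header = (
            f"filter bank: M={self.n_filters} N={self.length} "
            f"provenance={self.provenance} normalized={self.normalized} "
            f"sample_unit={self.sample_unit}\n(one filter per line)"
        )
        np.savetxt(Path(path), self.filters, fmt="%.12g", header=header)

    @classmethod
    def from_text(cls, path) -> "FilterBank":
        path = Path(path)
        provenance, normalized, sample_unit = "unknown", False, "beats"
        with open(path) as fh:
            first = fh.readline()
        for tok in first.lstrip("# ").split():
            if tok.startswith("provenance="):
                provenance = tok.split("=", 1)[1]
            elif tok.startswith("normalized="):
                normalized = tok.split("=", 1)[1] == "True"
            elif tok.startswith("sample_unit="):
                sample_unit = tok.split("=", 1)[1]
        filters = np.loadtxt(path, ndmin=2)
        return cls(
            filters=filters,
            provenance=provenance,
            normalized=normalized,
            sample_unit=sample_unit,
        )


@dataclass
class Stimulus:
    """Uniformly sampled stimulus trace (arbitrary voltage units)."""

    values: np.ndarray
    rate_hz: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "values", 1)
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate_hz

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate_hz

    def resample(self, rate_hz: float) -> "Stimulus":
        """Band-limited (polyphase) resampling to a new uniform rate."""
        from fractions import Fraction

        from scipy.signal import resample_poly

        frac = Fraction(rate_hz / self.rate_hz).limit_denominator(10_000)
        out = resample_poly(self.values, frac.numerator, frac.denominator)
        n_out = int(round(self.duration_s * rate_hz))
        out = out[:n_out]
        return Stimulus(values=out, rate_hz=rate_hz, label=self.label)

    def to_text(self, path) -> None:
        np.savetxt(
            Path(path),
            np.column_stack([self.times, self.values]),
            fmt="%.9g",
            header=f"stimulus at {self.rate_hz} Hz: time_s value",
        )

    @classmethod
    def from_text(cls, path, rate_hz: Optional[float] = None) -> "Stimulus":
        raw = np.loadtxt(Path(path), ndmin=2)
        t, v = raw[:, 0], raw[:, 1]
        if rate_hz is None:
            dt = np.diff(t)
            if dt.size == 0 or np.ptp(dt) > 1e-6 * np.mean(dt):
                raise ValueError("cannot infer a uniform sampling rate from times")
            rate_hz = 1.0 / float(np.mean(dt))
        return cls(values=v, rate_hz=float(rate_hz))


@dataclass
class HeartRateSignal:
    """Uniformly sampled instantaneous heart rate in beats/min."""

    values: np.ndarray
    rate_hz: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "values", 1)
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if np.any(self.values <= 0):
            raise ValueError("heart rate must be strictly positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate_hz

    def to_text(self, path) -> None:
        np.savetxt(
            Path(path),
            np.column_stack([self.times, self.values]),
            fmt="%.9g",
            header=f"heart rate at {self.rate_hz} Hz: time_s bpm",
        )

    @classmethod
    def from_text(cls, path, rate_hz: Optional[float] = None) -> "HeartRateSignal":
        raw = np.loadtxt(Path(path), ndmin=2)
        t, v = raw[:, 0], raw[:, 1]
        if rate_hz is None:
            dt = np.diff(t)
            if dt.size == 0 or np.ptp(dt) > 1e-6 * np.mean(dt):
                raise ValueError("cannot infer a uniform sampling rate from times")
            rate_hz = 1.0 / float(np.mean(dt))
        return cls(values=v, rate_hz=float(rate_hz))
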