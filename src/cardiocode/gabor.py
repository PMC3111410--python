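"""Gabor-atom matching for decoding filters.

A Gabor function — a Gaussian envelope modulated by a sinusoid,

    g(t) = a * exp(-(t - u)^2 / (2 s^2)) * cos(2 pi f (t - u) + phi)

— is the minimal time-frequency uncertainty atom, and the filter shapes
that emerge from the learning stage resemble it closely. Each filter is
summarized by its best-fitting atom: a coarse dictionary search over
(center u, spread s, frequency f) with the phase solved analytically per
cell, refined by bounded nonlinear least squares. The reported
correlation index is the absolute normalized inner product between the
filter and the atom, invariant to the filter's sign and scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .containers import FilterBank

__all__ = ["GaborParameters", "GaborFit", "gabor_atom", "fit_gabor", "fit_bank"]


@dataclass
class GaborParameters:
    """Parameters of one Gabor atom (times in beats, frequency cycles/beat)."""

    amplitude: float
    time_center: float
    time_spread: float
    frequency: float
    phase: float

    def __post_init__(self) -> None:
        if self.time_spread <= 0:
            raise ValueError("time_spread must be positive")
        if not 0 <= self.frequency <= 0.5:
            raise ValueError("frequency must lie in [0, 0.5]")
        # canonical phase in (-pi, pi]
        self.phase = math.remainder(self.phase, 2 * math.pi)
        if self.phase <= -math.pi:
            self.phase += 2 * math.pi


@dataclass
class GaborFit:
    """Best-fitting atom with its correlation index and residual."""

    params: GaborParameters
    correlation: float
    residual_norm: float
    refined: bool = True

    def __post_init__(self) -> None:
        if not -1 <= self.correlation <= 1 + 1e-12:
            raise ValueError("correlation index must lie in [-1, 1]")


def gabor_atom(params: GaborParameters, length: int) -> np.ndarray:
    """Sample a Gabor atom at integer times ``0 .. length-1``."""
    if length < 4:
        raise ValueError("length must be >= 4")
    t = np.arange(length, dtype=float)
    dt = t - params.time_center
    return (
        params.amplitude
        * np.exp(-(dt**2) / (2.0 * params.time_spread**2))
        * np.cos(2.0 * math.pi * params.frequency * dt + params.phase)
    )


def _dictionary_search(x: np.ndarray) -> GaborParameters:
    """Best (u, s, f) over a coarse grid; phase/amplitude solved per cell.

    For each envelope/frequency cell the atom space is the 2-D span of
    the cosine and sine quadrature atoms; the projection of ``x`` onto
    that span (via the 2x2 Gram system) yields the optimal phase and
    amplitude in closed form.
    """
    n = x.size
    u_grid = np.arange(0, n, 4, dtype=float)
    s_grid = np.geomspace(2.0, max(4.0, float(n)), 12)
    f_grid = np.arange(0.0, 0.5 + 1e-9, 0.005)
    t = np.arange(n, dtype=float)
    x_norm = np.linalg.norm(x)

    best_corr = -1.0
    best_params = None
    for u in u_grid:
        dt = t - u
        arg = 2.0 * math.pi * f_grid[:, None] * dt[None, :]  # (F, n)
        cos_arg, sin_arg = np.cos(arg), np.sin(arg)
        for s in s_grid:
            env = np.exp(-(dt**2) / (2.0 * s * s))
            c = env[None, :] * cos_arg
            sn = env[None, :] * sin_arg
            g11 = np.einsum("ij,ij->i", c, c)
            g22 = np.einsum("ij,ij->i", sn, sn)
            g12 = np.einsum("ij,ij->i", c, sn)
            b1, b2 = c @ x, sn @ x
            det = g11 * g22 - g12 * g12
            ok = det > 1e-12 * np.maximum(g11 * g22, 1e-300)
            alpha = np.where(ok, (b1 * g22 - b2 * g12) / np.where(ok, det, 1.0), 0.0)
            beta = np.where(ok, (b2 * g11 - b1 * g12) / np.where(ok, det, 1.0), 0.0)
            # fall back to the cosine-only projection where the pair is degenerate
            alpha = np.where(~ok & (g11 > 0), b1 / np.where(g11 > 0, g11, 1.0), alpha)
            proj = alpha * b1 + beta * b2  # = <x, atom>, also the atom energy term
            energy = (
                alpha**2 * g11 + beta**2 * g22 + 2 * alpha * beta * g12
            )
            valid = energy > 0
            corr = np.zeros(f_grid.size)
            corr[valid] = np.abs(proj[valid]) / (x_norm * np.sqrt(energy[valid]))
            k = int(np.argmax(corr))
            if corr[k] > best_corr:
                best_corr = float(corr[k])
                amp = math.hypot(alpha[k], beta[k])
                phase = math.atan2(-beta[k], alpha[k])
                best_params = GaborParameters(amp, u, s, float(f_grid[k]), phase)
    if best_params is None:  # pragma: no cover - requires pathological input
        raise RuntimeError("dictionary search failed to produce a candidate")
    return best_params


def _correlation(x: np.ndarray, atom: np.ndarray) -> float:
    na, nx = np.linalg.norm(atom), np.linalg.norm(x)
    if na == 0 or nx == 0:
        return 0.0
    return float((x @ atom) / (nx * na))


def fit_gabor(filter_coeffs: np.ndarray) -> GaborFit:
    """Fit the best single Gabor atom to a filter.

    Dictionary search (u step 4 beats, log-spaced spreads in [2, N],
    frequency step 0.005 cycles/beat, analytic phase) followed by
    bounded local least squares on all five parameters. If the
    refinement fails to improve the fit, the dictionary-stage atom is
    returned flagged ``refined=False``.
    """
    x = np.asarray(filter_coeffs, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("filter must be 1-D with length >= 4")
    if np.all(x == 0):
        raise ValueError("cannot fit an all-zero filter")
    n = x.size

    coarse = _dictionary_search(x)

    def unpack(theta) -> GaborParameters:
        a, u, s, f, phi = theta
        return GaborParameters(a, u, min(max(s, 1e-6), 10.0 * n), min(max(f, 0.0), 0.5), phi)

    def resid(theta):
        return gabor_atom(unpack(theta), n) - x

    theta0 = [
        coarse.amplitude,
        coarse.time_center,
        coarse.time_spread,
        coarse.frequency,
        coarse.phase,
    ]
    lower = [-np.inf, -n, 0.5, 0.0, -2 * math.pi]
    upper = [np.inf, 2 * n, 10.0 * n, 0.5, 2 * math.pi]
    refined = True
    try:
        sol = least_squares(resid, theta0, bounds=(lower, upper), max_nfev=500)
        params = unpack(sol.x)
    except Exception:
        params, refined = coarse, False

    atom = gabor_atom(params, n)
    corr = _correlation(x, atom)
    coarse_atom = gabor_atom(coarse, n)
    coarse_corr = _correlation(x, coarse_atom)
    if abs(corr) < abs(coarse_corr):
        params, atom, corr, refined = coarse, coarse_atom, coarse_corr, False

    # fold a negative correlation into the phase so the atom aligns with x
    if corr < 0:
        params = GaborParameters(
            params.amplitude,
            params.time_center,
            params.time_spread,
            params.frequency,
            params.phase + math.pi,
        )
        atom = -atom
        corr = -corr

    residual = float(np.linalg.norm(x - atom))
    return GaborFit(params=params, correlation=corr, residual_norm=residual, refined=refined)


def fit_bank(bank: FilterBank) -> pd.DataFrame:
    """Fit every filter in a bank; one row per filter."""
    rows = []
    for i in range(bank.n_filters):
        fit = fit_gabor(bank.filters[i])
        p = fit.params
        rows.append(
            {
                "index": i,
                "amplitude": p.amplitude,
                "time_center": p.time_center,
                "time_spread": p.time_spread,
                "frequency": p.frequency,
                "phase": p.phase,
                "correlation": fit.correlation,
                "refined": fit.refined,
            }
        )
    return pd.DataFrame(rows)
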