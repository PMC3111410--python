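"""Fixed-point ICA and derivation of the decoding filter bank.

The filter population is learned by maximizing non-Gaussianity
(a negentropy approximation) over whitened interval windows with the
fixed-point ("FastICA") iteration run in parallel for all units:

    w+  =  E{ z g(w'z) }  -  E{ g'(w'z) } w

followed by symmetric orthogonalization  W <- (W W')^(-1/2) W,  so no
unit is privileged. ``g`` is the derivative of the nonquadratic contrast
(``tanh`` for the log-cosh contrast, ``u^3`` for kurtosis).

The decoding filters are the columns of the mixing matrix in window
space, obtained by composing the dewhitening transform with the inverse
(= transpose) of the orthogonal unmixing matrix. PCA filters are exposed
as the second-order contrast, and :func:`match_filters` aligns a learned
bank with a ground-truth bank up to the sign/scale/permutation (and small
time-shift) ambiguities inherent to the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import linear_sum_assignment

from .containers import FilterBank, SegmentEnsemble
from .preprocess import Whitener, whiten

__all__ = [
    "UnmixingMatrix",
    "MatchResult",
    "IcaConvergenceError",
    "fastica",
    "symmetric_orthogonalize",
    "decoding_filters",
    "pca_filters",
    "match_filters",
]


class IcaConvergenceError(RuntimeError):
    """Fixed-point iteration failed to converge; carries per-iteration deltas."""

    def __init__(self, message: str, deltas: List[float]):
        super().__init__(message)
        self.deltas = deltas


@dataclass
class UnmixingMatrix:
    """Converged orthogonal unmixing matrix in whitened space."""

    W: np.ndarray
    nonlinearity: str
    n_iter: int
    deltas: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        gram = self.W @ self.W.T
        if np.max(np.abs(gram - np.eye(gram.shape[0]))) > 1e-8:
            raise ValueError("unmixing rows are not orthonormal")


@dataclass
class MatchResult:
    """Alignment of an estimated bank to a ground-truth bank.

    ``permutation[j]`` is the estimated-filter index assigned to truth
    filter ``j``; ``correlations[j]`` the absolute correlation at the best
    lag, ``signs[j]`` the sign and ``lags[j]`` the lag achieving it.
    """

    permutation: np.ndarray
    signs: np.ndarray
    lags: np.ndarray
    correlations: np.ndarray

    def __post_init__(self) -> None:
        uniq = np.unique(self.permutation)
        if uniq.size != self.permutation.size:
            raise ValueError("permutation assigns one estimated filter twice")
        if np.any(self.correlations < -1e-12) or np.any(self.correlations > 1 + 1e-9):
            raise ValueError("correlations must lie in [0, 1]")

    @property
    def median_correlation(self) -> float:
        return float(np.median(self.correlations))

    def fraction_above(self, threshold: float) -> float:
        return float(np.mean(self.correlations > threshold))


def symmetric_orthogonalize(W: np.ndarray) -> np.ndarray:
    """Return ``(W W')^(-1/2) W``: orthonormal rows spanning the same row space."""
    W = np.asarray(W, dtype=float)
    gram = W @ W.T
    evals, evecs = eigh(gram)
    if evals[0] <= 1e-12 * evals[-1]:
        raise ValueError("matrix is rank deficient; cannot orthogonalize symmetrically")
    inv_sqrt = (evecs / np.sqrt(evals)) @ evecs.T
    return inv_sqrt @ W


def _contrast(name: str):
    if name == "logcosh":

        def g(u):
            return np.tanh(u)

        def gprime(u):
            return 1.0 - np.tanh(u) ** 2

    elif name == "cube":

        def g(u):
            return u**3

        def gprime(u):
            return 3.0 * u**2

    else:
        raise ValueError(f"unknown nonlinearity {name!r}; use 'logcosh' or 'cube'")
    return g, gprime


def fastica(
    whitened: np.ndarray,
    n_components: Optional[int] = None,
    nonlinearity: str = "logcosh",
    tol: float = 1e-4,
    max_iter: int = 1000,
    seed: int = 0,
) -> UnmixingMatrix:
    """Parallel fixed-point ICA with symmetric orthogonalization.

    Parameters
    ----------
    whitened
        Data matrix ``(d, P)`` with (near-)identity sample covariance;
        a covariance deviation above 1e-3 raises ``ValueError``.
    n_components
        Number of units (default ``d``). Must not exceed ``d``.
    nonlinearity
        ``"logcosh"`` (g = tanh, robust default) or ``"cube"`` (kurtosis).
    tol
        Convergence threshold on ``max_i (1 - |<w_i, w_i_old>|)``.
    max_iter
        Iteration budget; exceeded -> :class:`IcaConvergenceError` with
        the per-iteration deltas attached (Gaussian data lands here, as
        the model is then unidentifiable).
    seed
        Seeds the random orthonormal initialization; runs are
        deterministic given the seed.
    """
    Z = np.asarray(whitened, dtype=float)
    if Z.ndim != 2:
        raise ValueError("whitened data must be 2-D (components x samples)")
    d, P = Z.shape
    if n_components is None:
        n_components = d
    if n_components > d:
        raise ValueError(f"n_components={n_components} exceeds data dimension {d}")

    cov = (Z @ Z.T) / (P - 1)
    dev = np.max(np.abs(cov - np.eye(d)))
    if dev > 1e-3:
        raise ValueError(
            f"input is not whitened (covariance deviates from identity by {dev:.2e}); "
            "run preprocess.whiten first"
        )

    g, gprime = _contrast(nonlinearity)
    rng = np.random.default_rng(seed)
    W = symmetric_orthogonalize(rng.standard_normal((n_components, d)))

    deltas: List[float] = []
    for iteration in range(1, max_iter + 1):
        WZ = W @ Z
        gw = g(WZ)
        W_new = (gw @ Z.T) / P - (gprime(WZ).mean(axis=1))[:, None] * W
        W_new = symmetric_orthogonalize(W_new)
        delta = float(np.max(1.0 - np.abs(np.sum(W_new * W, axis=1))))
        deltas.append(delta)
        W = W_new
        if delta < tol:
            return UnmixingMatrix(W=W, nonlinearity=nonlinearity, n_iter=iteration, deltas=deltas)

    raise IcaConvergenceError(
        f"fixed-point ICA did not converge in {max_iter} iterations "
        f"(last delta {deltas[-1]:.3e}, tol {tol:.1e})",
        deltas,
    )


def decoding_filters(
    unmixing: UnmixingMatrix,
    whitener: Whitener,
    normalize: bool = True,
) -> FilterBank:
    """Decoding filters: columns of the mixing matrix in window space.

    With orthogonal ``W`` in whitened space, the mixing matrix in the
    original window space is ``A = dewhitening @ W.T``; its columns are
    the impulse responses the generative model attributes to the filter
    bank. Rows of the returned bank are those columns.
    """
    W = unmixing.W
    if W.shape[1] != whitener.n_components:
        raise ValueError(
            f"unmixing dimension {W.shape[1]} != whitener components {whitener.n_components}"
        )
    A = whitener.dewhitening @ W.T  # (N, M)
    bank = FilterBank(filters=A.T.copy(), provenance="ica", normalized=False)
    if normalize:
        bank = bank.normalize()
    return bank


def pca_filters(ensemble: SegmentEnsemble, n: int) -> FilterBank:
    """Top-``n`` covariance eigenvectors as a (second-order) filter bank."""
    _, whitener = whiten(ensemble, n_components=n)
    evecs = whitener.dewhitening / np.sqrt(whitener.eigenvalues)[None, :]
    bank = FilterBank(
        filters=evecs.T.copy(),
        provenance="pca",
        normalized=True,
        eigenvalues=whitener.eigenvalues.copy(),
    )
    return bank


def _best_lag_correlation(a: np.ndarray, b: np.ndarray, max_lag: int) -> Tuple[float, int, int]:
    """Max |correlation| between unit-normalized a and b over lags in [-L, L]."""
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0, 1, 0
    xc = np.correlate(a, b, mode="full") / denom
    center = b.size - 1
    lo = max(center - max_lag, 0)
    hi = min(center + max_lag + 1, xc.size)
    window = xc[lo:hi]
    k = int(np.argmax(np.abs(window)))
    val = window[k]
    return float(abs(val)), int(np.sign(val)) or 1, int(lo + k - center)


def match_filters(
    estimated: FilterBank,
    truth: FilterBank,
    max_lag: int = 5,
) -> MatchResult:
    """Optimal assignment of estimated filters to ground-truth filters.

    The score between a pair is the maximum absolute normalized
    cross-correlation over time shifts up to ``max_lag`` samples (sign
    flips allowed), reflecting the scale/sign/permutation blindness of
    the learning stage and the small alignment ambiguity of convolutive
    excitation. Assignment maximizes the summed score (Hungarian
    algorithm); requires at least as many estimated as truth filters.
    """
    if estimated.length != truth.length:
        raise ValueError("banks must share filter length")
    if estimated.n_filters < truth.n_filters:
        raise ValueError("need at least as many estimated filters as truth filters")

    n_est, n_true = estimated.n_filters, truth.n_filters
    corr = np.zeros((n_true, n_est))
    sign = np.ones((n_true, n_est), dtype=int)
    lag = np.zeros((n_true, n_est), dtype=int)
    for j in range(n_true):
        for i in range(n_est):
            c, s, l = _best_lag_correlation(estimated.filters[i], truth.filters[j], max_lag)
            corr[j, i], sign[j, i], lag[j, i] = c, s, l

    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(n_true, dtype=int)
    perm[rows] = cols
    return MatchResult(
        permutation=perm,
        signs=sign[np.arange(n_true), perm],
        lags=lag[np.arange(n_true), perm],
        correlations=corr[np.arange(n_true), perm],
    )
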