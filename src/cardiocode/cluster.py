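"""Gaussian mean-shift clustering of filters in the (f_c, bandwidth) plane.

The filter population is divided into frequency bands without fixing the
number of clusters: each point is iterated uphill on a Gaussian kernel
density estimate (KDE) until it reaches a mode, and points sharing a
mode share a label. The kernel bandwidth is estimated from the data by a
K-nearest-neighbor rule. Mean shift with a Gaussian kernel is an ascent
scheme — the KDE value is non-decreasing along every trajectory — which
the implementation tracks and exposes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd

__all__ = ["ClusterResult", "knn_bandwidth", "mean_shift", "cluster_table"]

#: Lower floor for a degenerate (duplicate-dominated) KNN bandwidth.
MIN_BANDWIDTH = 1e-12


@dataclass
class ClusterResult:
    """Modes, labels and diagnostics of a Gaussian mean-shift run."""

    modes: np.ndarray        # (n_modes, 2) mode coordinates
    labels: np.ndarray       # (n_points,) mode index per point
    bandwidth: float         # kernel bandwidth used
    iterations: np.ndarray   # (n_points,) iterations until convergence
    kde_paths: List[np.ndarray] = field(default_factory=list)  # KDE value per step

    def __post_init__(self) -> None:
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= len(self.modes):
            raise ValueError("labels must index into modes")

    @property
    def n_clusters(self) -> int:
        return self.modes.shape[0]


def knn_bandwidth(points: np.ndarray, k: int | None = None) -> float:
    """Kernel bandwidth: mean distance to the k-th nearest neighbor.

    ``k`` defaults to ``round(sqrt(n))``, a standard heuristic. If
    duplicates make the estimate collapse, a small floor is returned
    with a warning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be (n, d)")
    n = pts.shape[0]
    if k is None:
        k = max(1, int(round(np.sqrt(n))))
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points {n}")
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    d = np.sqrt(d2)
    d.sort(axis=1)
    kth = d[:, k]  # column 0 is the zero self-distance
    bw = float(np.mean(kth))
    if bw < MIN_BANDWIDTH:
        warnings.warn(
            "KNN bandwidth collapsed (duplicate-dominated points); using floor",
            RuntimeWarning,
        )
        return MIN_BANDWIDTH
    return bw


def _kde(x: np.ndarray, pts: np.ndarray, h: float) -> float:
    d2 = np.sum((pts - x) ** 2, axis=1)
    return float(np.mean(np.exp(-d2 / (2.0 * h * h))))


def mean_shift(
    points: np.ndarray,
    bandwidth: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    merge_factor: float = 0.5,
) -> ClusterResult:
    """Gaussian mean-shift mode seeking.

    Each point ``x`` is iterated to the Gaussian-kernel weighted mean of
    all points, ``x <- sum_j x_j w_j / sum_j w_j`` with
    ``w_j = exp(-||x - x_j||^2 / 2h^2)``, until the shift falls below
    ``tol * h``. Converged locations within ``merge_factor * h`` of each
    other are merged into one mode; labels follow mode membership (ties
    broken by nearest mode).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be (n, d)")
    if bandwidth is None:
        bandwidth = knn_bandwidth(pts)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    h = float(bandwidth)
    n = pts.shape[0]

    converged = np.empty_like(pts)
    iterations = np.zeros(n, dtype=int)
    kde_paths: List[np.ndarray] = []
    worst_residual = 0.0
    failed = []

    for idx in range(n):
        x = pts[idx].copy()
        path = [_kde(x, pts, h)]
        for it in range(1, max_iter + 1):
            w = np.exp(-np.sum((pts - x) ** 2, axis=1) / (2.0 * h * h))
            total = w.sum()
            if total == 0:  # isolated point beyond kernel reach: already a mode
                break
            x_new = (w[:, None] * pts).sum(axis=0) / total
            shift = float(np.linalg.norm(x_new - x))
            x = x_new
            path.append(_kde(x, pts, h))
            if shift < tol * h:
                break
        else:
            worst_residual = max(worst_residual, shift)
            failed.append(idx)
        converged[idx] = x
        iterations[idx] = it
        kde_paths.append(np.asarray(path))

    if failed:
        raise RuntimeError(
            f"mean shift did not converge for {len(failed)} points within "
            f"{max_iter} iterations (worst residual {worst_residual:.3e})"
        )

    # merge converged locations into modes
    modes: List[np.ndarray] = []
    labels = np.empty(n, dtype=int)
    merge_tol = merge_factor * h
    for idx in range(n):
        x = converged[idx]
        for m, mode in enumerate(modes):
            if np.linalg.norm(x - mode) <= merge_tol:
                labels[idx] = m
                break
        else:
            modes.append(x.copy())
            labels[idx] = len(modes) - 1
    mode_arr = np.asarray(modes)

    # refine: assign each point to its nearest mode (tie-break by distance)
    d = np.linalg.norm(converged[:, None, :] - mode_arr[None, :, :], axis=-1)
    labels = np.argmin(d, axis=1)

    return ClusterResult(
        modes=mode_arr,
        labels=labels,
        bandwidth=h,
        iterations=iterations,
        kde_paths=kde_paths,
    )


def cluster_table(points: np.ndarray, result: ClusterResult) -> pd.DataFrame:
    """Tabular export: point coordinates, label, and assigned mode."""
    pts = np.asarray(points, dtype=float)
    return pd.DataFrame(
        {
            "index": np.arange(pts.shape[0]),
            "center_freq": pts[:, 0],
            "bandwidth_3db": pts[:, 1],
            "label": result.labels,
            "mode_center_freq": result.modes[result.labels, 0],
            "mode_bandwidth": result.modes[result.labels, 1],
        }
    )
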