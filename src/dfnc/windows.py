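"""Tapered sliding-window correlation among component time courses.

Each window applies a taper (a rectangle convolved with a Gaussian) as
observation weights and computes the full weighted Pearson correlation
matrix, vectorized to its upper triangle. With 197 retained volumes, a
20-sample window, and step 1, a run yields 178 windowed matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from dfnc.errors import ConformabilityError, InvalidConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "Taper",
    "WindowedFNC",
    "make_taper",
    "sliding_window_fnc",
    "vectorize",
    "unvectorize",
    "edge_labels",
    "window_majority_labels",
]


@dataclass(frozen=True)
class Taper:
    """Nonnegative window weights summing to 1, symmetric about the center."""

    window_length: int
    sigma: float
    weights: np.ndarray


def make_taper(window_length: int = 20, sigma: float = 3.0) -> Taper:
    """Convolve a length-``window_length`` rectangle with a discrete Gaussian
    (support +-3 sigma), keep the central ``window_length`` samples, and
    normalize to sum 1."""
    if window_length < 3:
        raise InvalidConfigError(f"window_length must be >= 3, got {window_length}")
    if sigma <= 0:
        raise InvalidConfigError(f"sigma must be positive, got {sigma}")
    # support +-3 sigma, capped: the central window_length samples of the
    # convolution only see kernel mass within ~window_length of the center
    half = int(min(np.ceil(3 * sigma), 10 * window_length))
    t = np.arange(-half, half + 1)
    gauss = np.exp(-0.5 * (t / sigma) ** 2)
    full = np.convolve(np.ones(window_length), gauss, mode="full")
    center = (full.shape[0] - window_length) // 2
    weights = full[center : center + window_length]
    weights = weights / weights.sum()
    return Taper(window_length=window_length, sigma=float(sigma), weights=weights)


@dataclass
class WindowedFNC:
    """Windows x edges matrix of weighted Pearson correlations.

    Edges are the upper triangle (row-major, diagonal excluded) of the
    components x components correlation matrix.
    """

    values: np.ndarray  # (n_windows, n_edges)
    window_starts: np.ndarray
    n_components: int
    taper: Taper
    step: int
    tr: float | None = None
    subject: str | None = None
    task: str | None = None

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]


def vectorize(matrix: np.ndarray) -> np.ndarray:
    """Upper triangle (diagonal excluded, row-major) of a square matrix."""
    matrix = np.asarray(matrix)
    n = matrix.shape[-1]
    iu = np.triu_indices(n, k=1)
    return matrix[..., iu[0], iu[1]]


def unvectorize(edges: np.ndarray) -> np.ndarray:
    """Rebuild the symmetric unit-diagonal matrix from an edge vector."""
    edges = np.asarray(edges, dtype=float)
    m = edges.shape[-1]
    n = int((1 + np.sqrt(1 + 8 * m)) / 2)
    if n * (n - 1) // 2 != m:
        raise ConformabilityError(f"length {m} is not a triangular number")
    out = np.zeros(edges.shape[:-1] + (n, n))
    iu = np.triu_indices(n, k=1)
    out[..., iu[0], iu[1]] = edges
    out[..., iu[1], iu[0]] = edges
    out[..., np.arange(n), np.arange(n)] = 1.0
    return out


def edge_labels(n_components: int, names: list[str] | None = None) -> list[str]:
    """Labels ``comp_i-comp_j`` for the vectorized upper triangle."""
    if names is None:
        names = [f"comp_{i + 1}" for i in range(n_components)]
    iu = np.triu_indices(n_components, k=1)
    return [f"{names[i]}-{names[j]}" for i, j in zip(*iu)]


def sliding_window_fnc(
    data: np.ndarray,
    taper: Taper | None = None,
    step: int = 1,
    tr: float | None = None,
    subject: str | None = None,
    task: str | None = None,
    fisher_z: bool = False,
) -> WindowedFNC:
    """Weighted Pearson correlation in every sliding window.

    ``data`` is time x components. For each window start the taper weights
    define weighted means and covariances; the number of windows is
    ``floor((T - w) / step) + 1``. Edges with zero weighted variance are set
    to 0 with a logged warning. ``fisher_z`` optionally applies
    ``arctanh`` to the edge values.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise InvalidConfigError(f"need a time x components matrix, got {data.shape}")
    taper = taper or make_taper()
    T, C = data.shape
    w = taper.window_length
    if T < w:
        raise InvalidConfigError(f"series length {T} shorter than window {w}")
    if step < 1:
        raise InvalidConfigError(f"step must be >= 1, got {step}")

    # (n_windows, w, C) view, strided by step
    windows = sliding_window_view(data, w, axis=0)[::step]  # (n_win, C, w)
    p = taper.weights
    mean = windows @ p  # (n_win, C)
    centered = windows - mean[:, :, None]
    cov = np.einsum("niw,njw,w->nij", centered, centered, p)
    var = np.einsum("nii->ni", cov)
    # a numerically constant component has variance at rounding-error scale
    mean_sq = np.einsum("niw,w->ni", windows**2, p)
    zero_var = var <= 1e-12 * np.maximum(mean_sq, np.finfo(float).tiny)
    sd = np.sqrt(np.clip(var, 0.0, None))
    denom = sd[:, :, None] * sd[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / denom
    bad = ~np.isfinite(corr) | zero_var[:, :, None] | zero_var[:, None, :]
    bad &= ~np.eye(C, dtype=bool)
    if bad.any():
        logger.warning(
            "zero weighted variance in %d window/edge cells; correlations set to 0",
            int(bad.sum()),
        )
        corr[bad] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)

    values = vectorize(corr)
    if fisher_z:
        values = np.arctanh(np.clip(values, -1 + 1e-15, 1 - 1e-15))
    starts = np.arange(0, T - w + 1, step)
    return WindowedFNC(
        values=values,
        window_starts=starts,
        n_components=C,
        taper=taper,
        step=step,
        tr=tr,
        subject=subject,
        task=task,
    )


def window_majority_labels(
    labels: np.ndarray, taper: Taper, step: int = 1
) -> np.ndarray:
    """Taper-weighted majority regime label per window.

    Maps a per-sample ground-truth label sequence onto windows: each window
    is labeled with the state carrying the largest total taper weight, the
    same weighting the windowed correlation applies to its samples.
    """
    labels = np.asarray(labels, dtype=np.int64)
    w = taper.window_length
    if labels.shape[0] < w:
        raise InvalidConfigError(
            f"label sequence length {labels.shape[0]} shorter than window {w}"
        )
    k = int(labels.max()) + 1
    onehot = np.eye(k)[labels]  # (T, k)
    views = sliding_window_view(onehot, w, axis=0)[::step]  # (n_win, k, w)
    scores = views @ taper.weights  # (n_win, k)
    return scores.argmax(axis=1)
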