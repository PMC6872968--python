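"""Nuisance modeling, temporal filtering, and framewise displacement.

Component/ROI time series are cleaned before windowed connectivity: the
HRF-convolved paradigm, six motion parameters, and their derivatives are
regressed out by ordinary least squares, then each series is linearly
detrended and low-pass filtered (zero-phase Butterworth).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.stats import gamma as gamma_dist

from dfnc.errors import ConformabilityError, InvalidConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "HRFKernel",
    "NuisanceModel",
    "canonical_hrf",
    "build_nuisance",
    "regress_out",
    "detrend_lowpass",
    "framewise_displacement",
]


@dataclass(frozen=True)
class HRFKernel:
    """Sampled hemodynamic response kernel with unit peak."""

    dt: float
    values: np.ndarray
    duration: float


@dataclass
class NuisanceModel:
    """Design matrix of nuisance regressors (time x p) with column labels."""

    regressors: np.ndarray
    labels: list[str]

    @property
    def n_volumes(self) -> int:
        return self.regressors.shape[0]


def canonical_hrf(tr: float, duration: float = 32.0) -> HRFKernel:
    """Canonical double-gamma HRF sampled every ``tr`` seconds.

    Difference of two gamma densities (shape 6 and 16, scale 1 s) with a
    peak/undershoot ratio of 6, normalized to unit peak. The kernel is 0 at
    t = 0 and peaks near 5 s.
    """
    if tr <= 0:
        raise InvalidConfigError(f"TR must be positive, got {tr!r}")
    t = np.arange(0, duration + tr / 2, tr)
    peak = gamma_dist.pdf(t, a=6, scale=1.0)
    undershoot = gamma_dist.pdf(t, a=16, scale=1.0)
    values = peak - undershoot / 6.0
    values = values / values.max()
    return HRFKernel(dt=tr, values=values, duration=duration)


def build_nuisance(
    paradigm,
    motion: np.ndarray,
    tr: float,
    n_volumes: int,
    oversample: int = 16,
) -> NuisanceModel:
    """Assemble the nuisance design: HRF-convolved task boxcar, 6 motion
    parameters, their backward-difference derivatives, and an intercept.

    The boxcar is convolved on an oversampled grid for accuracy, then
    decimated to the TR grid. All-zero columns (other than the intercept)
    are dropped with a logged warning.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ConformabilityError(f"motion must be (n_volumes, 6), got {motion.shape}")
    if motion.shape[0] != n_volumes:
        raise ConformabilityError(
            f"motion length {motion.shape[0]} != n_volumes {n_volumes}"
        )

    dt = tr / oversample
    grid = np.arange(int(round(n_volumes * oversample))) * dt
    box = np.zeros(grid.shape[0])
    for _, row in paradigm.onsets().iterrows():
        if row["condition"] == "task":
            box[(grid >= row["onset"]) & (grid < row["onset"] + row["duration"])] = 1.0
    hrf = canonical_hrf(dt)
    task = np.convolve(box, hrf.values)[: grid.shape[0]][::oversample][:n_volumes]

    derivatives = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    columns = [task[:, None], motion, derivatives, np.ones((n_volumes, 1))]
    labels = (
        ["task"]
        + [f"motion_{i + 1}" for i in range(6)]
        + [f"motion_deriv_{i + 1}" for i in range(6)]
        + ["intercept"]
    )
    X = np.hstack(columns)

    keep = [i for i in range(X.shape[1]) if labels[i] == "intercept" or np.ptp(X[:, i]) > 0]
    dropped = [labels[i] for i in range(X.shape[1]) if i not in keep]
    if dropped:
        logger.warning("dropping constant nuisance columns: %s", ", ".join(dropped))
    return NuisanceModel(regressors=X[:, keep], labels=[labels[i] for i in keep])


def regress_out(data: np.ndarray, model: NuisanceModel) -> np.ndarray:
    """OLS residuals of each column of ``data`` (time x components) on the
    nuisance design. Collinear design columns are dropped with a warning."""
    data = np.asarray(data, dtype=float)
    X = model.regressors
    if data.shape[0] != X.shape[0]:
        raise ConformabilityError(
            f"data has {data.shape[0]} rows but model has {X.shape[0]}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr as scipy_qr

        _, _, perm = scipy_qr(X, mode="economic", pivoting=True)
        keep = np.sort(perm[:rank])
        dropped = [model.labels[i] for i in perm[rank:]]
        logger.warning("dropping collinear nuisance columns: %s", ", ".join(dropped))
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, data, rcond=None)
    return data - X @ beta


def detrend_lowpass(
    data: np.ndarray, tr: float, cutoff: float = 0.1, order: int = 5
) -> np.ndarray:
    """Linear detrend per component, then zero-phase Butterworth low-pass."""
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 30:
        raise InvalidConfigError(
            f"need at least 30 samples for stable filtering, got {data.shape[0]}"
        )
    nyquist = 0.5 / tr
    if cutoff >= nyquist:
        raise InvalidConfigError(
            f"cutoff {cutoff} Hz must be below Nyquist {nyquist} Hz"
        )
    detrended = signal.detrend(data, axis=0, type="linear")
    sos = signal.butter(order, cutoff, btype="low", fs=1.0 / tr, output="sos")
    return signal.sosfiltfilt(sos, detrended, axis=0)


def framewise_displacement(motion: np.ndarray, radius: float = 50.0) -> np.ndarray:
    """Power framewise displacement: sum of absolute backward differences of
    the three translations (mm) plus ``radius`` times those of the three
    rotations (radians). First frame is 0."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ConformabilityError(f"motion must be (n_volumes, 6), got {motion.shape}")
    deltas = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = deltas[:, :3].sum(axis=1) + radius * deltas[:, 3:].sum(axis=1)
    return fd
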