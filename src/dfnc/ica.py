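"""Two-stage PCA + repeated-run ICA with stability scoring.

Subject data (time x voxels) are reduced per subject, temporally
concatenated, reduced again at the group level, and unmixed by a
fixed-point negentropy ICA run repeatedly from different seeds. Estimates
are clustered across runs by absolute spatial correlation; each component's
stability index (Iq) is its mean intra-cluster minus mean extra-cluster
absolute correlation. Subject maps/time courses come from dual-regression
back-reconstruction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from dfnc.errors import ConformabilityError, DecompositionError, InvalidConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "GroupDecomposition",
    "SubjectComponents",
    "two_stage_pca",
    "run_ica_stable",
    "back_reconstruct",
    "select_components",
]


@dataclass
class PCAReduction:
    """Stored projections from the two PCA stages."""

    reduced: np.ndarray  # (n2, n_voxels) group-level reduced data
    subject_bases: list[np.ndarray]  # per subject (T_i, n1) left singular vectors
    group_basis: np.ndarray  # (n_subjects * n1, n2)
    n1: int
    n2: int
    explained_variance_ratio: np.ndarray  # group-stage, length n2


@dataclass
class GroupDecomposition:
    """Group spatial maps with per-component stability."""

    maps: np.ndarray  # (n_components, n_voxels), unit norm, peak positive
    mixing: np.ndarray  # (n2, n_components) on the reduced data
    stability: np.ndarray | None  # Iq per component; None when n_runs == 1
    reduction: PCAReduction


@dataclass
class SubjectComponents:
    """Back-reconstructed subject maps and time courses."""

    maps: np.ndarray  # (n_components, n_voxels)
    timecourses: np.ndarray  # (T, n_components)
    selection: np.ndarray | None = None  # boolean mask over components


def _fix_sign(maps: np.ndarray) -> np.ndarray:
    """Flip each map so its peak-magnitude element is positive."""
    out = maps.copy()
    for i, row in enumerate(out):
        peak = np.abs(row).argmax()
        if row[peak] < 0:
            out[i] = -row
    return out


def two_stage_pca(
    subject_data: list[np.ndarray], n1: int = 27, n2: int = 18
) -> PCAReduction:
    """Per-subject PCA to ``n1`` components, temporal concatenation, then a
    group PCA to ``n2`` components."""
    if len(subject_data) < 2:
        raise InvalidConfigError("two-stage PCA needs at least 2 subjects")
    if n2 > n1:
        raise InvalidConfigError(f"n2={n2} must not exceed n1={n1}")
    reduced_blocks = []
    bases = []
    for i, Y in enumerate(subject_data):
        Y = np.asarray(Y, dtype=float)
        if min(Y.shape) < n1:
            raise InvalidConfigError(
                f"subject {i}: n1={n1} exceeds min data dimension {min(Y.shape)}"
            )
        Yc = Y - Y.mean(axis=0)
        U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
        bases.append(U[:, :n1])
        reduced_blocks.append(s[:n1, None] * Vt[:n1])  # (n1, n_voxels)
    stacked = np.vstack(reduced_blocks)  # (n_subjects * n1, n_voxels)
    Ug, sg, Vtg = np.linalg.svd(stacked, full_matrices=False)
    evr = sg**2 / (sg**2).sum()
    return PCAReduction(
        reduced=sg[:n2, None] * Vtg[:n2],
        subject_bases=bases,
        group_basis=Ug[:, :n2],
        n1=n1,
        n2=n2,
        explained_variance_ratio=evr[:n2],
    )


def _single_ica(X: np.ndarray, seed: int, max_iter: int = 1000) -> np.ndarray:
    """One ICA run on (n_channels, n_voxels) data; returns unit-norm maps."""
    n_comp = X.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        ica = FastICA(
            n_components=n_comp,
            random_state=seed,
            max_iter=max_iter,
            whiten="unit-variance",
        )
        sources = ica.fit_transform(X.T).T  # (n_comp, n_voxels)
    norms = np.linalg.norm(sources, axis=1, keepdims=True)
    return _fix_sign(sources / norms)


def run_ica_stable(
    reduction: PCAReduction | np.ndarray,
    n_runs: int = 10,
    seed: int = 0,
    max_retries: int = 3,
) -> GroupDecomposition:
    """Repeated-run ICA with greedy cross-run clustering of estimates.

    All ``n_runs * n_components`` estimates are pooled; clusters are grown
    greedily by absolute spatial correlation and each component is
    represented by its centrotype (the member with the highest mean
    intra-cluster |r|). Iq = mean intra-cluster minus mean extra-cluster
    absolute correlation; undefined (None) for ``n_runs == 1``.
    """
    if isinstance(reduction, np.ndarray):
        reduction = PCAReduction(
            reduced=np.asarray(reduction, dtype=float),
            subject_bases=[],
            group_basis=np.empty((0, reduction.shape[0])),
            n1=reduction.shape[0],
            n2=reduction.shape[0],
            explained_variance_ratio=np.array([]),
        )
    X = reduction.reduced
    n_comp = X.shape[0]
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_runs * (max_retries + 1))]

    estimates = []
    seed_idx = 0
    for run in range(n_runs):
        for attempt in range(max_retries + 1):
            try:
                estimates.append(_single_ica(X, run_seeds[seed_idx]))
                seed_idx += 1
                break
            except (ConvergenceWarning, Exception) as exc:  # noqa: BLE001
                seed_idx += 1
                if isinstance(exc, (KeyboardInterrupt, SystemExit)):
                    raise
                logger.warning("ICA run %d attempt %d failed (%s); retrying", run, attempt, exc)
        else:
            logger.warning("ICA run %d failed after retries; skipped", run)
    if not estimates:
        raise DecompositionError("all ICA runs failed")
    n_ok = len(estimates)

    pooled = np.vstack(estimates)  # (n_ok * n_comp, n_voxels)
    if n_ok == 1:
        return GroupDecomposition(
            maps=estimates[0],
            mixing=_mixing_for(reduction, estimates[0]),
            stability=None,
            reduction=reduction,
        )

    sim = np.abs(np.corrcoef(pooled))  # |r| between all estimates
    np.fill_diagonal(sim, 0.0)
    n_total = pooled.shape[0]
    unassigned = set(range(n_total))
    clusters: list[list[int]] = []
    for _ in range(n_comp):
        if not unassigned:
            break
        # seed the cluster at the unassigned pair with maximal |r|
        idx = sorted(unassigned)
        sub = sim[np.ix_(idx, idx)]
        i, j = np.unravel_index(sub.argmax(), sub.shape)
        cluster = [idx[i], idx[j]]
        unassigned -= set(cluster)
        while len(cluster) < n_ok and unassigned:
            rest = sorted(unassigned)
            mean_sim = sim[np.ix_(rest, cluster)].mean(axis=1)
            best = rest[int(mean_sim.argmax())]
            cluster.append(best)
            unassigned.remove(best)
        clusters.append(cluster)

    maps = np.empty((n_comp, pooled.shape[1]))
    iq = np.empty(n_comp)
    member_mask = np.zeros(n_total, dtype=bool)
    for c, cluster in enumerate(clusters):
        member_mask[:] = False
        member_mask[cluster] = True
        intra = sim[np.ix_(cluster, cluster)]
        intra_mean = intra.sum() / (len(cluster) * (len(cluster) - 1))
        extra = sim[np.ix_(cluster, np.where(~member_mask)[0])]
        extra_mean = extra.mean() if extra.size else 0.0
        iq[c] = intra_mean - extra_mean
        within_scores = intra.sum(axis=1)
        maps[c] = pooled[cluster[int(within_scores.argmax())]]
    maps = _fix_sign(maps)

    order = np.argsort(-iq)
    return GroupDecomposition(
        maps=maps[order],
        mixing=_mixing_for(reduction, maps[order]),
        stability=iq[order],
        reduction=reduction,
    )


def _mixing_for(reduction: PCAReduction, maps: np.ndarray) -> np.ndarray:
    """Least-squares mixing of the maps within the reduced data."""
    return reduction.reduced @ np.linalg.pinv(maps)


def back_reconstruct(
    decomposition: GroupDecomposition, subject_data: np.ndarray
) -> SubjectComponents:
    """Dual regression: group maps -> subject time courses -> subject maps."""
    Y = np.asarray(subject_data, dtype=float)
    maps = decomposition.maps
    if Y.ndim != 2 or Y.shape[1] != maps.shape[1]:
        raise ConformabilityError(
            f"subject data {Y.shape} does not conform to maps {maps.shape}"
        )
    timecourses = Y @ np.linalg.pinv(maps)  # (T, n_comp)
    subject_maps = np.linalg.pinv(timecourses) @ Y  # (n_comp, n_voxels)
    return SubjectComponents(maps=_fix_sign(subject_maps), timecourses=timecourses)


def select_components(
    subject_components: list[SubjectComponents],
    tr: float,
    low_freq_cutoff: float = 0.10,
    power_fraction_threshold: float | None = 0.5,
    exclusion_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean retention mask over components.

    A component is rejected when its spatial peak (subject-average absolute
    map) falls inside ``exclusion_mask``, or when its mean low-frequency
    power fraction (power below ``low_freq_cutoff`` over total power up to
    Nyquist, averaged across subjects) falls below
    ``power_fraction_threshold``. With no criteria configured all components
    are retained.
    """
    if not subject_components:
        raise InvalidConfigError("need at least one subject")
    n_comp = subject_components[0].maps.shape[0]
    keep = np.ones(n_comp, dtype=bool)

    if exclusion_mask is not None:
        mask = np.asarray(exclusion_mask, dtype=bool).ravel()
        mean_maps = np.mean([np.abs(sc.maps) for sc in subject_components], axis=0)
        if mean_maps.shape[1] != mask.size:
            raise ConformabilityError("exclusion mask does not match map size")
        peaks = mean_maps.argmax(axis=1)
        keep &= ~mask[peaks]

    if power_fraction_threshold is not None:
        if not (0 <= power_fraction_threshold <= 1):
            raise InvalidConfigError("power_fraction_threshold must lie in [0, 1]")
        fracs = np.zeros(n_comp)
        for sc in subject_components:
            freqs, psd = sp_signal.periodogram(sc.timecourses, fs=1.0 / tr, axis=0)
            total = psd.sum(axis=0)
            low = psd[freqs < low_freq_cutoff].sum(axis=0)
            with np.errstate(invalid="ignore"):
                frac = np.where(total > 0, low / total, 1.0)
            fracs += frac
        fracs /= len(subject_components)
        keep &= fracs >= power_fraction_threshold

    if not keep.any():
        logger.warning("component selection rejected every component")
    return keep
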