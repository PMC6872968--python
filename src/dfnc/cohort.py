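"""Synthetic multi-subject, two-task cohort with planted state structure.

Every downstream stage (windowed correlation, state clustering, inference)
can be validated against the ground truth planted here: a first-order Markov
chain switches the covariance regime at TR resolution, a task boxcar
convolved with the canonical HRF drives designated components, motion is an
AR(1)-smoothed walk rescaled to a target mean framewise displacement, and
behavioral sensitivity (d') is coupled to state dwell time through a shared
Gaussian latent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from dfnc.errors import ConformabilityError, DecompositionError, InvalidConfigError

TASKS = ("discrimination", "nback")

__all__ = [
    "TASKS",
    "Paradigm",
    "GroundTruth",
    "SubjectRun",
    "Cohort",
    "make_paradigm",
    "default_ground_truth",
    "sample_state_sequence",
    "simulate_subject",
    "simulate_voxel_mixture",
    "simulate_behavior",
    "simulate_cohort",
    "cohort_behavior_table",
]


# ---------------------------------------------------------------------------
# paradigm
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Paradigm:
    """Block timing of one run.

    ``block_specs`` is the ordered list of ``(kind, duration_s)`` pairs that
    follows the initial fixation, with ``kind`` in ``{"task", "rest"}``.
    """

    fixation_duration: float
    block_specs: tuple[tuple[str, float], ...]
    stimulus_duration: float
    inter_stimulus_interval: float
    stimuli_per_block: int
    tr: float

    @property
    def total_duration(self) -> float:
        return self.fixation_duration + sum(d for _, d in self.block_specs)

    @property
    def n_volumes(self) -> int:
        return int(round(self.total_duration / self.tr))

    @property
    def task_block_duration(self) -> float:
        durations = {d for kind, d in self.block_specs if kind == "task"}
        if not durations:
            return 0.0
        return durations.pop()

    def onsets(self) -> pd.DataFrame:
        """Three-column onset/duration/condition table (seconds)."""
        rows = [(0.0, self.fixation_duration, "fixation")]
        t = self.fixation_duration
        for kind, dur in self.block_specs:
            rows.append((t, dur, kind))
            t += dur
        return pd.DataFrame(rows, columns=["onset", "duration", "condition"])

    def boxcar(self, condition: str = "task") -> np.ndarray:
        """Indicator of ``condition`` sampled on the TR grid (length n_volumes)."""
        grid = np.arange(self.n_volumes) * self.tr
        box = np.zeros(self.n_volumes)
        for _, row in self.onsets().iterrows():
            if row["condition"] == condition:
                box[(grid >= row["onset"]) & (grid < row["onset"] + row["duration"])] = 1.0
        return box


def make_paradigm(
    fixation_duration: float = 8.0,
    n_task_blocks: int = 8,
    rest_block_duration: float = 12.0,
    stimulus_duration: float = 2.5,
    inter_stimulus_interval: float = 0.5,
    stimuli_per_block: int = 12,
    trailing_rest: float = 10.0,
    tr: float = 2.0,
) -> Paradigm:
    """Build a block paradigm: fixation, then task blocks interleaved with rest.

    The task-block duration is derived as
    ``stimuli_per_block * (stimulus_duration + inter_stimulus_interval)``.
    Defaults give 8 task blocks of 36 s interleaved with 8 rest blocks of
    12 s after an 8 s fixation, plus 10 s trailing rest: 402 s, 201 volumes
    at TR 2 s.
    """
    for name, value in [
        ("fixation_duration", fixation_duration),
        ("rest_block_duration", rest_block_duration),
        ("stimulus_duration", stimulus_duration),
        ("inter_stimulus_interval", inter_stimulus_interval),
        ("tr", tr),
    ]:
        if value <= 0:
            raise InvalidConfigError(f"{name} must be positive, got {value!r}")
    if stimuli_per_block < 1:
        raise InvalidConfigError(
            f"stimuli_per_block must be >= 1, got {stimuli_per_block!r}"
        )
    if n_task_blocks < 1:
        raise InvalidConfigError(f"n_task_blocks must be >= 1, got {n_task_blocks!r}")
    if trailing_rest < 0:
        raise InvalidConfigError(f"trailing_rest must be >= 0, got {trailing_rest!r}")

    task_dur = stimuli_per_block * (stimulus_duration + inter_stimulus_interval)
    blocks: list[tuple[str, float]] = []
    for i in range(n_task_blocks):
        blocks.append(("task", task_dur))
        blocks.append(("rest", rest_block_duration))
    if trailing_rest > 0:
        blocks.append(("rest", trailing_rest))
    return Paradigm(
        fixation_duration=fixation_duration,
        block_specs=tuple(blocks),
        stimulus_duration=stimulus_duration,
        inter_stimulus_interval=inter_stimulus_interval,
        stimuli_per_block=stimuli_per_block,
        tr=tr,
    )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Planted statistical structure of the cohort."""

    state_covariances: np.ndarray  # (k, n_components, n_components), correlation scale
    transition_matrix: np.ndarray  # (k, k) row-stochastic
    task_amplitude: float = 1.0
    noise_sd: float = 0.2
    behavior_coupling: float = 0.58
    behavior_latent_sd: float = 1.0
    d_prime_base: float = 1.5
    coupled_state: int = 1
    task_components: tuple[int, ...] = (0, 1)
    target_fd: float = 0.04
    # when set, rest/fixation periods are pinned to this regime instead of
    # evolving with the Markov chain (default: regimes independent of paradigm)
    rest_state: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.state_covariances = np.asarray(self.state_covariances, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        k = self.state_covariances.shape[0]
        if self.transition_matrix.shape != (k, k):
            raise InvalidConfigError(
                "transition_matrix shape "
                f"{self.transition_matrix.shape} does not match {k} states"
            )
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-8):
            raise InvalidConfigError("transition_matrix rows must sum to 1")
        if np.any(self.transition_matrix < 0):
            raise InvalidConfigError("transition_matrix entries must be >= 0")
        if abs(self.behavior_coupling) > 1:
            raise InvalidConfigError("behavior_coupling must lie in [-1, 1]")
        for s, cov in enumerate(self.state_covariances):
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise InvalidConfigError(f"state {s} covariance is not symmetric")
            if not np.allclose(np.diag(cov), 1.0, atol=1e-10):
                raise InvalidConfigError(f"state {s} covariance must have unit diagonal")

    @property
    def n_states(self) -> int:
        return self.state_covariances.shape[0]

    @property
    def n_components(self) -> int:
        return self.state_covariances.shape[1]

    def cholesky_factors(self) -> np.ndarray:
        factors = np.empty_like(self.state_covariances)
        for s, cov in enumerate(self.state_covariances):
            try:
                factors[s] = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:
                raise DecompositionError(
                    f"state {s} covariance is not positive definite"
                ) from exc
        return factors


def _sign_pattern_correlation(v: np.ndarray, rho: float) -> np.ndarray:
    """Unit-diagonal correlation ``(1 - rho) I + rho v v^T`` for ``v`` in
    {-1, +1}^n; positive definite for 0 < rho < 1."""
    return (1.0 - rho) * np.eye(v.size) + rho * np.outer(v, v)


def default_ground_truth(
    n_components: int = 14,
    n_states: int = 4,
    self_transition: float = 0.985,
    state_corr: float = 0.6,
    seed: int = 0,
    **kwargs,
) -> GroundTruth:
    """Well-separated planted states built from near-orthogonal sign patterns.

    State ``s`` has correlation ``(1 - rho) I + rho v_s v_s^T`` where the
    ``v_s`` are distinct rows of a Hadamard matrix (columns permuted by the
    seed). Orthogonal sign vectors disagree on about half of the component
    pairs, so every pair of states is separated by a large, near-uniform L1
    centroid distance — the regime the downstream recovery guarantees assume.
    """
    from scipy.linalg import hadamard

    if n_states < 1:
        raise InvalidConfigError("n_states must be >= 1")
    order = 1
    while order < max(n_components, n_states + 1):
        order *= 2
    H = hadamard(order)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_components)
    covs = [
        _sign_pattern_correlation(H[s + 1, :n_components][perm], state_corr)
        for s in range(n_states)
    ]
    if n_states == 1:
        trans = np.ones((1, 1))
    else:
        trans = np.full((n_states, n_states), (1 - self_transition) / (n_states - 1))
        np.fill_diagonal(trans, self_transition)
    return GroundTruth(
        state_covariances=np.stack(covs),
        transition_matrix=trans,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# markov regimes
# ---------------------------------------------------------------------------


def sample_state_sequence(
    transition_matrix: np.ndarray,
    n_steps: int,
    seed: int | np.random.Generator,
    initial_distribution: np.ndarray | None = None,
) -> np.ndarray:
    """Sample a first-order Markov label sequence (labels ``0..k-1``).

    The chain starts from ``initial_distribution`` (default: uniform) and is
    fully reproducible for a fixed seed.
    """
    P = np.asarray(transition_matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise InvalidConfigError(f"transition matrix must be square, got {P.shape}")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise InvalidConfigError("transition matrix rows must sum to 1 (tol 1e-8)")
    if np.any(P < 0):
        raise InvalidConfigError("transition matrix entries must be >= 0")
    if n_steps < 1:
        raise InvalidConfigError(f"n_steps must be >= 1, got {n_steps}")

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = P.shape[0]
    init = (
        np.full(k, 1.0 / k)
        if initial_distribution is None
        else np.asarray(initial_distribution, dtype=float)
    )
    cum = np.cumsum(P, axis=1)
    u = rng.random(n_steps)
    labels = np.empty(n_steps, dtype=np.int64)
    labels[0] = np.searchsorted(np.cumsum(init), u[0], side="right")
    for t in range(1, n_steps):
        labels[t] = np.searchsorted(cum[labels[t - 1]], u[t], side="right")
    return np.minimum(labels, k - 1)


# ---------------------------------------------------------------------------
# subject-level simulation
# ---------------------------------------------------------------------------


@dataclass
class SubjectRun:
    """One subject's run: component time series plus simulation ground truth."""

    subject: str
    task: str
    data: np.ndarray  # (n_volumes, n_components)
    tr: float
    motion: np.ndarray  # (n_volumes, 6)
    state_labels: np.ndarray  # (n_volumes,) true regime per TR

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]


def _simulate_motion(
    n_volumes: int, target_fd: float, rng: np.random.Generator, ar: float = 0.8
) -> np.ndarray:
    """AR(1)-smoothed Gaussian walk over 6 parameters, rescaled so the mean
    Power framewise displacement equals ``target_fd`` (50 mm head radius)."""
    if target_fd == 0:
        return np.zeros((n_volumes, 6))
    steps = np.empty((n_volumes, 6))
    steps[0] = 0.0
    innov = rng.standard_normal((n_volumes, 6))
    for t in range(1, n_volumes):
        steps[t] = ar * steps[t - 1] + innov[t]
    motion = np.cumsum(steps, axis=0)
    # rotations start two orders smaller so the 50 mm radius term is comparable
    motion[:, 3:] *= 0.01
    deltas = np.abs(np.diff(motion, axis=0))
    fd = deltas[:, :3].sum(axis=1) + 50.0 * deltas[:, 3:].sum(axis=1)
    mean_fd = fd.mean()
    if mean_fd == 0:
        return motion
    return motion * (target_fd / mean_fd)


def simulate_subject(
    paradigm: Paradigm,
    ground_truth: GroundTruth,
    subject_seed: int | np.random.Generator,
    subject: str = "sub-01",
    task: str = TASKS[0],
    state_labels: np.ndarray | None = None,
) -> SubjectRun:
    """Simulate one run: state-conditional Gaussian draws plus HRF-convolved
    task signal on the designated components plus white noise."""
    from dfnc.prep import canonical_hrf  # local import to avoid a cycle

    rng = (
        subject_seed
        if isinstance(subject_seed, np.random.Generator)
        else np.random.default_rng(subject_seed)
    )
    T = paradigm.n_volumes
    C = ground_truth.n_components
    if state_labels is None:
        state_labels = sample_state_sequence(ground_truth.transition_matrix, T, rng)
        if ground_truth.rest_state is not None:
            state_labels = np.where(
                paradigm.boxcar("task") > 0, state_labels, ground_truth.rest_state
            )
    else:
        state_labels = np.asarray(state_labels, dtype=np.int64)
        if state_labels.shape != (T,):
            raise ConformabilityError(
                f"state_labels length {state_labels.shape} != n_volumes {T}"
            )

    factors = ground_truth.cholesky_factors()
    z = rng.standard_normal((T, C))
    data = np.einsum("tij,tj->ti", factors[state_labels], z)

    if ground_truth.task_amplitude != 0:
        hrf = canonical_hrf(paradigm.tr)
        reg = np.convolve(paradigm.boxcar("task"), hrf.values)[:T]
        for c in ground_truth.task_components:
            data[:, c] += ground_truth.task_amplitude * reg

    if ground_truth.noise_sd > 0:
        data += ground_truth.noise_sd * rng.standard_normal((T, C))

    motion = _simulate_motion(T, ground_truth.target_fd, rng)
    return SubjectRun(
        subject=subject,
        task=task,
        data=data,
        tr=paradigm.tr,
        motion=motion,
        state_labels=state_labels,
    )


def simulate_voxel_mixture(
    spatial_maps: np.ndarray,
    component_timeseries: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Voxels x time mixture: ``spatial_maps.T @ component_timeseries`` plus
    white Gaussian noise. ``spatial_maps`` is components x voxels and
    ``component_timeseries`` is components x time."""
    maps = np.asarray(spatial_maps, dtype=float)
    ts = np.asarray(component_timeseries, dtype=float)
    if maps.ndim != 2 or ts.ndim != 2 or maps.shape[0] != ts.shape[0]:
        raise ConformabilityError(
            f"maps {maps.shape} and time series {ts.shape} are not conformable"
        )
    out = maps.T @ ts
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        out = out + noise_sd * rng.standard_normal(out.shape)
    return out


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


def simulate_behavior(
    d_prime_true: float,
    n_trials: int,
    latents: np.ndarray | float = 0.0,
    seed: int | np.random.Generator = 0,
    subjects: list[str] | None = None,
    task: str = TASKS[0],
) -> pd.DataFrame:
    """Draw hit / false-alarm counts from the equal-variance signal-detection
    model.

    Subject ``i`` responds with sensitivity ``d_prime_true + latents[i]`` and
    neutral criterion: hit rate ``Phi(d/2)``, false-alarm rate ``Phi(-d/2)``,
    each observed over ``n_trials`` binomial trials. The estimated d' (with
    log-linear correction) converges to the planted per-subject value as
    ``n_trials`` grows.
    """
    if n_trials < 1:
        raise InvalidConfigError(f"n_trials must be >= 1, got {n_trials}")
    if not np.isfinite(d_prime_true):
        raise InvalidConfigError("d_prime_true must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latents = np.atleast_1d(np.asarray(latents, dtype=float))
    n_sub = latents.shape[0]
    if subjects is None:
        subjects = [f"sub-{i + 1:02d}" for i in range(n_sub)]

    d = d_prime_true + latents
    hit_rate = norm.cdf(d / 2.0)
    fa_rate = norm.cdf(-d / 2.0)
    hits = rng.binomial(n_trials, hit_rate)
    fas = rng.binomial(n_trials, fa_rate)
    return pd.DataFrame(
        {
            "subject": subjects,
            "task": task,
            "n_signal_trials": n_trials,
            "n_noise_trials": n_trials,
            "hits": hits,
            "false_alarms": fas,
            "d_prime_true": d,
        }
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    paradigm: Paradigm
    ground_truth: GroundTruth
    runs: list[SubjectRun]
    behavior: pd.DataFrame
    seed: int = 0

    @property
    def subjects(self) -> list[str]:
        return sorted({r.subject for r in self.runs})


def _dwell_fraction(labels: np.ndarray, state: int) -> float:
    return float(np.mean(labels == state))


def _coupled_latents(
    dwell: np.ndarray, coupling: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian latent correlated with the (standardized) realized dwell."""
    sd = dwell.std()
    z = (dwell - dwell.mean()) / sd if sd > 0 else np.zeros_like(dwell)
    eps = rng.standard_normal(dwell.shape[0])
    return coupling * z + np.sqrt(max(0.0, 1.0 - coupling**2)) * eps


def simulate_cohort(
    n_subjects: int = 20,
    paradigm: Paradigm | None = None,
    ground_truth: GroundTruth | None = None,
    n_trials: int = 96,
    seed: int = 0,
    tasks: tuple[str, ...] = TASKS,
    timeseries: bool = True,
) -> Cohort:
    """Simulate the full two-task cohort as a pure function of (config, seed).

    Behavioral d' is coupled to the fractional dwell time of
    ``ground_truth.coupled_state`` within each task via a shared Gaussian
    latent at correlation ``behavior_coupling``. With ``timeseries=False``
    only state sequences, motion summaries, and behavior are produced (fast
    path for replicate studies).
    """
    paradigm = paradigm or make_paradigm()
    gt = ground_truth if ground_truth is not None else default_ground_truth(seed=seed)
    master = np.random.SeedSequence([seed, gt.seed])
    run_seeds = master.spawn(len(tasks) * n_subjects + len(tasks))

    runs: list[SubjectRun] = []
    behavior_frames = []
    idx = 0
    for t_idx, task in enumerate(tasks):
        dwell = np.empty(n_subjects)
        fd_means = np.empty(n_subjects)
        subjects = [f"sub-{i + 1:02d}" for i in range(n_subjects)]
        for i in range(n_subjects):
            rng = np.random.default_rng(run_seeds[idx])
            idx += 1
            labels = sample_state_sequence(
                gt.transition_matrix, paradigm.n_volumes, rng
            )
            dwell[i] = _dwell_fraction(labels, gt.coupled_state)
            if timeseries:
                run = simulate_subject(
                    paradigm, gt, rng, subject=subjects[i], task=task, state_labels=labels
                )
            else:
                run = SubjectRun(
                    subject=subjects[i],
                    task=task,
                    data=np.empty((0, gt.n_components)),
                    tr=paradigm.tr,
                    motion=_simulate_motion(paradigm.n_volumes, gt.target_fd, rng),
                    state_labels=labels,
                )
            deltas = np.abs(np.diff(run.motion, axis=0))
            fd = deltas[:, :3].sum(axis=1) + 50.0 * deltas[:, 3:].sum(axis=1)
            fd_means[i] = fd.mean() if fd.size else 0.0
            runs.append(run)

        task_rng = np.random.default_rng(run_seeds[idx])
        idx += 1
        latents = gt.behavior_latent_sd * _coupled_latents(
            dwell, gt.behavior_coupling, task_rng
        )
        beh = simulate_behavior(
            gt.d_prime_base, n_trials, latents, task_rng, subjects=subjects, task=task
        )
        beh["mean_fd"] = fd_means
        beh["true_dwell_coupled_state"] = dwell
        behavior_frames.append(beh)

    return Cohort(
        paradigm=paradigm,
        ground_truth=gt,
        runs=runs,
        behavior=pd.concat(behavior_frames, ignore_index=True),
        seed=seed,
    )


def cohort_behavior_table(cohort: Cohort) -> pd.DataFrame:
    """Behavior table augmented with corrected d' estimates."""
    from dfnc.inference import dprime

    beh = cohort.behavior.copy()
    beh["d_prime"] = [
        dprime(r.hits, r.n_signal_trials, r.false_alarms, r.n_noise_trials)
        for r in beh.itertuples()
    ]
    return beh
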