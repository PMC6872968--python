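"""Group and brain-behavior inference.

Between-task differences in state metrics are tested by permutation of the
group labels; state-specific edgewise differences by paired t-tests with
Benjamini-Hochberg FDR; behavioral sensitivity by d' with log-linear
correction; and brain-behavior association by a first-order partial Pearson
correlation controlling mean framewise displacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri
from statsmodels.stats.multitest import multipletests

from dfnc.errors import InvalidConfigError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "permutation_mean_diff",
    "state_edge_paired_t",
    "dprime",
    "partial_corr_behavior",
    "ks_normality",
]


@dataclass
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    sidedness: str = "two-sided"
    n_permutations: int | None = None
    df: int | None = None
    q_value: float | None = None
    r: float | None = None


def permutation_mean_diff(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator = 0,
    sidedness: str = "two-sided",
) -> TestResult:
    """Permutation test on the difference of group means.

    Values are pooled and randomly reassigned to the two groups
    ``n_permutations`` times. Two-sided (default):
    ``p = (1 + #{|perm| >= |observed|}) / (B + 1)``; ``sidedness='greater'``
    applies the one-sided rule on the signed difference.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each group needs at least 2 values")
    if n_permutations < 100:
        raise InvalidConfigError(f"need >= 100 permutations, got {n_permutations}")
    if sidedness not in ("two-sided", "greater"):
        raise InvalidConfigError(f"unknown sidedness {sidedness!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n_a, n_tot = a.size, pooled.size
    # one permutation per row
    perms = rng.permuted(
        np.broadcast_to(pooled, (n_permutations, n_tot)).copy(), axis=1
    )
    perm_stats = perms[:, :n_a].mean(axis=1) - perms[:, n_a:].mean(axis=1)
    if sidedness == "two-sided":
        count = int(np.count_nonzero(np.abs(perm_stats) >= abs(observed)))
    else:
        count = int(np.count_nonzero(perm_stats >= observed))
    p = (1 + count) / (n_permutations + 1)
    return TestResult(
        statistic=float(observed),
        p_value=float(p),
        sidedness=sidedness,
        n_permutations=n_permutations,
    )


def state_mean_fnc(
    windows: np.ndarray, labels: np.ndarray, state: int
) -> np.ndarray | None:
    """Mean edge vector over the windows one run spent in ``state``;
    None if the run never visited it."""
    mask = np.asarray(labels) == state
    if not mask.any():
        return None
    return np.asarray(windows, dtype=float)[mask].mean(axis=0)


def state_edge_paired_t(
    task_a_means: dict[str, np.ndarray],
    task_b_means: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> pd.DataFrame | None:
    """Edgewise paired t-tests between tasks on state-specific mean FNC.

    Inputs map subject id -> mean edge vector for the state (from
    :func:`state_mean_fnc`); subjects missing in either task (no windows in
    the state) are excluded pairwise with a log message. Returns a tidy
    frame with t, p, BH-FDR q, and the rejection flag per edge, or None if
    fewer than 3 complete pairs remain.
    """
    common = sorted(set(task_a_means) & set(task_b_means))
    dropped = sorted(set(task_a_means) ^ set(task_b_means))
    if dropped:
        logger.info("excluding %d incomplete pairs: %s", len(dropped), dropped)
    if len(common) < 3:
        logger.warning("fewer than 3 complete pairs; paired t-test skipped")
        return None
    A = np.vstack([task_a_means[s] for s in common])
    B = np.vstack([task_b_means[s] for s in common])
    t, p = stats.ttest_rel(A, B, axis=0)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "edge": np.arange(A.shape[1]),
            "t": t,
            "p": p,
            "q": q,
            "reject": reject,
            "n_pairs": len(common),
        }
    )


def dprime(hits: int, n_signal: int, false_alarms: int, n_noise: int) -> float:
    """Signal-detection sensitivity with the log-linear correction.

    ``d' = Phi^-1((hits + 0.5) / (n_signal + 1)) -
    Phi^-1((false_alarms + 0.5) / (n_noise + 1))``; the correction keeps d'
    finite at perfect or zero rates and is applied always.
    """
    if n_signal <= 0 or n_noise <= 0:
        raise InvalidInputError("trial denominators must be positive")
    if not (0 <= hits <= n_signal) or not (0 <= false_alarms <= n_noise):
        raise InvalidInputError("counts must lie within their trial totals")
    hit_rate = (hits + 0.5) / (n_signal + 1)
    fa_rate = (false_alarms + 0.5) / (n_noise + 1)
    return float(ndtri(hit_rate) - ndtri(fa_rate))


def partial_corr_behavior(
    metric: np.ndarray,
    behavior: np.ndarray,
    covariate: np.ndarray,
) -> TestResult:
    """First-order partial Pearson correlation of ``metric`` and
    ``behavior`` controlling ``covariate``, with significance from
    ``t = r sqrt(n - 3) / sqrt(1 - r^2)`` on ``n - 3`` df (two-sided)."""
    x = np.asarray(metric, dtype=float)
    y = np.asarray(behavior, dtype=float)
    z = np.asarray(covariate, dtype=float)
    n = x.size
    if y.size != n or z.size != n:
        raise InvalidInputError("metric, behavior, covariate must have equal length")
    if n < 4:
        raise InvalidInputError(f"need n >= 4, got {n}")
    if np.any(~np.isfinite(np.concatenate([x, y, z]))):
        raise InvalidInputError("missing or non-finite values are not allowed")
    for name, v in [("metric", x), ("behavior", y), ("covariate", z)]:
        if np.std(v) == 0:
            raise InvalidInputError(f"{name} has zero variance")

    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    r = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        t = r * np.sqrt(df) / np.sqrt(1 - r**2)
        p = 2 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), p_value=float(max(p, np.finfo(float).tiny)),
                      df=df, r=r)


def ks_normality(values: np.ndarray) -> TestResult:
    """Kolmogorov-Smirnov test against a fitted normal (diagnostic only)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise InvalidInputError("need at least 3 values")
    stat, p = stats.kstest((v - v.mean()) / v.std(ddof=1), "norm")
    return TestResult(statistic=float(stat), p_value=float(p))
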