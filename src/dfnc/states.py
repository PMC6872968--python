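"""Brain-state clustering and state metrics.

Pooled windowed-FNC rows from all subjects/tasks are clustered by k-means
under the Manhattan (L1) distance with elementwise-median centroid updates
(k-medians). The number of states is chosen by an elbow rule on the
within/between cluster-distance ratio over k = 2..10. Per subject/task,
state metrics are the transition count and fractional dwell time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from dfnc.errors import InvalidConfigError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "StateModel",
    "StateMetrics",
    "kmeans_l1",
    "validity_curve",
    "select_k_elbow",
    "fit_states",
    "state_metrics",
    "metrics_table",
]


@dataclass
class StateModel:
    """Fitted state clustering for a single k."""

    k: int
    centroids: np.ndarray  # (k, n_edges)
    labels: np.ndarray  # (n_windows,) values 0..k-1
    objective: float  # total within-cluster L1 distance
    n_iter: int
    validity: dict[int, float] = field(default_factory=dict)  # k -> within/between ratio


@dataclass
class StateMetrics:
    """Per-sequence transition count and fractional dwell time."""

    n_transitions: int
    fractional_dwell: np.ndarray  # length k, sums to 1


def _kmeans_l1_once(
    X: np.ndarray, k: int, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, int]:
    n = X.shape[0]
    # k-means++-style seeding under L1
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    closest = cdist(X, centroids[:1], metric="cityblock").ravel()
    for j in range(1, k):
        probs = closest / closest.sum() if closest.sum() > 0 else np.full(n, 1.0 / n)
        centroids[j] = X[rng.choice(n, p=probs)]
        closest = np.minimum(closest, cdist(X, centroids[j : j + 1], metric="cityblock").ravel())

    labels = np.full(n, -1)
    objective = np.inf
    for it in range(max_iter):
        dists = cdist(X, centroids, metric="cityblock")
        new_labels = dists.argmin(axis=1)
        row_mins = dists[np.arange(n), new_labels]
        for j in range(k):
            mask = new_labels == j
            if mask.any():
                centroids[j] = np.median(X[mask], axis=0)
            else:  # re-seed empty cluster to the farthest point
                far = row_mins.argmax()
                centroids[j] = X[far]
                new_labels[far] = j
                row_mins[far] = 0.0
        new_objective = float(
            np.abs(X - centroids[new_labels]).sum()
        )
        if np.array_equal(new_labels, labels):
            labels = new_labels
            objective = new_objective
            return labels, centroids, objective, it + 1
        labels, objective = new_labels, new_objective
    return labels, centroids, objective, max_iter


def kmeans_l1(
    X: np.ndarray,
    k: int,
    max_iter: int = 150,
    n_replicates: int = 20,
    seed: int | np.random.Generator = 0,
) -> StateModel:
    """L1 k-means (k-medians): assignment by Manhattan distance, centroid
    update by elementwise median, best of ``n_replicates`` restarts by total
    within-cluster L1 distance. State indices are canonical: sorted by
    descending pooled dwell (cluster size), ties by first occurrence.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidConfigError(f"X must be 2-D, got shape {X.shape}")
    if k < 1:
        raise InvalidConfigError(f"k must be >= 1, got {k}")
    if k > X.shape[0]:
        raise InvalidConfigError(f"k={k} exceeds number of rows {X.shape[0]}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    best = None
    for _ in range(max(1, n_replicates)):
        labels, centroids, objective, n_iter = _kmeans_l1_once(X, k, max_iter, rng)
        if best is None or objective < best[2]:
            best = (labels, centroids, objective, n_iter)
    labels, centroids, objective, n_iter = best

    # canonical ordering by descending occupancy
    counts = np.bincount(labels, minlength=k)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return StateModel(
        k=k,
        centroids=centroids[order],
        labels=remap[labels],
        objective=objective,
        n_iter=n_iter,
    )


def validity_curve(
    X: np.ndarray,
    k_range: range = range(2, 11),
    max_iter: int = 150,
    n_replicates: int = 20,
    seed: int | np.random.Generator = 0,
) -> dict[int, float]:
    """Within/between cluster-distance ratio for each k.

    Ratio = mean L1 distance of rows to their own centroid divided by mean
    pairwise L1 distance among centroids.
    """
    X = np.asarray(X, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    curve: dict[int, float] = {}
    for k in k_range:
        if k > X.shape[0]:
            raise InvalidConfigError(f"k={k} exceeds number of rows {X.shape[0]}")
        model = kmeans_l1(X, k, max_iter=max_iter, n_replicates=n_replicates, seed=rng)
        within = model.objective / X.shape[0]
        iu = np.triu_indices(k, 1)
        between = cdist(model.centroids, model.centroids, metric="cityblock")[iu].mean()
        curve[k] = within / between if between > 0 else np.inf
    return curve


def select_k_elbow(curve: dict[int, float]) -> int:
    """Elbow of the validity curve: the interior k maximizing the discrete
    second difference ``ratio(k-1) - 2 ratio(k) + ratio(k+1)``, ties broken
    toward smaller k. A flat curve returns the smallest k with a warning."""
    ks = sorted(curve)
    if len(ks) < 3:
        raise InvalidConfigError("validity curve needs at least 3 consecutive k values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise InvalidConfigError("validity curve must cover consecutive k values")
    values = np.array([curve[k] for k in ks])
    second = values[:-2] - 2 * values[1:-1] + values[2:]
    if second.max() < 1e-9:
        warnings.warn("validity curve is flat; returning smallest k", stacklevel=2)
        return ks[0]
    return ks[1 + int(second.argmax())]


def fit_states(
    X: np.ndarray,
    k: int | None = None,
    k_range: range = range(2, 11),
    max_iter: int = 150,
    n_replicates: int = 20,
    seed: int = 0,
) -> StateModel:
    """Cluster pooled windows; if ``k`` is None select it by the elbow rule."""
    curve: dict[int, float] = {}
    if k is None:
        curve = validity_curve(
            X, k_range=k_range, max_iter=max_iter, n_replicates=n_replicates, seed=seed
        )
        k = select_k_elbow(curve)
    model = kmeans_l1(X, k, max_iter=max_iter, n_replicates=n_replicates, seed=seed)
    model.validity = curve
    return model


def state_metrics(labels: np.ndarray, k: int) -> StateMetrics:
    """Transition count and fractional dwell time of one label sequence.

    ``n_transitions`` counts adjacent unequal labels; ``fractional_dwell[s]``
    is the share of windows assigned to state ``s`` (labels 0..k-1).
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise InvalidInputError("empty label sequence")
    if labels.min() < 0 or labels.max() >= k:
        raise InvalidInputError(f"labels must lie in [0, {k}), got range "
                                f"[{labels.min()}, {labels.max()}]")
    n_transitions = int(np.count_nonzero(labels[1:] != labels[:-1]))
    dwell = np.bincount(labels, minlength=k).astype(float) / labels.size
    return StateMetrics(n_transitions=n_transitions, fractional_dwell=dwell)


def metrics_table(
    labels_by_run: dict[tuple[str, str], np.ndarray], k: int
) -> pd.DataFrame:
    """Tidy per subject/task metrics: one row per run with transition count
    and dwell_1..dwell_k columns."""
    rows = []
    for (subject, task), labels in sorted(labels_by_run.items()):
        m = state_metrics(labels, k)
        row = {"subject": subject, "task": task, "n_transitions": m.n_transitions}
        for s in range(k):
            row[f"dwell_{s + 1}"] = m.fractional_dwell[s]
        rows.append(row)
    return pd.DataFrame(rows)
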