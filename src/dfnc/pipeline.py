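"""End-to-end orchestration: simulate -> prep -> FNC -> states -> inference.

Each stage writes its outputs under the run directory as plain text; the
run report (markdown + JSON) summarizes the chosen k, per-task state
metrics, between-task tests, and brain-behavior correlations. Reruns with
the same config and seed are numerically identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dfnc import io
from dfnc.cohort import (
    Cohort,
    SubjectRun,
    cohort_behavior_table,
    default_ground_truth,
    make_paradigm,
    simulate_cohort,
)
from dfnc.config import RunConfig
from dfnc.errors import DFNCError, InvalidInputError
from dfnc.inference import (
    dprime,
    ks_normality,
    partial_corr_behavior,
    permutation_mean_diff,
    state_edge_paired_t,
    state_mean_fnc,
)
from dfnc.prep import (
    NuisanceModel,
    build_nuisance,
    detrend_lowpass,
    framewise_displacement,
    regress_out,
)
from dfnc.states import StateModel, fit_states, metrics_table
from dfnc.windows import (
    WindowedFNC,
    make_taper,
    sliding_window_fnc,
    window_majority_labels,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    config: RunConfig
    out_dir: Path
    cohort: Cohort | None
    windows: dict[tuple[str, str], WindowedFNC]
    model: StateModel
    labels_by_run: dict[tuple[str, str], np.ndarray]
    metrics: pd.DataFrame
    behavior: pd.DataFrame | None
    tests: dict = field(default_factory=dict)
    true_window_labels: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


def _prep_run(run: SubjectRun, paradigm, config: RunConfig) -> tuple[np.ndarray, float]:
    """Drop dummies, regress nuisance, detrend + low-pass; returns the clean
    series and the run's mean framewise displacement."""
    data = run.data[config.n_drop :]
    motion = run.motion
    if config.regress_nuisance:
        model = build_nuisance(paradigm, motion, config.tr, motion.shape[0])
        cropped = NuisanceModel(
            regressors=model.regressors[config.n_drop :], labels=model.labels
        )
        data = regress_out(data, cropped)
    data = detrend_lowpass(data, config.tr, cutoff=config.lowpass_cutoff)
    fd = framewise_displacement(motion[config.n_drop :], radius=config.head_radius)
    return data, float(fd.mean())


def _load_runs(config: RunConfig) -> list[SubjectRun]:
    base = Path(config.input_dir)
    if not base.exists():
        raise InvalidInputError(f"input directory not found: {base}")
    runs = []
    for ts_path in sorted(base.glob("*_timeseries.tsv")):
        stem = ts_path.name.replace("_timeseries.tsv", "")
        subject, _, task = stem.rpartition("_")
        motion_path = base / f"{stem}_motion.txt"
        data = io.read_timeseries(ts_path).to_numpy()
        motion = (
            io.read_motion(motion_path)
            if motion_path.exists()
            else np.zeros((data.shape[0], 6))
        )
        runs.append(
            SubjectRun(
                subject=subject,
                task=task,
                data=data,
                tr=config.tr,
                motion=motion,
                state_labels=np.zeros(data.shape[0], dtype=np.int64),
            )
        )
    if not runs:
        raise InvalidInputError(f"no *_timeseries.tsv files found in {base}")
    return runs


def run_pipeline(config: RunConfig, out_dir: str | Path) -> PipelineResult:
    """Execute every enabled stage and write all outputs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.write(out / "config.yaml")
    stage = "simulate"
    try:
        paradigm = make_paradigm(tr=config.tr)
        cohort = None
        if config.simulate:
            gt = default_ground_truth(
                n_components=config.n_components,
                n_states=config.n_states_true,
                self_transition=config.self_transition,
                behavior_coupling=config.behavior_coupling,
                seed=config.seed,
            )
            cohort = simulate_cohort(
                n_subjects=config.n_subjects,
                paradigm=paradigm,
                ground_truth=gt,
                n_trials=config.n_trials,
                seed=config.seed,
            )
            io.write_cohort(out / "sim", cohort)
            runs = cohort.runs
        else:
            runs = _load_runs(config)

        stage = "prep"
        clean: dict[tuple[str, str], np.ndarray] = {}
        mean_fd: dict[tuple[str, str], float] = {}
        for run in runs:
            data, fd = _prep_run(run, paradigm, config)
            clean[(run.subject, run.task)] = data
            mean_fd[(run.subject, run.task)] = fd

        stage = "fnc"
        taper = make_taper(config.window_length, config.sigma)
        windows: dict[tuple[str, str], WindowedFNC] = {}
        true_win: dict[tuple[str, str], np.ndarray] = {}
        fnc_dir = out / "fnc"
        fnc_dir.mkdir(exist_ok=True)
        for (subject, task), data in clean.items():
            wfnc = sliding_window_fnc(
                data,
                taper,
                step=config.step,
                tr=config.tr,
                subject=subject,
                task=task,
                fisher_z=config.fisher_z,
            )
            windows[(subject, task)] = wfnc
            io.write_windowed_fnc(fnc_dir / f"{subject}_{task}_fnc.tsv", wfnc)
        if cohort is not None:
            for run in runs:
                true_win[(run.subject, run.task)] = window_majority_labels(
                    run.state_labels[config.n_drop :], taper, config.step
                )

        stage = "states"
        keys = sorted(windows)
        pooled = np.vstack([windows[key].values for key in keys])
        model = fit_states(
            pooled,
            k=config.k,
            k_range=config.k_range,
            max_iter=config.max_iter,
            n_replicates=config.n_replicates,
            seed=config.seed,
        )
        labels_by_run: dict[tuple[str, str], np.ndarray] = {}
        offset = 0
        for key in keys:
            n = windows[key].n_windows
            labels_by_run[key] = model.labels[offset : offset + n]
            offset += n
        metrics = metrics_table(labels_by_run, model.k)
        metrics["mean_fd"] = [mean_fd[(r.subject, r.task)] for r in metrics.itertuples()]
        _write_states(out, model, labels_by_run, metrics)

        stage = "behavior"
        behavior = None
        if cohort is not None:
            behavior = cohort_behavior_table(cohort)
        elif (Path(config.input_dir or ".") / "behavior.tsv").exists():
            behavior = pd.read_csv(Path(config.input_dir) / "behavior.tsv", sep="\t")
            behavior["d_prime"] = [
                dprime(r.hits, r.n_signal_trials, r.false_alarms, r.n_noise_trials)
                for r in behavior.itertuples()
            ]

        stage = "inference"
        tests = _run_inference(config, model, windows, labels_by_run, metrics, behavior)

        result = PipelineResult(
            config=config,
            out_dir=out,
            cohort=cohort,
            windows=windows,
            model=model,
            labels_by_run=labels_by_run,
            metrics=metrics,
            behavior=behavior,
            tests=tests,
            true_window_labels=true_win,
        )
        stage = "report"
        from dfnc.report import write_report

        write_report(result)
        return result
    except DFNCError:
        logger.exception("pipeline failed in stage %r", stage)
        raise
    except Exception:
        logger.exception("pipeline failed in stage %r", stage)
        raise


def _write_states(out: Path, model: StateModel, labels_by_run, metrics) -> None:
    states_dir = out / "states"
    states_dir.mkdir(exist_ok=True)
    pd.DataFrame(
        model.centroids, index=[f"state_{s + 1}" for s in range(model.k)]
    ).to_csv(states_dir / "centroids.tsv", sep="\t", float_format="%.10g")
    rows = []
    for (subject, task), labels in sorted(labels_by_run.items()):
        for w_idx, lab in enumerate(labels):
            rows.append((subject, task, w_idx, int(lab) + 1))
    pd.DataFrame(rows, columns=["subject", "task", "window", "state"]).to_csv(
        states_dir / "labels.tsv", sep="\t", index=False
    )
    metrics.to_csv(states_dir / "metrics.tsv", sep="\t", index=False)
    if model.validity:
        pd.DataFrame(
            {"k": list(model.validity), "ratio": list(model.validity.values())}
        ).to_csv(states_dir / "validity_curve.tsv", sep="\t", index=False)


def _run_inference(
    config: RunConfig,
    model: StateModel,
    windows: dict[tuple[str, str], WindowedFNC],
    labels_by_run: dict[tuple[str, str], np.ndarray],
    metrics: pd.DataFrame,
    behavior: pd.DataFrame | None,
) -> dict:
    tasks = sorted(metrics["task"].unique())
    tests: dict = {"metric_permutation": {}, "edge_paired_t": {}, "behavior": {},
                   "normality": {}}
    if len(tasks) != 2:
        logger.warning("inference needs exactly 2 tasks, found %s; skipped", tasks)
        return tests
    a_rows = metrics[metrics["task"] == tasks[0]]
    b_rows = metrics[metrics["task"] == tasks[1]]

    measure_cols = ["n_transitions"] + [f"dwell_{s + 1}" for s in range(model.k)]
    rng = np.random.default_rng(config.seed)
    for col in measure_cols:
        res = permutation_mean_diff(
            a_rows[col].to_numpy(),
            b_rows[col].to_numpy(),
            n_permutations=config.n_permutations,
            seed=rng,
            sidedness=config.permutation_sidedness,
        )
        tests["metric_permutation"][col] = {
            "statistic": res.statistic,
            "p": res.p_value,
            "n_permutations": res.n_permutations,
        }
        try:
            ks = ks_normality(metrics[col].to_numpy())
            tests["normality"][col] = {"statistic": ks.statistic, "p": ks.p_value}
        except InvalidInputError:
            pass

    for s in range(model.k):
        means_a = {}
        means_b = {}
        for (subject, task), wfnc in windows.items():
            m = state_mean_fnc(wfnc.values, labels_by_run[(subject, task)], s)
            if m is None:
                continue
            (means_a if task == tasks[0] else means_b)[subject] = m
        table = state_edge_paired_t(means_a, means_b, alpha=config.alpha)
        if table is not None:
            tests["edge_paired_t"][f"state_{s + 1}"] = {
                "n_pairs": int(table["n_pairs"].iloc[0]),
                "n_significant": int(table["reject"].sum()),
                "min_q": float(table["q"].min()),
            }

    if behavior is not None and "mean_fd" in metrics.columns:
        merged = metrics.merge(
            behavior[["subject", "task", "d_prime"]], on=["subject", "task"]
        )
        for task in tasks:
            sub = merged[merged["task"] == task]
            if len(sub) < 4:
                continue
            for col in measure_cols:
                try:
                    res = partial_corr_behavior(
                        sub[col].to_numpy(),
                        sub["d_prime"].to_numpy(),
                        sub["mean_fd"].to_numpy(),
                    )
                except InvalidInputError as exc:
                    logger.warning("partial correlation skipped (%s, %s): %s", task, col, exc)
                    continue
                tests["behavior"][f"{task}:{col}"] = {
                    "r": res.r,
                    "t": res.statistic,
                    "p": res.p_value,
                    "df": res.df,
                }
    return tests
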