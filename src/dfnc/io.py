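"""Plain-text readers/writers for every pipeline artifact.

Dialects: time series as TSV (rows = TRs, columns = named components);
motion as 6-column whitespace text (realignment-parameter dialect);
paradigm as onset/duration/condition TSV; behavior as TSV; ground truth and
run summaries as JSON; windowed FNC as TSV plus a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dfnc.cohort import Cohort, GroundTruth, Paradigm
from dfnc.windows import Taper, WindowedFNC, edge_labels

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_motion",
    "read_motion",
    "write_paradigm",
    "write_ground_truth",
    "read_ground_truth",
    "write_windowed_fnc",
    "read_windowed_fnc",
    "write_cohort",
    "read_nifti_timeseries",
]


def write_timeseries(path: str | Path, data: np.ndarray, names: list[str] | None = None) -> None:
    data = np.asarray(data)
    if names is None:
        names = [f"comp_{i + 1}" for i in range(data.shape[1])]
    pd.DataFrame(data, columns=names).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_motion(path: str | Path, motion: np.ndarray) -> None:
    np.savetxt(path, np.asarray(motion), fmt="%.10e")


def read_motion(path: str | Path) -> np.ndarray:
    motion = np.loadtxt(path)
    if motion.ndim == 1:
        motion = motion[None, :]
    return motion


def write_paradigm(path: str | Path, paradigm: Paradigm) -> None:
    paradigm.onsets().to_csv(path, sep="\t", index=False)


def write_ground_truth(path: str | Path, gt: GroundTruth) -> None:
    payload = {
        "state_covariances": gt.state_covariances.tolist(),
        "transition_matrix": gt.transition_matrix.tolist(),
        "task_amplitude": gt.task_amplitude,
        "noise_sd": gt.noise_sd,
        "behavior_coupling": gt.behavior_coupling,
        "behavior_latent_sd": gt.behavior_latent_sd,
        "d_prime_base": gt.d_prime_base,
        "coupled_state": gt.coupled_state,
        "task_components": list(gt.task_components),
        "target_fd": gt.target_fd,
        "rest_state": gt.rest_state,
        "seed": gt.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    payload["state_covariances"] = np.asarray(payload["state_covariances"])
    payload["transition_matrix"] = np.asarray(payload["transition_matrix"])
    payload["task_components"] = tuple(payload["task_components"])
    return GroundTruth(**payload)


def write_windowed_fnc(path: str | Path, wfnc: WindowedFNC) -> None:
    """TSV of edge values (one row per window) plus a `.json` sidecar with
    the window parameters and identity."""
    path = Path(path)
    labels = edge_labels(wfnc.n_components)
    df = pd.DataFrame(wfnc.values, columns=labels)
    df.insert(0, "window_start", wfnc.window_starts)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = {
        "window_length": wfnc.taper.window_length,
        "sigma": wfnc.taper.sigma,
        "step": wfnc.step,
        "tr": wfnc.tr,
        "subject": wfnc.subject,
        "task": wfnc.task,
        "n_components": wfnc.n_components,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_windowed_fnc(path: str | Path) -> WindowedFNC:
    from dfnc.windows import make_taper

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    taper = make_taper(sidecar["window_length"], sidecar["sigma"])
    return WindowedFNC(
        values=df.drop(columns=["window_start"]).to_numpy(),
        window_starts=df["window_start"].to_numpy(),
        n_components=sidecar["n_components"],
        taper=taper,
        step=sidecar["step"],
        tr=sidecar["tr"],
        subject=sidecar["subject"],
        task=sidecar["task"],
    )


def write_cohort(out_dir: str | Path, cohort: Cohort) -> None:
    """Write the full synthetic cohort in the plain-text dialects above."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_paradigm(out / "paradigm.tsv", cohort.paradigm)
    write_ground_truth(out / "ground_truth.json", cohort.ground_truth)
    cohort.behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
    for run in cohort.runs:
        stem = f"{run.subject}_{run.task}"
        if run.data.size:
            write_timeseries(out / f"{stem}_timeseries.tsv", run.data)
        write_motion(out / f"{stem}_motion.txt", run.motion)
        np.savetxt(out / f"{stem}_true_states.tsv", run.state_labels[None].T, fmt="%d")


def read_nifti_timeseries(path: str | Path, mask: np.ndarray | None = None) -> np.ndarray:
    """Load a 4-D NIfTI as a time x voxels matrix (requires nibabel)."""
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover
        raise ImportError("NIfTI support requires the optional nibabel dependency") from exc
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D NIfTI, got shape {data.shape}")
    flat = data.reshape(-1, data.shape[-1]).T  # (T, voxels)
    if mask is not None:
        flat = flat[:, np.asarray(mask, dtype=bool).ravel()]
    return flat
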