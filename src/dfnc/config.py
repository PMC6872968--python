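"""Run configuration: every numeric parameter of the pipeline in one place,
serialized verbatim into the run outputs for provenance."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from dfnc.errors import InvalidConfigError


@dataclass
class RunConfig:
    # data source
    simulate: bool = True
    input_dir: str | None = None
    n_subjects: int = 20
    n_components: int = 14
    n_states_true: int = 4
    n_trials: int = 96
    behavior_coupling: float = 0.58
    self_transition: float = 0.985

    # ingestion / prep
    tr: float = 2.0
    n_drop: int = 4
    lowpass_cutoff: float = 0.1
    head_radius: float = 50.0
    regress_nuisance: bool = True

    # optional group ICA stage (voxel-level inputs only)
    use_ica: bool = False
    n1: int = 27
    n2: int = 18
    ica_runs: int = 10

    # windowing
    window_length: int = 20
    sigma: float = 3.0
    step: int = 1
    fisher_z: bool = False

    # state clustering
    k: int | None = None
    k_min: int = 2
    k_max: int = 10
    max_iter: int = 150
    n_replicates: int = 20

    # inference
    n_permutations: int = 10_000
    alpha: float = 0.05
    permutation_sidedness: str = "two-sided"
    paired_tasks: bool = False

    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise InvalidConfigError(f"tr must be positive, got {self.tr}")
        if self.n_drop < 0:
            raise InvalidConfigError(f"n_drop must be >= 0, got {self.n_drop}")
        if self.window_length < 3:
            raise InvalidConfigError("window_length must be >= 3")
        if self.step < 1:
            raise InvalidConfigError("step must be >= 1")
        if not 2 <= self.k_min < self.k_max:
            raise InvalidConfigError("need 2 <= k_min < k_max")
        if self.k is not None and self.k < 1:
            raise InvalidConfigError("k must be >= 1 when given")
        if not 0 < self.alpha < 1:
            raise InvalidConfigError("alpha must lie in (0, 1)")
        if self.n_permutations < 100:
            raise InvalidConfigError("n_permutations must be >= 100")
        if not self.simulate and not self.input_dir:
            raise InvalidConfigError("input_dir is required when simulate is off")

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise InvalidConfigError(f"config file not found: {path}")
        text = path.read_text()
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(payload or {})

    def write(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
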