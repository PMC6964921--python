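"""Run configuration: layered JSON overrides and a resolved-config hash.

Defaults collect the study constants in one place (dt = 150 ms, 750 deg/s^2
acceleration threshold, 50 Hz filter cutoff, 400 ms saccade window, 175 ms
early/late cutoff, 100 ms pre-saccadic lead, 50 ms step window) next to the
model and dataset parameters.  Resolution order: built-in defaults < config
file < explicit overrides.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .synthesis import DatasetConfig
from .trace_analysis import AnalysisConfig
from .trigger_model import ModelParams, NoiseModel


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    mode: str = "model"  # model | scripted
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    model: ModelParams = field(default_factory=ModelParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _build(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Resolve a RunConfig from defaults, an optional JSON file, and overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = json.load(fh)
    if overrides:
        for key, val in overrides.items():
            if isinstance(val, dict):
                data.setdefault(key, {}).update(val)
            else:
                data[key] = val
    noise = _build(NoiseModel, data.get("model", {}).pop("noise", {}) or {})
    model = _build(ModelParams, {**data.get("model", {}), "noise": noise})
    return RunConfig(
        seed=int(data.get("seed", 0)),
        mode=data.get("mode", "model"),
        dataset=_build(DatasetConfig, data.get("dataset", {})),
        model=model,
        analysis=_build(AnalysisConfig, data.get("analysis", {})),
    )


def save_config(config: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=1, sort_keys=True)
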