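"""Structured run configuration with strict key validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Parameters of a full synthetic pipeline run.

    Unknown keys are rejected on load; the config round-trips losslessly
    through YAML.
    """

    # stages to execute, in order
    stages: list = field(default_factory=lambda: ["series", "fit", "model"])
    seed: int = 1
    out_dir: str = "escapewatch_run"

    # model parameters
    load: float = 0.281
    escape_rate: float = 2.1e-7
    ref_growth: float = 1.0

    # stability-series generation / fitting
    generations: list = field(default_factory=lambda: [14, 22, 30, 38, 46, 54, 62, 70, 78])
    noise_sd: float = 0.03
    n_reps: int = 5
    observable_kind: str = "relative_titer"
    free_parameters: list = field(default_factory=lambda: ["load", "escape_rate"])

    # sequencing emulation / scan
    depth: float = 1500.0
    read_len: int = 150
    error_rate: float = 0.003
    timepoint: float = 53.0
    min_support: int = 3

    # growth stage
    growth_rate: float = 0.84
    od_noise_sd: float = 0.02

    def validate(self) -> "RunConfig":
        known_stages = {"series", "fit", "model", "reads", "scan", "growth"}
        unknown = set(self.stages) - known_stages
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load a YAML config, rejecting unknown keys."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return RunConfig(**data).validate()


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
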