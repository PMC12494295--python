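"""Run configuration: strict JSON schema with defaults and round-tripping.

Unknown keys are rejected; every physical quantity carries its unit in
the key name.  ``save(load(x)) == load(x)`` holds for any valid file.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "SimulationSection", "load_config", "save_config"]

_EXPERIMENTS = ("ttx", "block_async", "block_burst", "random_pool",
                "benchmark_sparse", "benchmark_synchronous",
                "benchmark_surrogate")


class SimulationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    grid_step_ms: float = Field(0.1, gt=0)
    duration_ms: float = Field(20000.0, gt=0)
    warmup_ms: float = Field(2000.0, ge=0)
    record_interval_ms: float = Field(10.0, gt=0)
    integrator_tol: float = Field(1e-6, gt=0)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    experiment: str
    master_seed: int = 1
    output_dir: str = "runs"
    log_level: str = "INFO"
    benchmark_scale: float = Field(0.1, gt=0)
    simulation: SimulationSection = Field(default_factory=SimulationSection)

    def model_post_init(self, _ctx) -> None:
        if self.experiment not in _EXPERIMENTS:
            raise ValueError(
                f"experiment must be one of {_EXPERIMENTS}, got "
                f"{self.experiment!r}")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = json.load(fh)
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.model_dump(), fh, indent=2)
        fh.write("\n")
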