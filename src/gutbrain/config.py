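"""Run configuration schema and reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__

__all__ = ["RunConfig", "write_manifest"]


class ParetoSettings(BaseModel):
    max_iterations: int = Field(100, gt=0)
    tolerance: float = Field(1e-6, gt=0)


class CouplingSettings(BaseModel):
    dt_hours: float = Field(0.25, gt=0)
    horizon_hours: float = Field(6.0, gt=0)
    initial_concentration: float = Field(1e-4, ge=0)

    @field_validator("horizon_hours")
    @classmethod
    def _divisible(cls, v, info):
        dt = info.data.get("dt_hours", 0.25)
        n = v / dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("dt_hours must divide horizon_hours evenly")
        return v


class RunConfig(BaseModel):
    """Validated configuration of a full pipeline run.

    ``fixtures`` as a model path means "generate the toy fixture set".
    """

    members: list[str] | Literal["fixtures"] = "fixtures"
    host: str | Literal["fixtures"] = "fixtures"
    brain: str | Literal["fixtures"] = "fixtures"
    diet: str = "high_fiber"
    beneficial_percent: float = Field(20.0, ge=0, le=100)
    pareto: ParetoSettings = ParetoSettings()
    pbpk_parameters: str | Literal["fixtures"] = "fixtures"
    coupling: CouplingSettings = CouplingSettings()
    output_dir: str = "gutbrain_out"
    log_level: str = "INFO"
    solver: str = "glpk"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(config: RunConfig, output_dir: str | Path) -> Path:
    """Write a manifest sufficient to reproduce the run."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "gutbrain",
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": config.model_dump(),
        "solver": config.solver,
        "seed": config.seed,
        "python": platform.python_version(),
    }
    path = output_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
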