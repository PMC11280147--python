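"""Run configuration: validated settings for the CLI pipeline (YAML or JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator


class CircuitConfig(BaseModel):
    """Fixed circuit elements shared by every patient's calibration."""

    r_svc: float = Field(0.0, ge=0, description="series SVC+junction resistance, WU*m^2")
    r_lpa_vessel: float = Field(0.0, ge=0)
    r_rpa_vessel: float = Field(0.0, ge=0)
    distal_pressure_column: str = "p_la"


class OptimizerConfig(BaseModel):
    tol: float = Field(1e-4, gt=0)
    max_evals: int = Field(2000, gt=0)
    penalty: float = Field(1e6, gt=0)
    init: tuple[float, float] | None = None  # None -> cohort initial guess


class SyntheticConfig(BaseModel):
    """Waveform stand-in settings used when no measured waveforms are given."""

    cycle_length: float = Field(0.8, gt=0, description="cardiac cycle length, s")
    dt: float = Field(0.001, gt=0, description="timestep, s")
    pulsatility: float = Field(0.3, ge=0, lt=1)
    noise: float = Field(0.0, ge=0, description="branch-flow noise SD as fraction of mean")
    seed: int = 0


class RunConfig(BaseModel):
    table: str = "bundled"
    waveform_dir: str | None = None
    out_dir: str = "glennpvr_out"
    circuit: CircuitConfig = CircuitConfig()
    optimizer: OptimizerConfig = OptimizerConfig()
    synthetic: SyntheticConfig = SyntheticConfig()

    @field_validator("table")
    @classmethod
    def _table_exists(cls, v: str) -> str:
        if v != "bundled" and not Path(v).exists():
            raise ValueError(f"patient table not found: {v}")
        return v


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON) run configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    return RunConfig.model_validate(data or {})


def default_config_yaml() -> str:
    """All defaults, as YAML — what --show-config prints."""
    return yaml.safe_dump(RunConfig().model_dump(), sort_keys=False)
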