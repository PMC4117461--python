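"""Run configuration: validation, file loading and named fixtures.

Configurations are flat-ish JSON or YAML documents validated with pydantic;
unknown keys are rejected at every level.  Two named fixtures ship with the
package: ``fig2`` (the reference constant set, p = 1.0253) and
``fig2-panels`` (the eight swept supply levels).
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .model import ModelParameters, fig2_parameters, FIG2_PANEL_P
from .simulate import SolverSettings

__all__ = ["RunConfig", "load_config", "fixture", "FIXTURES"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
    D1: float = 0.28
    D4: float = 156.0
    D5: float = 156.0
    k2: float = 0.00034580
    a: float = 800.0
    b: float = 656.0
    c: float = 100.0
    d: float = 100.0
    e: float = 100.0
    f: float = 100.0
    p: float = 1.0253
    R: float = 1.0

    def to_params(self) -> ModelParameters:
        return ModelParameters(**self.model_dump()).validate()


class SolverSection(_Strict):
    t_end: float = 2000.0
    sample_dt: float = 0.1
    rtol: float = 1e-8
    atol: float = 1e-10
    max_steps: int = 50000
    method: str = "LSODA"

    def to_settings(self) -> SolverSettings:
        return SolverSettings(**self.model_dump()).validate()


class AnalysisSection(_Strict):
    window: tuple[float, float] = (50.0, 1000.0)
    variable: str = "x"
    prominence_frac: float = 0.05
    sustained_ratio: float = 0.25
    init: tuple[float, float] = (1e-6, 1e-6)

    @field_validator("variable")
    @classmethod
    def _check_var(cls, v):
        if v not in ("x", "z"):
            raise ValueError("variable must be 'x' or 'z'")
        return v


class ScanSection(_Strict):
    p_list: list[float] | None = None
    eps_min: float = 0.01
    eps_max: float = 0.25
    points: int = 12
    bracket: tuple[float, float] = (0.795, 0.81)
    resolution: float = 1e-3
    p_c: float | None = None  # None: use the simulation/bisection estimate


class StabilitySection(_Strict):
    p_c: float = 0.8
    order: tuple[int, int] = (2, 1)
    alt_order: tuple[int, int] | None = (3, 1)
    eps_hi: float = 0.25
    eps_lo: float = 1e-8
    rel_tol: float = 1e-3
    n_branch: int = 61


class RunConfig(_Strict):
    """Top-level configuration tying all modules together."""

    model: ModelSection = Field(default_factory=ModelSection)
    solver: SolverSection = Field(default_factory=SolverSection)
    analysis: AnalysisSection = Field(default_factory=AnalysisSection)
    scan: ScanSection = Field(default_factory=ScanSection)
    stability: StabilitySection = Field(default_factory=StabilitySection)

    def resolved(self) -> dict:
        """Fully-resolved dict for provenance embedding in outputs."""
        return self.model_dump(mode="json")


def load_config(path) -> RunConfig:
    """Load and validate a JSON or YAML configuration file."""
    text = Path(path).read_text()
    suffix = Path(path).suffix.lower()
    if suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(data)}")
    return RunConfig.model_validate(data)


def fixture(name: str) -> RunConfig:
    """A named in-package configuration fixture."""
    if name == "fig2":
        return RunConfig()
    if name == "fig2-panels":
        cfg = RunConfig()
        cfg.scan.p_list = list(FIG2_PANEL_P)
        return cfg
    raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")


FIXTURES = ("fig2", "fig2-panels")

# re-export for convenience: the underlying parameter preset
fig2 = fig2_parameters
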