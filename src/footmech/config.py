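"""Scenario configuration: validated schema with documented defaults.

A scenario file (YAML or JSON) describes one simulation end to end:
synthetic geometry parameters, axial load, flatfoot attenuation factor,
optional reconstruction method, muscle activation table and solver
settings.  Validation happens before any computation.
"""

from __future__ import annotations

import json
import pathlib
from typing import Literal, Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .assembly import DEFAULT_MUSCLE_FRACTIONS, ModelOptions
from .geometry import GeometryParams
from .solver import SolverSettings

__all__ = ["GeometryConfig", "SolverConfig", "ScenarioConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid scenario configuration."""


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    foot_length: float = Field(250.0, gt=0, description="foot length, mm")
    arch_height: float = Field(45.0, ge=0, description="navicular height, mm")
    hindfoot_alignment: float = Field(0.0, description="coronal pre-tilt, deg (+valgus)")
    scale: float = Field(1.0, gt=0)
    random_seed: int = 0
    perturbation_sd: float = Field(0.0, ge=0, description="landmark jitter SD, mm")

    def to_params(self) -> GeometryParams:
        return GeometryParams(**self.model_dump())


class SolverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    residual_tol: float = Field(1e-3, gt=0, description="generalized residual, N")
    char_length: float = Field(100.0, gt=0, description="torque scaling length, mm")
    max_iterations: int = Field(500, ge=1)
    hessian_fd_step: float = Field(1e-6, gt=0)
    ramp_steps: int = Field(6, ge=1)
    trust_init: float = Field(1.0, gt=0)
    trust_max: float = Field(8.0, gt=0)

    def to_settings(self) -> SolverSettings:
        return SolverSettings(**self.model_dump())


class ScenarioConfig(BaseModel):
    """One simulated condition (validated before any compute)."""

    model_config = ConfigDict(extra="forbid")

    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    load: float = Field(680.0, ge=0, description="axial load through the tibia, N")
    attenuation_factor: float = Field(0.5, gt=0, le=1)
    condition: Literal["intact", "flatfoot"] = "flatfoot"
    reconstruction: Literal["none", "ISLR", "ASLR", "CSILR", "CSPLR"] = "none"
    muscles: Optional[dict[str, float]] = Field(
        None,
        description="muscle name -> constant force as fraction of the axial "
        "load; omitted = package defaults, {} = muscle-free",
    )
    solver: SolverConfig = Field(default_factory=SolverConfig)
    output_dir: str = "results"
    seed: Optional[int] = Field(None, description="overrides geometry.random_seed")

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        if self.reconstruction != "none" and self.condition != "flatfoot":
            raise ValueError("a reconstruction requires the flatfoot condition")
        if self.muscles:
            unknown = set(self.muscles) - set(DEFAULT_MUSCLE_FRACTIONS)
            if unknown:
                raise ValueError(f"unknown muscles in config: {sorted(unknown)}")
        return self

    def geometry_params(self) -> GeometryParams:
        params = self.geometry.to_params()
        if self.seed is not None:
            params = GeometryParams(
                foot_length=params.foot_length,
                arch_height=params.arch_height,
                hindfoot_alignment=params.hindfoot_alignment,
                scale=params.scale,
                random_seed=self.seed,
                perturbation_sd=params.perturbation_sd,
            )
        return params

    def model_options(self) -> ModelOptions:
        return ModelOptions(muscle_fractions=self.muscles)

    def solver_settings(self) -> SolverSettings:
        return self.solver.to_settings()


def load_config(path) -> ScenarioConfig:
    """Load and validate a YAML or JSON scenario file."""
    path = pathlib.Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: expected a mapping at top level")
    try:
        return ScenarioConfig(**data)
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc
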