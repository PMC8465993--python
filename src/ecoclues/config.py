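"""Run configuration: schema-validated YAML, unknown keys rejected."""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SceneConfig(_Strict):
    n_rows: int = 100
    n_cols: int = 100
    cell_size_km: float = 1.0
    spatial_smoothness: float = 5.0
    noise_amplitude: float = 0.1
    n_settlements: int = 4
    n_roads: int = 3
    n_rivers: int = 2
    n_species: int = 5
    urban_growth_cells: int = 150  # cells converted for the second-date map
    logistic_coefficients: dict[int, dict[str, float]] | None = None


class DemandConfig(_Strict):
    start_year: int = 2015
    horizon_year: int = 2025
    step_years: int = 5
    # wetland (class 3) outflow frozen by default, consistent with its
    # elasticity of 1 (strictly protected water bodies)
    outflow_modifiers: dict[int, float] = Field(default_factory=lambda: {3: 0.0})
    inflow_modifiers: dict[int, float] = Field(default_factory=dict)


class AllocationConfig(_Strict):
    elasticity: dict[int, float] = Field(
        default_factory=lambda: {1: 0.6, 2: 0.6, 3: 1.0, 4: 0.4, 5: 0.9, 6: 0.3}
    )
    tolerance_frac: float = 0.001
    max_iterations: int = 1000
    step_size: float = 0.05


class PathsConfig(_Strict):
    scene_dir: str | None = None
    landuse_t0: str | None = None
    landuse_t1: str | None = None
    models: str | None = None
    demand: str | None = None


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "ecoclues_out"
    scene: SceneConfig = Field(default_factory=SceneConfig)
    demand: DemandConfig = Field(default_factory=DemandConfig)
    allocation: AllocationConfig = Field(default_factory=AllocationConfig)
    grading_thresholds: tuple[float, float, float] = (0.35, 0.65, 0.85)
    runoff_coefficients: dict[int, float] = Field(
        default_factory=lambda: {1: 0.15, 2: 0.25, 3: 0.05, 4: 0.35, 5: 0.60, 6: 0.45}
    )
    paths: PathsConfig = Field(default_factory=PathsConfig)

    @field_validator("grading_thresholds")
    @classmethod
    def _ordered(cls, v):
        if not 0 < v[0] < v[1] < v[2] < 1:
            raise ValueError("grading thresholds must be strictly increasing in (0, 1)")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def digest(self) -> str:
        """Stable hash of the fully-resolved configuration (for run logs)."""
        canon = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
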