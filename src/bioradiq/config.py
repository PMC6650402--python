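"""Experiment configuration: schema-validated YAML with the study's defaults.

All defaults equal the published values where printed: plate constants
8770 / 1535 / 1024 / 1.25, 45-min exposures exchanged every 60 min for
405 min (7 frames), 0.04625 MBq / 0.5 mL medium activity, 5 mM glucose,
109.77 min 18F half-life.  Seeds are explicit: no wall-clock seeding.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import simulate
from .decay import NuclideSpec
from .plate import PlateCalibration
from .quantify import ExposureSchedule

__all__ = ["ExperimentConfig", "load_config", "config_hash", "ConfigError"]


class ConfigError(ValueError):
    """Invalid experiment configuration."""


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CalibrationConfig(_Base):
    dose_scale: float = Field(8770.0, gt=0)
    psl_offset: float = Field(1535.0, gt=0)
    psl_per_decade: float = Field(1024.0, gt=0)
    sensitivity_ratio: float = Field(1.25, ge=1)

    def build(self) -> PlateCalibration:
        return PlateCalibration(**self.model_dump())


class NuclideConfig(_Base):
    name: str = "F-18"
    half_life_min: float = Field(109.77, gt=0)

    def build(self) -> NuclideSpec:
        return NuclideSpec(**self.model_dump())


class ScheduleConfig(_Base):
    n_frames: int = Field(7, ge=1)
    interval_min: float = Field(60.0, gt=0)
    duration_min: float = Field(45.0, gt=0)
    start_min: float = 0.0

    def build(self) -> ExposureSchedule:
        return ExposureSchedule.regular(
            self.n_frames, self.interval_min, self.duration_min, self.start_min
        )


class ScenarioConfig(_Base):
    name: str = "fig3_glucose"
    n_replicates: Optional[int] = None
    replicate_cv: float = Field(0.15, ge=0)
    noise_scale: Optional[float] = Field(1.0, gt=0)
    medium_dose_rate_per_MBq: float = Field(6000.0, ge=0)
    mu_per_um: float = Field(0.0025, gt=0)
    psl_floor: float = Field(1.0, ge=0)

    def build(self, seed: int):
        if self.name not in simulate.SCENARIO_NAMES:
            raise ConfigError(
                f"scenario.name must be one of {simulate.SCENARIO_NAMES}, got {self.name!r}"
            )
        return simulate.scenario(
            self.name,
            seed=seed,
            n_replicates=self.n_replicates,
            replicate_cv=self.replicate_cv,
            noise_scale=self.noise_scale,
            medium_dose_rate_per_MBq=self.medium_dose_rate_per_MBq,
            mu_per_um=self.mu_per_um,
            psl_floor=self.psl_floor,
        )


class DosimetryConfig(_Base):
    activity_MBq: float = Field(0.04625, ge=0)
    biological_half_life_min: Optional[float] = Field(None, gt=0)  # None = pure physical decay
    energy_per_decay_J: float = Field(1.5e-16, ge=0)
    target_mass_kg: float = Field(1.1e-5, gt=0)
    radiation_weighting: float = Field(1.0, ge=0)
    tissue_weighting: float = Field(0.01, ge=0)


class StatsConfig(_Base):
    control_label: str = "control"
    alternative: str = "two-sided"
    max_exact: int = Field(10000, ge=1)
    n_permutations: int = Field(10000, ge=10000)


class ExperimentConfig(_Base):
    seed: int
    calibration: CalibrationConfig = CalibrationConfig()
    nuclide: NuclideConfig = NuclideConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    scenario: ScenarioConfig = ScenarioConfig()
    dosimetry: DosimetryConfig = DosimetryConfig()
    stats: StatsConfig = StatsConfig()


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment config; errors name the field."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        return ExperimentConfig.model_validate(raw)
    except ValidationError as exc:
        fields = ", ".join(".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors())
        raise ConfigError(f"invalid config {path}: problem with field(s): {fields}\n{exc}") from exc


def config_hash(config: ExperimentConfig) -> str:
    """Stable short hash of the full configuration, recorded in every output."""
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
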