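"""Run configuration, serialization, and reproducible test-fixture generation.

Configs are YAML (JSON accepted — YAML is a superset) with a versioned
schema; every stochastic run requires an explicit seed.  Validation errors
name the offending field path (pydantic).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .photophysics import ExcitationProfile, Fluorophore, get_fluorophore

__all__ = [
    "SCHEMA_VERSION",
    "ConfigError",
    "FluorophoreSpec",
    "ExcitationSpec",
    "ProtocolSpec",
    "ImagerSpec",
    "SimulationSpec",
    "RunConfig",
    "load_config",
    "save_config",
    "generate_fixtures",
]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid or unsupported configuration."""


class FluorophoreSpec(BaseModel):
    """Either a library reference (``name`` only) or inline parameters."""

    name: str
    epsilon: Optional[float] = Field(None, gt=0)
    quantum_yield: Optional[float] = Field(None, gt=0, le=1)
    lifetime: Optional[float] = Field(None, gt=0)
    bleach_rate: float = Field(0.0, ge=0)
    excitation_wavelength: Optional[float] = None
    emission_wavelength: Optional[float] = None

    def build(self) -> Fluorophore:
        if self.epsilon is None or self.quantum_yield is None or self.lifetime is None:
            fl = get_fluorophore(self.name)
            if self.bleach_rate:
                fl = fl.with_bleaching(self.bleach_rate)
            return fl
        return Fluorophore(
            name=self.name,
            epsilon=self.epsilon,
            quantum_yield=self.quantum_yield,
            lifetime=self.lifetime,
            bleach_rate=self.bleach_rate,
            excitation_wavelength=self.excitation_wavelength,
            emission_wavelength=self.emission_wavelength,
        )


class ExcitationSpec(BaseModel):
    segments: list[tuple[float, float]] = Field(min_length=1)
    shutoff_tail: Optional[float] = Field(None, gt=0)
    coupling: float = Field(1.0, ge=0)

    def build(self) -> ExcitationProfile:
        return ExcitationProfile(
            tuple(self.segments), shutoff_tail=self.shutoff_tail, coupling=self.coupling
        )


class ProtocolSpec(BaseModel):
    mode: Literal["cw", "tg"]
    t_int: float = Field(gt=0)
    gate_delay: float = Field(0.0, ge=0)
    shots: int = Field(1, ge=1)
    pulse_duration: Optional[float] = Field(None, gt=0)


class ImagerSpec(BaseModel):
    pixels: int = Field(100, ge=1)
    emission_coupling: float = Field(0.01, gt=0, le=1)
    excitation_coupling: float = Field(0.01, gt=0, le=1)
    qe_emission: float = Field(0.45, gt=0, le=1)
    qe_excitation: float = Field(0.45, gt=0, le=1)
    read_noise: float = Field(2.0, ge=0)
    dark_current: float = Field(5.0, ge=0)
    well_capacity: float = Field(50_000.0, gt=0)
    filter_od: float = Field(6.0, ge=0)
    excitation_tail: float = Field(50e-9, ge=0)


class SimulationSpec(BaseModel):
    n_total: int = Field(ge=1)
    t_end: float = Field(gt=0)
    trials: int = Field(1, ge=1)
    seed: Optional[int] = None
    grid_points: int = Field(200, ge=2)


class RunConfig(BaseModel):
    """Top-level run description tying all module inputs together."""

    schema_version: int = SCHEMA_VERSION
    fluorophore: FluorophoreSpec
    excitation: ExcitationSpec
    protocol: Optional[ProtocolSpec] = None
    imager: Optional[ImagerSpec] = None
    simulation: SimulationSpec
    stochastic: bool = False
    output_dir: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema_version {self.schema_version}; "
                f"this build reads version {SCHEMA_VERSION}"
            )
        if self.stochastic and self.simulation.seed is None:
            raise ValueError("stochastic runs require simulation.seed")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        raise ConfigError(str(err)) from err


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def generate_fixtures(kind: str, seed: int, out_dir: str | Path | None = None):
    """Reproducible synthetic inputs for property tests.

    kinds:
      ``random-fluorophore`` — valid random parameter sets spanning the
      library's five-decade lifetime range (1 ns – 1 ms);
      ``pulse-schedule`` — random piecewise-constant excitation schedules;
      ``poisson-times`` — homogeneous Poisson photon-time sets (the null
      model for PSD-estimator tests).

    Returns a DataFrame (or times array); when ``out_dir`` is given the
    fixture is also written there as CSV.
    """
    rng = np.random.default_rng(seed)
    if kind == "random-fluorophore":
        n = 20
        df = pd.DataFrame(
            {
                "name": [f"synthetic-{i:02d}" for i in range(n)],
                "epsilon": 10 ** rng.uniform(3, 5, n),
                "quantum_yield": rng.uniform(0.05, 1.0, n),
                "lifetime": 10 ** rng.uniform(-9, -3, n),
                "bleach_rate": np.where(rng.random(n) < 0.5, 0.0, 10 ** rng.uniform(0, 5, n)),
                "excitation_wavelength": rng.uniform(300, 600, n).round(0),
                "emission_wavelength": rng.uniform(400, 700, n).round(0),
            }
        )
        out = df
        fname = "random_fluorophores.csv"
    elif kind == "pulse-schedule":
        n_seg = int(rng.integers(2, 8))
        starts = np.sort(rng.uniform(0.0, 1e-4, n_seg))
        starts[0] = 0.0
        df = pd.DataFrame(
            {"start": starts, "flux": 10 ** rng.uniform(18, 23, n_seg)}
        )
        df.loc[df.index[-1], "flux"] = 0.0  # end dark
        out = df
        fname = "pulse_schedule.csv"
    elif kind == "poisson-times":
        rate, horizon = 1e5, 0.1
        n = rng.poisson(rate * horizon)
        times = np.sort(rng.uniform(0.0, horizon, n))
        out = pd.DataFrame({"time": times})
        fname = "poisson_times.csv"
    else:
        raise KeyError(f"unknown fixture kind {kind!r}")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out.to_csv(out_dir / fname, index=False)
    return out
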