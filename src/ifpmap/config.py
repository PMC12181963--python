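"""Run configuration for the CLI pipeline.

A single JSON or YAML file with per-stage sections; every referenced
module's preconditions are validated here, before any stage runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ensemble import NoiseModel
from .errors import ValidationError
from .partition import DEFAULT_HI, DEFAULT_LO, DEFAULT_N_CELLS, Partition

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    # partition
    lo: float = DEFAULT_LO
    hi: float = DEFAULT_HI
    n_cells: int = DEFAULT_N_CELLS
    # synthetic experiment
    map_kind: str = "random_semi_markov"
    skew_peak: float = 0.5
    n_cells_per_day: int = 20_000
    days: int = 5
    burn_in_steps: int = 50
    # dynamics noise
    noise_family: str = "none"
    noise_sigma: float = 0.0
    noise_boundary: str = "reflect"
    # inference
    ridge: float = 1e-6
    sigma_grid: tuple[float, ...] = ()
    # simulation
    n_simulate: int = 100_000
    carry_ensemble: bool = False
    # randomness
    seed: int = 0

    def __post_init__(self):
        if not self.hi > self.lo:
            raise ValidationError("partition: need hi > lo")
        if self.n_cells < 2:
            raise ValidationError("partition: need n_cells >= 2")
        if self.days < 2:
            raise ValidationError(
                "synth/infer stage: days must be >= 2 (at least one day pair)"
            )
        if self.n_cells_per_day < 1000:
            raise ValidationError("synth stage: n_cells_per_day must be >= 1000")
        if self.n_simulate < 1000:
            raise ValidationError("simulate stage: n_simulate must be >= 1000")
        if self.ridge < 0:
            raise ValidationError("infer stage: ridge must be >= 0")
        if any(s < 0 for s in self.sigma_grid):
            raise ValidationError("infer stage: sigma_grid values must be >= 0")
        # constructing the noise model validates family/sigma/boundary
        self.noise

    @property
    def partition(self) -> Partition:
        return Partition.uniform(self.lo, self.hi, self.n_cells)

    @property
    def noise(self) -> NoiseModel:
        return NoiseModel(
            family=self.noise_family,
            sigma=self.noise_sigma,
            boundary=self.noise_boundary,
        )

    def to_dict(self) -> dict:
        return {
            "lo": self.lo,
            "hi": self.hi,
            "n_cells": self.n_cells,
            "map_kind": self.map_kind,
            "skew_peak": self.skew_peak,
            "n_cells_per_day": self.n_cells_per_day,
            "days": self.days,
            "burn_in_steps": self.burn_in_steps,
            "noise_family": self.noise_family,
            "noise_sigma": self.noise_sigma,
            "noise_boundary": self.noise_boundary,
            "ridge": self.ridge,
            "sigma_grid": list(self.sigma_grid),
            "n_simulate": self.n_simulate,
            "carry_ensemble": self.carry_ensemble,
            "seed": self.seed,
        }


def load_config(path) -> RunConfig:
    """Load a RunConfig from JSON (``.json``) or YAML (anything else)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError("config file must hold a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "sigma_grid" in raw:
        raw["sigma_grid"] = tuple(raw["sigma_grid"])
    return RunConfig(**raw)
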