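"""Declarative pipeline configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # filtering / estimation
    min_obs: int = 12
    flow_unit: str = "m3s"  # default for observation rows without a unit
    days_per_year: float = 365.25
    # yield allocation
    yield_granularity: str = "per_region"  # or "per_level"
    constituents: tuple[str, ...] = ("POC", "DOC")
    # validation thresholds
    max_up_obs: int = 20
    min_down_obs: int = 30
    # synthetic-data scenario
    seed: int = 0
    n_units: int = 300
    n_stations: int = 25
    sigma: float = 0.3
    n_days: int = 3653
    # paths
    out_dir: str = "outputs"
    units_path: str = "outputs/units.csv"
    corrections_path: str | None = None
    stations_path: str = "outputs/stations.csv"
    observations_path: str = "outputs/observations.csv"

    def __post_init__(self) -> None:
        if self.min_obs < 1 or self.max_up_obs < 1 or self.min_down_obs < 1:
            raise ValueError("thresholds must be positive")
        if self.yield_granularity not in ("per_region", "per_level"):
            raise ValueError("yield_granularity must be per_region or per_level")
        if isinstance(self.constituents, list):
            self.constituents = tuple(self.constituents)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def out_path(self, name: str) -> Path:
        return Path(self.out_dir) / name
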