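"""Run configuration: a plain YAML key-value schema with validation.

The config captures everything a pipeline run needs — grid, record span,
fire-process and weather parameters, accounting thresholds, epochs and the
seed — and round-trips losslessly to file, so every reported number is
traceable to a (config, seed) pair.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "firetrends_run"

    # analysis grid (edges of the NW corner cell; degrees)
    nrows: int = 40
    ncols: int = 40
    lat_origin: float = -34.0
    lon_origin: float = 148.0
    cell_size: float = 0.01

    # fire process
    start_year: int = 1988
    end_year: int = 2019
    fire_probability: float = 0.03
    prescribed_mean_km2: float = 16.0
    prescribed_sd_km2: float = 4.0

    # monthly product
    month_weights: list[float] = field(
        # July..June; mass concentrated on the Austral spring/summer fire season
        default_factory=lambda: [0.02, 0.03, 0.08, 0.12, 0.17, 0.22, 0.18, 0.08, 0.04, 0.03, 0.02, 0.01]
    )
    double_burn_fraction: float = 0.01

    # weather / indices
    weather_shape: list[int] = field(default_factory=lambda: [8, 8])
    tmax_trend_per_decade: float = 0.3
    lightning_rate: float = 0.05
    fire_year_start_month: int = 7
    ffdi_thresholds: list[float] = field(default_factory=lambda: [25.0, 50.0])
    dry_lightning_mm: float = 2.5
    megafire_km2: float = 10_000.0
    epoch1: list[int] = field(default_factory=lambda: [1988, 2003])
    epoch2: list[int] = field(default_factory=lambda: [2004, 2019])

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError("start_year must be <= end_year")
        for name in ("cell_size", "dry_lightning_mm", "megafire_km2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(t <= 0 for t in self.ffdi_thresholds):
            raise ValueError("FFDI thresholds must be positive")
        if len(self.month_weights) != 12 or abs(sum(self.month_weights) - 1.0) > 1e-8:
            raise ValueError("month_weights must be 12 values summing to 1")
        if not 1 <= self.fire_year_start_month <= 12:
            raise ValueError("fire_year_start_month must be a month")
        e1, e2 = self.epoch1, self.epoch2
        if len(e1) != 2 or len(e2) != 2 or e1[0] > e1[1] or e2[0] > e2[1]:
            raise ValueError("epochs must be (first_year, last_year) pairs")
        if not (e1[1] < e2[0] or e2[1] < e1[0]):
            raise ValueError("epochs must not overlap")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return asdict(self)
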