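"""Synthetic fire histories, daily weather cubes and monthly burned rasters.

Every generator takes a single seed and derives independent substreams from
it with :class:`numpy.random.SeedSequence`, so reruns are bit-reproducible
and adding one generator never perturbs another. The defaults describe a
temperate-forest fire regime: rare per-pixel wildfire occurrence (annual
probability of a few percent, i.e. fire return intervals of decades), a
small stationary prescribed-burn program, and Austral seasonality with the
hottest, driest conditions in December–February.

The truth process allows at most one fire per pixel per year (the annual
resolution of agency fire histories); cells burning twice appear only in the
monthly satellite-product layer, where they exercise the union accounting
rule downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .burned_area import MonthlyBurnedGrid, fire_year_months
from .grids import GridSpec, cell_area_km2

__all__ = [
    "FireProcessParams",
    "FireHistoryStack",
    "WeatherCoupling",
    "simulate_fire_history",
    "VariableCycle",
    "WeatherGenParams",
    "simulate_weather",
    "simulate_monthly_burned",
]


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class WeatherCoupling:
    """Optional logistic link from an annual fire-weather index to fire odds.

    Per year t, log-odds(p_t) = log-odds(p) + coef * index[t]; with coef = 0
    or a zero index the history reduces to stationary Bernoulli(p).
    """

    coef: float
    annual_index: np.ndarray


@dataclass
class FireProcessParams:
    """Parameters of the pixelwise Bernoulli wildfire truth process."""

    shape: tuple[int, int] = (100, 100)
    start_year: int = 1930
    end_year: int = 2019
    p: float | np.ndarray = 0.02
    prescribed_mean_km2: float = 30.0
    prescribed_sd_km2: float = 7.0
    coupling: WeatherCoupling | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError("start_year must be <= end_year")
        p = np.asarray(self.p, dtype=float)
        if not np.all(np.isfinite(p)):
            raise ValueError("fire probability p must be finite")
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("fire probability p must lie in the open interval (0, 1)")
        if p.ndim == 2 and p.shape != self.shape:
            raise ValueError("p map shape does not match grid shape")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def p_map(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.p, dtype=float), self.shape).copy()


@dataclass
class FireHistoryStack:
    """Annual per-pixel fire occurrence with cause attribute.

    ``wildfire`` and ``prescribed`` are boolean arrays of shape
    (n_years, nrows, ncols); ``true_p`` carries the generating probability map
    for parameter-recovery tests (None for observational data).
    """

    years: np.ndarray
    wildfire: np.ndarray
    prescribed: np.ndarray | None = None
    grid: GridSpec | None = None
    true_p: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.wildfire = np.asarray(self.wildfire, dtype=bool)
        if np.any(np.diff(self.years) != 1):
            raise ValueError("history years must be consecutive (no gap years)")
        if self.wildfire.shape[0] != self.years.size:
            raise ValueError("wildfire stack and years length mismatch")
        if self.prescribed is not None:
            self.prescribed = np.asarray(self.prescribed, dtype=bool)
            if self.prescribed.shape != self.wildfire.shape:
                raise ValueError("prescribed stack shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.wildfire.shape[1:]

    @property
    def n_years(self) -> int:
        return self.years.size

    def year_index(self, year: int) -> int:
        idx = int(year) - int(self.years[0])
        if not 0 <= idx < self.n_years:
            raise ValueError(f"year {year} outside record {self.years[0]}..{self.years[-1]}")
        return idx


def simulate_fire_history(params: FireProcessParams) -> FireHistoryStack:
    """Simulate an annual wildfire + prescribed-burn history.

    Wildfire occurrences are independent Bernoulli(p) per pixel-year unless a
    weather coupling modulates the annual probability. Prescribed burns are a
    separate stationary process: each year a target area is drawn (normal,
    truncated at zero) and converted to a random cell set of matching count.
    """
    rng_wild, rng_presc = _substreams(params.seed, 2)
    ny = params.n_years
    p_map = params.p_map

    if params.coupling is not None:
        idx = np.asarray(params.coupling.annual_index, dtype=float)
        if idx.size != ny:
            raise ValueError("coupling annual_index length must equal the record length")
        logit = np.log(p_map / (1.0 - p_map))
        p_t = 1.0 / (1.0 + np.exp(-(logit[None] + params.coupling.coef * idx[:, None, None])))
    else:
        p_t = np.broadcast_to(p_map, (ny, *params.shape))
    wildfire = rng_wild.random((ny, *params.shape)) < p_t

    # prescribed burns: nominal 1 km2 cells unless a grid supplies real areas
    mean_cell = 1.0
    n_cells_total = params.shape[0] * params.shape[1]
    prescribed = np.zeros((ny, *params.shape), dtype=bool)
    if params.prescribed_mean_km2 > 0:
        targets = rng_presc.normal(params.prescribed_mean_km2, params.prescribed_sd_km2, ny)
        counts = np.clip(np.rint(targets / mean_cell), 0, n_cells_total).astype(int)
        for t, k in enumerate(counts):
            if k > 0:
                flat = rng_presc.choice(n_cells_total, size=k, replace=False)
                prescribed[t].ravel()[flat] = True

    return FireHistoryStack(
        years=np.arange(params.start_year, params.end_year + 1),
        wildfire=wildfire,
        prescribed=prescribed,
        true_p=p_map,
    )


@dataclass
class VariableCycle:
    """Seasonal cycle + trend + noise for one daily weather variable.

    value(day) = mean + amplitude·cos(2π(doy − peak_doy)/365.25)
                 + trend_per_decade·(years since start)/10
                 + N(0, synoptic_sd) [shared across the domain]
                 + N(0, noise_sd)    [independent per pixel].

    The synoptic term emulates weather-system variability coherent across
    the (small) analysis domain; the pixel term is local noise.
    """

    mean: float
    amplitude: float = 0.0
    peak_doy: float = 15.0
    trend_per_decade: float = 0.0
    noise_sd: float = 0.0
    synoptic_sd: float = 0.0


@dataclass
class WeatherGenParams:
    """Parameters of the synthetic daily weather cube.

    Defaults emulate a southeast-Australian temperate forest climate: Tmax
    peaking mid-January (DJF summer), relative humidity and rainfall peaking
    in winter, and a small dewpoint depression floor aloft. The dewpoint at
    850 hPa is generated as T850 minus a non-negative depression, so
    Td850 <= T850 holds by construction.
    """

    shape: tuple[int, int] = (10, 10)
    tmax: VariableCycle = field(default_factory=lambda: VariableCycle(mean=20.0, amplitude=8.0, peak_doy=15, noise_sd=1.5, synoptic_sd=4.0))
    rh: VariableCycle = field(default_factory=lambda: VariableCycle(mean=55.0, amplitude=-15.0, peak_doy=15, noise_sd=4.0, synoptic_sd=10.0))
    wind: VariableCycle = field(default_factory=lambda: VariableCycle(mean=20.0, amplitude=5.0, peak_doy=290, noise_sd=3.0, synoptic_sd=7.0))
    rain: VariableCycle = field(default_factory=lambda: VariableCycle(mean=2.0, amplitude=-1.0, peak_doy=15, noise_sd=2.0, synoptic_sd=3.5))
    t850: VariableCycle = field(default_factory=lambda: VariableCycle(mean=12.0, amplitude=7.0, peak_doy=15, noise_sd=1.0, synoptic_sd=2.5))
    t700: VariableCycle = field(default_factory=lambda: VariableCycle(mean=4.0, amplitude=6.0, peak_doy=15, noise_sd=1.0, synoptic_sd=2.5))
    dewpoint_depression_850: VariableCycle = field(default_factory=lambda: VariableCycle(mean=8.0, amplitude=4.0, peak_doy=15, noise_sd=1.5, synoptic_sd=3.0))
    lightning_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lightning_rate <= 1.0:
            raise ValueError("lightning_rate must be a probability")


_WEATHER_VARS = ("tmax", "rh", "wind", "rain", "t850", "t700", "dewpoint_depression_850")


def _cycle_values(cyc: VariableCycle, doy: np.ndarray, years_since: np.ndarray) -> np.ndarray:
    seasonal = cyc.mean + cyc.amplitude * np.cos(2 * np.pi * (doy - cyc.peak_doy) / 365.25)
    return seasonal + cyc.trend_per_decade * years_since / 10.0


def simulate_weather(params: WeatherGenParams, years: Sequence[int]) -> xr.Dataset:
    """Simulate a daily gridded weather cube over calendar ``years``.

    Returns an xarray Dataset with dims (time, lat, lon) and variables tmax
    (°C), rh (%), wind (km/h), rain (mm/day), t850/t700/td850 (°C) and a
    lightning-day flag. RH is clipped to [0, 100], rain to >= 0, and
    td850 <= t850 always.
    """
    years = list(years)
    if not years:
        raise ValueError("years must be non-empty")
    time = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    doy = time.dayofyear.to_numpy().astype(float)
    years_since = (time - time[0]).days.to_numpy() / 365.25
    nr, nc = params.shape

    rngs = _substreams(params.seed, len(_WEATHER_VARS) + 1)
    data = {}
    for name, rng in zip(_WEATHER_VARS, rngs):
        cyc = getattr(params, name)
        vals = np.broadcast_to(
            _cycle_values(cyc, doy, years_since)[:, None, None], (time.size, nr, nc)
        ).copy()
        if cyc.synoptic_sd > 0:
            vals += rng.normal(0.0, cyc.synoptic_sd, (time.size, 1, 1))
        if cyc.noise_sd > 0:
            vals += rng.normal(0.0, cyc.noise_sd, (time.size, nr, nc))
        data[name] = vals

    data["rh"] = np.clip(data["rh"], 0.0, 100.0)
    data["rain"] = np.clip(data["rain"], 0.0, None)
    data["wind"] = np.clip(data["wind"], 0.0, None)
    dd = np.clip(data.pop("dewpoint_depression_850"), 0.0, None)
    data["td850"] = data["t850"] - dd
    lightning = rngs[-1].random((time.size, nr, nc)) < params.lightning_rate

    coords = {
        "time": time,
        "lat": -30.0 - 0.05 * np.arange(nr),  # nominal SE-Australian latitudes
        "lon": 145.0 + 0.05 * np.arange(nc),
    }
    ds = xr.Dataset(
        {name: (("time", "lat", "lon"), np.asarray(arr)) for name, arr in data.items()},
        coords=coords,
    )
    ds["lightning"] = (("time", "lat", "lon"), lightning)
    ds.attrs["seed"] = params.seed
    for name in ("tmax", "t850", "t700", "td850"):
        ds[name].attrs["units"] = "degC"
    ds["rh"].attrs["units"] = "%"
    ds["wind"].attrs["units"] = "km/h"
    ds["rain"].attrs["units"] = "mm/day"
    return ds


def simulate_monthly_burned(
    history: FireHistoryStack,
    month_weights: Sequence[float],
    double_burn_fraction: float = 0.0,
    start_month: int = 7,
    seed: int = 0,
    source: str = "synthetic",
) -> list[MonthlyBurnedGrid]:
    """Distribute each annual wildfire into one month of its fire year.

    ``month_weights`` gives the probability of each of the 12 fire-year
    months (July first by default) and must sum to 1. A configurable small
    fraction of burned pixels is additionally marked as burning in a second,
    distinct month, emulating multi-burn flags in satellite monthly products.
    History years are interpreted as fire-year labels.
    """
    w = np.asarray(month_weights, dtype=float)
    if w.shape != (12,):
        raise ValueError("month_weights must have 12 entries")
    if not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError(f"month weights must sum to 1, got {w.sum()}")
    if not 0.0 <= double_burn_fraction <= 1.0:
        raise ValueError("double_burn_fraction must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    out: list[MonthlyBurnedGrid] = []
    shape = history.shape
    for t, fy in enumerate(history.years):
        calendar = fire_year_months(int(fy), start_month)
        rasters = np.zeros((12, *shape), dtype=bool)
        rows, cols = np.nonzero(history.wildfire[t])
        if rows.size:
            months = rng.choice(12, size=rows.size, p=w)
            rasters[months, rows, cols] = True
            n_double = int(np.floor(double_burn_fraction * rows.size))
            if n_double > 0:
                pick = rng.choice(rows.size, size=n_double, replace=False)
                second = (months[pick] + rng.integers(1, 12, size=n_double)) % 12
                rasters[second, rows[pick], cols[pick]] = True
        for k, (y, m) in enumerate(calendar):
            out.append(
                MonthlyBurnedGrid(
                    burned=rasters[k], year=y, month=m, grid=history.grid, source=source
                )
            )
    return out
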