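"""Burned-area accounting: fire years, seasons, union areas, cause splits.

The accounting conventions here follow the Australian record: a *fire year*
runs July–June (labelled by its starting calendar year) so that the Austral
summer is never split, seasons are the Austral calendar seasons, and a cell
that burns more than once within a fire year contributes its area once (the
union rule — multi-burn cells are flagged but not recounted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grids import ForestMask, GridSpec

__all__ = [
    "SEASONS",
    "SEASON_ORDER",
    "assign_fire_year",
    "assign_season",
    "fire_year_months",
    "MonthlyBurnedGrid",
    "FireYearSeries",
    "fire_year_burned_area",
    "aggregate_fire_years",
    "split_by_cause",
    "MegafireResult",
    "megafire_years",
]

#: Austral seasons by calendar month.
SEASONS = {
    12: "summer", 1: "summer", 2: "summer",
    3: "autumn", 4: "autumn", 5: "autumn",
    6: "winter", 7: "winter", 8: "winter",
    9: "spring", 10: "spring", 11: "spring",
}
SEASON_ORDER = ("summer", "autumn", "winter", "spring")


def assign_fire_year(year: int, month: int, start_month: int = 7) -> int:
    """Fire year containing (year, month): months >= start_month belong to
    fire year ``year``, earlier months to ``year - 1``.

    With the default July start, fire year y covers July y … June y+1.
    """
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return year if month >= start_month else year - 1


def assign_season(month: int) -> str:
    """Austral season of a calendar month (DJF summer … SON spring)."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return SEASONS[month]


def fire_year_months(fire_year: int, start_month: int = 7) -> list[tuple[int, int]]:
    """The 12 (calendar year, month) pairs of a fire year, in order."""
    months = []
    for k in range(12):
        m = (start_month - 1 + k) % 12 + 1
        y = fire_year + (1 if m < start_month else 0)
        months.append((y, m))
    return months


@dataclass
class MonthlyBurnedGrid:
    """Boolean burned raster for one calendar month."""

    burned: np.ndarray
    year: int
    month: int
    grid: GridSpec | None = None
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.burned = np.asarray(self.burned, dtype=bool)
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month}")
        if self.grid is not None and self.burned.shape != self.grid.shape:
            raise ValueError("burned raster shape does not match grid")


@dataclass
class FireYearSeries:
    """A per-fire-year scalar series (area in km², or day counts).

    ``values`` is indexed by the fire-year label (starting calendar year of
    July). ``seasons``, when present, is a DataFrame with one column per
    Austral season whose rows sum to the annual values.
    """

    values: pd.Series
    name: str = "value"
    units: str = ""
    seasons: pd.DataFrame | None = None
    regions: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, name=self.name)
        self.values.index = self.values.index.astype(int)
        self.values.index.name = "fire_year"

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        df = self.values.to_frame()
        if self.seasons is not None:
            df = df.join(self.seasons)
        return df


def _check_fire_year_block(
    months: Sequence[MonthlyBurnedGrid], start_month: int
) -> int:
    """Validate that ``months`` is exactly one complete fire year; return its label."""
    if len(months) != 12:
        raise ValueError(f"a fire year needs 12 months, got {len(months)}")
    fy = assign_fire_year(months[0].year, months[0].month, start_month)
    expected = fire_year_months(fy, start_month)
    got = [(m.year, m.month) for m in months]
    if got != expected:
        raise ValueError(
            f"months {got} are not the consecutive fire year {fy} ({expected})"
        )
    shapes = {m.burned.shape for m in months}
    if len(shapes) != 1:
        raise ValueError("monthly rasters are on different grids")
    return fy


def fire_year_burned_area(
    months: Sequence[MonthlyBurnedGrid],
    mask: ForestMask | np.ndarray | None = None,
    cell_areas: np.ndarray | None = None,
    start_month: int = 7,
) -> dict:
    """Burned area of one complete fire year over a forest mask.

    The annual area is the sum of cell areas over the *union* of burned∩forest
    cells — a cell burning in several months is counted once. Seasonal areas
    attribute each cell to the season of its first burn within the fire year,
    so they sum exactly to the annual union area. Returns a dict with keys
    ``fire_year``, ``area_km2``, ``season_area_km2``, ``n_cells``,
    ``n_multiburn_cells``.
    """
    fy = _check_fire_year_block(months, start_month)
    shape = months[0].burned.shape
    if mask is None:
        mask_arr = np.ones(shape, dtype=bool)
    else:
        mask_arr = mask.mask if isinstance(mask, ForestMask) else np.asarray(mask, bool)
    if mask_arr.shape != shape:
        raise ValueError("forest mask shape does not match burned rasters")
    if cell_areas is None:
        cell_areas = np.ones(shape)
    cell_areas = np.asarray(cell_areas, dtype=float)
    if cell_areas.shape != shape:
        raise ValueError("cell-area raster shape does not match burned rasters")

    burn_count = np.zeros(shape, dtype=np.int16)
    first_month_idx = np.full(shape, -1, dtype=np.int16)
    for k, m in enumerate(months):
        b = m.burned & mask_arr
        newly = b & (first_month_idx < 0)
        first_month_idx[newly] = k
        burn_count += b

    union = burn_count > 0
    season_area = {s: 0.0 for s in SEASON_ORDER}
    for k, m in enumerate(months):
        cells = union & (first_month_idx == k)
        season_area[assign_season(m.month)] += float(cell_areas[cells].sum())
    return {
        "fire_year": fy,
        "area_km2": float(cell_areas[union].sum()),
        "season_area_km2": season_area,
        "n_cells": int(union.sum()),
        "n_multiburn_cells": int((burn_count > 1).sum()),
    }


def aggregate_fire_years(
    months: Iterable[MonthlyBurnedGrid],
    mask: ForestMask | np.ndarray | None = None,
    cell_areas: np.ndarray | None = None,
    start_month: int = 7,
    drop_incomplete: bool = True,
) -> FireYearSeries:
    """Aggregate a monthly burned record into a per-fire-year area series.

    Incomplete leading/trailing fire years are dropped by default; with
    ``drop_incomplete=False`` they raise instead (no silent partial years).
    """
    by_fy: dict[int, list[MonthlyBurnedGrid]] = {}
    for m in months:
        by_fy.setdefault(assign_fire_year(m.year, m.month, start_month), []).append(m)
    values = {}
    seasons = {}
    for fy in sorted(by_fy):
        # chronological order: start_month..12 of y, then 1..start_month-1 of y+1
        block = sorted(by_fy[fy], key=lambda m: m.year * 12 + m.month)
        if len(block) != 12:
            if drop_incomplete:
                continue
            raise ValueError(f"fire year {fy} is incomplete ({len(block)} months)")
        rec = fire_year_burned_area(block, mask, cell_areas, start_month)
        values[fy] = rec["area_km2"]
        seasons[fy] = rec["season_area_km2"]
    series = pd.Series(values, dtype=float)
    seasons_df = pd.DataFrame.from_dict(seasons, orient="index")[list(SEASON_ORDER)] if seasons else None
    return FireYearSeries(
        values=series,
        name="burned_area",
        units="km2",
        seasons=seasons_df,
        meta={"start_month": start_month},
    )


def split_by_cause(
    history,
    cell_areas: np.ndarray | None = None,
    on_unknown: str = "error",
) -> tuple[FireYearSeries, FireYearSeries]:
    """Split an annual fire-history stack into wildfire and prescribed series.

    Returns per-year totals (pixel-event counts, or km² when ``cell_areas``
    is given) for each cause; the two series sum to the unsplit total by
    construction. ``history`` must carry both cause layers; absence of the
    cause attribute is an error.
    """
    if getattr(history, "prescribed", None) is None or getattr(history, "wildfire", None) is None:
        raise ValueError("fire history has no cause attribute (wildfire/prescribed layers)")
    if on_unknown not in ("error", "wildfire"):
        raise ValueError("on_unknown must be 'error' or 'wildfire'")
    w = np.asarray(history.wildfire, bool)
    p = np.asarray(history.prescribed, bool)
    if cell_areas is None:
        wt = np.ones(w.shape[1:])
        units = "pixel-events"
    else:
        wt = np.asarray(cell_areas, float)
        units = "km2"
    years = np.asarray(history.years, int)
    wild = pd.Series((w * wt).sum(axis=(1, 2)), index=years)
    presc = pd.Series((p * wt).sum(axis=(1, 2)), index=years)
    return (
        FireYearSeries(wild, name="wildfire", units=units),
        FireYearSeries(presc, name="prescribed", units=units),
    )


@dataclass
class MegafireResult:
    """Megafire years under the absolute-threshold and percentile definitions.

    The two definitions are reported separately; ``percentile_years`` includes
    every year tied at the percentile cutoff.
    """

    threshold_years: list[int]
    percentile_years: list[int]
    threshold_km2: float
    percentile: float
    cutoff_value: float


def megafire_years(
    series: FireYearSeries,
    threshold_km2: float = 10_000.0,
    percentile: float = 90.0,
) -> MegafireResult:
    """Identify megafire years: burned area over an absolute threshold
    (default 10,000 km² = 1 Mha) and, separately, the top decile of years.
    """
    v = series.values
    if len(v) == 0:
        raise ValueError("empty series")
    cutoff = float(np.percentile(v.to_numpy(), percentile))
    return MegafireResult(
        threshold_years=[int(y) for y in v.index[v > threshold_km2]],
        percentile_years=[int(y) for y in v.index[v >= cutoff]],
        threshold_km2=threshold_km2,
        percentile=percentile,
        cutoff_value=cutoff,
    )
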