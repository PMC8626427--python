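"""Fire-weather risk factors: KBDI, drought factor, FFDI, C-Haines, dry lightning.

All index constants live in one table below, with their published sources:

* FFDI — McArthur Forest Fire Danger Meter Mark 5 as formulated by
  Noble, Bary & Gill (1980), Aust. J. Ecol. 5:201-203:
  FFDI = 2 exp(-0.450 + 0.987 ln DF - 0.0345 RH + 0.0338 T + 0.0234 V).
* KBDI — Keetch & Byram (1968) soil-moisture deficit recursion in its
  metric (mm, 0-203.2) form as given by Finkele et al. (2006, BMRC/Aust.
  Met. Mag.), with a 5.08 mm interception allowance per rain event.
* Drought factor — Griffiths (1999, Aust. Forestry 62:202-206) limiting
  form driven by KBDI and the age/amount of the last significant rain event.
* C-Haines — Mills & McCaw (2010, CAWCR Tech. Rep. 20) continental
  adaptation of the Haines index: CA = 0.5 (T850 - T700) - 2;
  CB = (DD850 / 3) - 1 with DD capped at 30 °C and CB excess above 5 halved.
* Dry lightning — lightning on a day with rainfall below 2.5 mm.

Threshold comparisons on FFDI are inclusive (>=): the "Very High" danger
class starts at FFDI >= 25 and "Severe" at FFDI >= 50.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .burned_area import FireYearSeries, assign_fire_year, fire_year_months
from .grids import ForestMask

__all__ = [
    "CONSTANTS",
    "KBDI_MAX_MM",
    "kbdi_update",
    "kbdi_series",
    "drought_factor",
    "ffdi",
    "chaines",
    "dry_lightning",
    "compute_indices",
    "days_over_threshold",
    "epoch_change",
    "epoch_frequency_change_pct",
]

#: Single source of truth for index constants (see module docstring for citations).
CONSTANTS = {
    "ffdi": {"a": -0.450, "b_df": 0.987, "b_rh": -0.0345, "b_t": 0.0338, "b_v": 0.0234, "scale": 2.0},
    "kbdi": {"max_mm": 203.2, "interception_mm": 5.08, "et1": 0.968, "et2": 0.0875,
             "et3": 1.5552, "et4": 8.30, "et5": 10.88, "et6": 0.001736},
    "drought_factor": {"event_rain_mm": 2.0, "n_exp": 1.3, "df_max": 10.0},
    "chaines": {"ca_scale": 0.5, "ca_off": 2.0, "cb_div": 3.0, "cb_off": 1.0,
                "dd_cap": 30.0, "cb_soft_cap": 5.0},
    "dry_lightning": {"rain_threshold_mm": 2.5},
    "ffdi_classes": {"very_high": 25.0, "severe": 50.0},
}

KBDI_MAX_MM = CONSTANTS["kbdi"]["max_mm"]


def kbdi_update(kbdi_prev, rain_mm, tmax_c, annual_rain_mm, interception_carry=0.0):
    """One daily Keetch–Byram step (metric form); returns (kbdi, carry).

    The first 5.08 mm of each rain event are intercepted and do not reduce
    the deficit; ``interception_carry`` is the amount of the current event
    already charged against that allowance (pass the returned carry into the
    next day's call; it resets on a dry day). Evapotranspiration then adds

        dQ = (203.2 - Q)(0.968 e^{0.0875 T + 1.5552} - 8.30) 1e-3
             / (1 + 10.88 e^{-0.001736 R_annual}),

    and the result is clamped to [0, 203.2]. All arguments broadcast.
    """
    c = CONSTANTS["kbdi"]
    kbdi_prev = np.asarray(kbdi_prev, dtype=float)
    rain = np.asarray(rain_mm, dtype=float)
    if np.any(rain < 0):
        raise ValueError("rainfall cannot be negative")
    carry = np.asarray(interception_carry, dtype=float)

    allowance = np.maximum(c["interception_mm"] - carry, 0.0)
    effective = np.maximum(rain - allowance, 0.0)
    new_carry = np.where(rain > 0, np.minimum(carry + rain, c["interception_mm"]), 0.0)

    q = np.clip(kbdi_prev - effective, 0.0, c["max_mm"])
    et = (
        (c["max_mm"] - q)
        * (c["et1"] * np.exp(c["et2"] * np.asarray(tmax_c, float) + c["et3"]) - c["et4"])
        * 1e-3
        / (1.0 + c["et5"] * np.exp(-c["et6"] * np.asarray(annual_rain_mm, float)))
    )
    et = np.maximum(et, 0.0)
    q = np.clip(q + et, 0.0, c["max_mm"])
    if q.ndim == 0:
        return float(q), float(new_carry)
    return q, new_carry


def kbdi_series(
    rain: np.ndarray, tmax: np.ndarray, annual_rain_mm, kbdi0=None
) -> np.ndarray:
    """Run the KBDI recursion over a (time, ...) rain/tmax sequence."""
    rain = np.asarray(rain, float)
    tmax = np.asarray(tmax, float)
    if rain.shape != tmax.shape:
        raise ValueError("rain and tmax shapes differ")
    out = np.empty_like(rain)
    state = np.full(rain.shape[1:], KBDI_MAX_MM / 2 if kbdi0 is None else kbdi0, dtype=float)
    carry = np.zeros(rain.shape[1:])
    for t in range(rain.shape[0]):
        state, carry = kbdi_update(state, rain[t], tmax[t], annual_rain_mm, carry)
        state = np.atleast_1d(np.asarray(state))
        carry = np.atleast_1d(np.asarray(carry))
        out[t] = state
    return out


def drought_factor(
    kbdi,
    days_since_rain,
    last_event_rain_mm,
    method: Literal["griffiths", "kbdi_linear"] = "griffiths",
):
    """Drought factor (fuel availability, 0-10) from KBDI and recent rain.

    Griffiths' limiting form: with N days since the last significant rain
    event (> 2 mm) of amount P,

        x   = N^1.3 / (N^1.3 + P - 2)          (x = 1 if no such event)
        xlim= 1/(1 + 0.1135 K)        if K < 20
            = 75/(270.525 - 1.267 K)  otherwise
        DF  = min(10, 10.5 (1 - e^{-(K+30)/40}) (41 x'^2 + x')/(40 x'^2 + x' + 1))

    where x' = min(x, xlim). The ``kbdi_linear`` fallback is a bare ramp
    10·K/203.2, useful as a simple monotone stand-in in tests.
    """
    k = np.asarray(kbdi, dtype=float)
    if method == "kbdi_linear":
        df = 10.0 * k / KBDI_MAX_MM
        return float(df) if df.ndim == 0 else df
    if method != "griffiths":
        raise ValueError(f"unknown drought-factor method {method!r}")
    c = CONSTANTS["drought_factor"]
    n = np.maximum(np.asarray(days_since_rain, dtype=float), 0.8)  # same-day event floor
    p_evt = np.asarray(last_event_rain_mm, dtype=float)
    npow = n ** c["n_exp"]
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(p_evt > c["event_rain_mm"], npow / (npow + p_evt - c["event_rain_mm"]), 1.0)
    xlim = np.where(k < 20.0, 1.0 / (1.0 + 0.1135 * k), 75.0 / (270.525 - 1.267 * k))
    x = np.minimum(x, xlim)
    df = 10.5 * (1.0 - np.exp(-(k + 30.0) / 40.0)) * (41.0 * x**2 + x) / (40.0 * x**2 + x + 1.0)
    df = np.clip(df, 0.0, c["df_max"])
    return float(df) if df.ndim == 0 else df


def ffdi(tmax_c, rh_pct, wind_kmh, df):
    """McArthur Mark 5 Forest Fire Danger Index.

    FFDI = 2 exp(-0.450 + 0.987 ln DF - 0.0345 RH + 0.0338 T + 0.0234 V).
    DF <= 0 maps to FFDI 0 (the log singularity handled by convention).
    """
    c = CONSTANTS["ffdi"]
    rh = np.asarray(rh_pct, dtype=float)
    v = np.asarray(wind_kmh, dtype=float)
    d = np.asarray(df, dtype=float)
    t = np.asarray(tmax_c, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("relative humidity must be within [0, 100]%")
    if np.any(v < 0):
        raise ValueError("wind speed cannot be negative")
    if np.any(d < 0) or np.any(d > 10):
        raise ValueError("drought factor must be within [0, 10]")
    with np.errstate(divide="ignore"):
        logdf = np.where(d > 0, np.log(np.where(d > 0, d, 1.0)), 0.0)
        out = np.where(
            d > 0,
            c["scale"] * np.exp(c["a"] + c["b_df"] * logdf + c["b_rh"] * rh + c["b_t"] * t + c["b_v"] * v),
            0.0,
        )
    return float(out) if out.ndim == 0 else out


def chaines(t850, t700, td850, components: bool = False):
    """Continuous Haines index for pyroconvection risk.

    Stability term CA = 0.5 (T850 - T700) - 2; humidity term from the 850 hPa
    dewpoint depression DD = min(T850 - Td850, 30): CB = DD/3 - 1, with any
    excess of CB above 5 halved. Returns CA + CB (or (CH, CA, CB) with
    ``components=True``). Requires Td850 <= T850.
    """
    c = CONSTANTS["chaines"]
    t8 = np.asarray(t850, dtype=float)
    t7 = np.asarray(t700, dtype=float)
    td = np.asarray(td850, dtype=float)
    if np.any(td > t8 + 1e-9):
        raise ValueError("dewpoint above temperature at 850 hPa")
    ca = c["ca_scale"] * (t8 - t7) - c["ca_off"]
    dd = np.minimum(t8 - td, c["dd_cap"])
    cb = dd / c["cb_div"] - c["cb_off"]
    cb = np.where(cb > c["cb_soft_cap"], c["cb_soft_cap"] + (cb - c["cb_soft_cap"]) / 2.0, cb)
    ch = ca + cb
    if components:
        return ch, ca, cb
    return float(ch) if ch.ndim == 0 else ch


def dry_lightning(lightning_flag, rain_mm, threshold_mm: float | None = None):
    """Dry-lightning flag: lightning on a day with rainfall below ~2.5 mm."""
    thr = CONSTANTS["dry_lightning"]["rain_threshold_mm"] if threshold_mm is None else threshold_mm
    rain = np.asarray(rain_mm, dtype=float)
    if np.any(rain < 0):
        raise ValueError("rainfall cannot be negative")
    flag = np.asarray(lightning_flag, dtype=bool) & (rain < thr)
    return bool(flag) if flag.ndim == 0 else flag


def compute_indices(cube: xr.Dataset, kbdi0: float | None = None) -> xr.Dataset:
    """Compute daily KBDI, drought factor, FFDI, C-Haines and dry lightning
    from a weather cube with variables tmax, rh, wind, rain, t850, t700,
    td850, lightning on dims (time, lat, lon).

    The mean annual rainfall that conditions the KBDI evapotranspiration term
    is taken from the cube itself (per-pixel mean of calendar-year totals).
    Drought-factor rain events are tracked as days with rain above 2 mm.
    """
    needed = {"tmax", "rh", "wind", "rain", "t850", "t700", "td850", "lightning"}
    missing = needed - set(cube.data_vars)
    if missing:
        raise ValueError(f"weather cube is missing variables: {sorted(missing)}")
    rain = cube["rain"].to_numpy()
    tmax = cube["tmax"].to_numpy()
    annual_rain = cube["rain"].groupby("time.year").sum("time").mean("year").to_numpy()

    nt = rain.shape[0]
    space = rain.shape[1:]
    evt_thr = CONSTANTS["drought_factor"]["event_rain_mm"]

    kbdi = np.empty_like(rain)
    df = np.empty_like(rain)
    state = np.full(space, KBDI_MAX_MM / 2 if kbdi0 is None else kbdi0, dtype=float)
    carry = np.zeros(space)
    days_since = np.full(space, 60.0)  # long-dry spin-up assumption
    last_amount = np.zeros(space)
    for t in range(nt):
        state, carry = kbdi_update(state, rain[t], tmax[t], annual_rain, carry)
        is_event = rain[t] > evt_thr
        days_since = np.where(is_event, 0.0, days_since + 1.0)
        last_amount = np.where(is_event, rain[t], last_amount)
        kbdi[t] = state
        df[t] = drought_factor(state, days_since, last_amount)

    out = xr.Dataset(coords=cube.coords)
    dims = cube["rain"].dims
    out["kbdi"] = (dims, kbdi)
    out["drought_factor"] = (dims, df)
    out["ffdi"] = (dims, ffdi(tmax, cube["rh"].to_numpy(), cube["wind"].to_numpy(), df))
    out["c_haines"] = (
        dims,
        chaines(cube["t850"].to_numpy(), cube["t700"].to_numpy(), cube["td850"].to_numpy()),
    )
    out["dry_lightning"] = (dims, dry_lightning(cube["lightning"].to_numpy(), rain))
    return out


def days_over_threshold(
    ffdi_cube: xr.DataArray,
    mask: ForestMask | np.ndarray | None,
    threshold: float,
    mode: Literal["forest_mean", "per_pixel"] = "forest_mean",
    start_month: int = 7,
    drop_incomplete: bool = True,
) -> FireYearSeries:
    """Count days per fire year with FFDI at or above a threshold.

    ``forest_mean`` (default): the spatial mean FFDI over the forest mask is
    formed per day and compared to the threshold — one national daily index
    series. ``per_pixel``: each pixel's exceedance days are counted, then
    averaged spatially. The comparison is inclusive (>=). The mode is
    recorded in the series metadata. Incomplete fire years raise unless
    ``drop_incomplete``.
    """
    if mask is None:
        m = np.ones(ffdi_cube.shape[1:], dtype=bool)
    else:
        m = mask.mask if isinstance(mask, ForestMask) else np.asarray(mask, bool)
    vals = ffdi_cube.to_numpy()
    if m.shape != vals.shape[1:]:
        raise ValueError("forest mask shape does not match the FFDI cube")
    time = pd.DatetimeIndex(ffdi_cube["time"].to_numpy())
    fy = np.array([assign_fire_year(y, mo, start_month) for y, mo in zip(time.year, time.month)])

    if mode == "forest_mean":
        daily = vals[:, m].mean(axis=1)
        exceed = (daily >= threshold).astype(float)
    elif mode == "per_pixel":
        exceed = (vals[:, m] >= threshold).mean(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    counts = {}
    for y in np.unique(fy):
        sel = fy == y
        months_present = {(yy, mm) for yy, mm in zip(time.year[sel], time.month[sel])}
        if months_present != set(fire_year_months(int(y), start_month)):
            if drop_incomplete:
                continue
            raise ValueError(f"fire year {y} is incomplete in the FFDI cube")
        counts[int(y)] = float(exceed[sel].sum())
    return FireYearSeries(
        pd.Series(counts, dtype=float),
        name=f"days_ffdi_ge_{threshold:g}",
        units="days",
        meta={"mode": mode, "threshold": threshold, "inclusive": True},
    )


def _epoch_mean(da: xr.DataArray, epoch: tuple[int, int]) -> xr.DataArray:
    y0, y1 = epoch
    years = da["time"].dt.year
    present = set(np.unique(years.to_numpy()))
    missing = set(range(y0, y1 + 1)) - present
    if missing:
        raise ValueError(f"epoch {epoch} missing years {sorted(missing)}")
    sel = da.sel(time=(years >= y0) & (years <= y1))
    if sel.dtype == bool:
        sel = sel.astype(float)
    return sel.mean("time")


def epoch_change(
    da: xr.DataArray,
    epoch1: tuple[int, int] = (1980, 1999),
    epoch2: tuple[int, int] = (2000, 2019),
) -> xr.DataArray:
    """Per-pixel mean(epoch2) − mean(epoch1) change map, calendar years."""
    return _epoch_mean(da, epoch2) - _epoch_mean(da, epoch1)


def epoch_frequency_change_pct(
    flags: xr.DataArray,
    epoch1: tuple[int, int] = (1980, 1999),
    epoch2: tuple[int, int] = (2000, 2016),
) -> xr.DataArray:
    """Percent change in occurrence frequency of a daily flag between epochs
    (the headline statistic for dry-lightning environments)."""
    f1 = _epoch_mean(flags, epoch1)
    f2 = _epoch_mean(flags, epoch2)
    return 100.0 * (f2 - f1) / xr.where(f1 > 0, f1, np.nan)
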