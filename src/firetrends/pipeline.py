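"""End-to-end orchestration: simulate → aggregate → YSLF → fire weather → trends.

`run_pipeline` executes every stage deterministically from a
:class:`~firetrends.config.RunConfig` and returns a bundle of tables and fit
reports; `write_outputs` persists them as CSV/JSON plus a manifest with a
SHA-256 of every output and the full parameter set, so each reported number
is traceable to config + seed. Any stage failure aborts with the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import burned_area as ba
from . import fire_weather as fw
from . import synthetic, trends, yslf
from .config import RunConfig
from .grids import GridSpec, cell_area_km2

__all__ = ["PipelineError", "ReportBundle", "run_pipeline", "write_outputs", "render_report"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class ReportBundle:
    config: RunConfig
    burned_series: ba.FireYearSeries
    cause_split: tuple[ba.FireYearSeries, ba.FireYearSeries]
    megafires: ba.MegafireResult
    yslf_decades: pd.DataFrame
    burned_fraction: float
    ffdi_days: dict[float, ba.FireYearSeries]
    epoch_changes: dict[str, float]
    fits: dict[str, dict]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


def _fit_report(fit: trends.TrendFitResult) -> dict:
    rep = {
        "model": fit.model,
        "intercept": fit.intercept,
        "slope": fit.slope,
        "slope_pvalue": fit.slope_pvalue,
        "r_squared": fit.r_squared,
        "n": fit.n,
    }
    if fit.growth_rate is not None:
        rep["growth_rate_pct"] = 100.0 * fit.growth_rate
    return rep


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full synthetic analysis pipeline for one (config, seed)."""
    grid = GridSpec(
        nrows=config.nrows,
        ncols=config.ncols,
        lat_origin=config.lat_origin,
        lon_origin=config.lon_origin,
        cell_size=config.cell_size,
    )
    areas = cell_area_km2(grid)
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)

    @_stage("simulate_fire_history")
    def sim_history():
        params = synthetic.FireProcessParams(
            shape=grid.shape,
            start_year=config.start_year,
            end_year=config.end_year,
            p=config.fire_probability,
            prescribed_mean_km2=config.prescribed_mean_km2,
            prescribed_sd_km2=config.prescribed_sd_km2,
            seed=int(seeds[0]),
        )
        hist = synthetic.simulate_fire_history(params)
        hist.grid = grid
        return hist

    history = sim_history()

    @_stage("simulate_monthly_burned")
    def sim_monthly():
        return synthetic.simulate_monthly_burned(
            history,
            config.month_weights,
            double_burn_fraction=config.double_burn_fraction,
            start_month=config.fire_year_start_month,
            seed=int(seeds[1]),
        )

    monthly = sim_monthly()

    @_stage("burned_area_aggregate")
    def aggregate():
        series = ba.aggregate_fire_years(
            monthly, mask=None, cell_areas=areas, start_month=config.fire_year_start_month
        )
        split = ba.split_by_cause(history, cell_areas=areas)
        mega = ba.megafire_years(series, threshold_km2=config.megafire_km2)
        return series, split, mega

    burned_series, cause_split, megafires = aggregate()

    @_stage("yslf_reconstruct")
    def run_yslf():
        grid_y = yslf.reconstruct(history, seed=int(seeds[2]))
        rows = []
        first_full = ((config.start_year + 9) // 10) * 10
        for dec in range(first_full, config.end_year - 8, 10):
            mean, sd = yslf.decadal_summary(grid_y, dec)
            rows.append({"decade": dec, "mean_yslf": mean, "sd_yslf": sd})
        frac = float(grid_y.eligible.mean())
        return pd.DataFrame(rows), frac

    yslf_decades, burned_fraction = run_yslf()

    @_stage("fire_weather")
    def run_weather():
        wparams = synthetic.WeatherGenParams(
            shape=tuple(config.weather_shape),
            lightning_rate=config.lightning_rate,
            seed=int(seeds[3]),
        )
        wparams.tmax.trend_per_decade = config.tmax_trend_per_decade
        cube = synthetic.simulate_weather(
            wparams, range(config.start_year, config.end_year + 1)
        )
        indices = fw.compute_indices(cube)
        days = {
            thr: fw.days_over_threshold(
                indices["ffdi"], None, thr, start_month=config.fire_year_start_month
            )
            for thr in config.ffdi_thresholds
        }
        e1, e2 = tuple(config.epoch1), tuple(config.epoch2)
        changes = {
            "tmax_change_c": float(fw.epoch_change(cube["tmax"], e1, e2).mean()),
            "ffdi_change": float(fw.epoch_change(indices["ffdi"], e1, e2).mean()),
            "c_haines_change": float(fw.epoch_change(indices["c_haines"], e1, e2).mean()),
            "dry_lightning_change_pct": float(
                fw.epoch_frequency_change_pct(indices["dry_lightning"], e1, e2).mean()
            ),
        }
        return days, changes

    ffdi_days, epoch_changes = run_weather()

    @_stage("trends")
    def run_trends():
        fits = {}
        fits["burned_area_linear"] = _fit_report(trends.fit_linear(burned_series))
        fits["burned_area_exponential"] = _fit_report(trends.fit_exponential(burned_series))
        mid = (config.start_year + config.end_year + 1) // 2
        fits["percent_change_halves"] = {
            "split_year": mid,
            "percent": trends.percent_change_halves(burned_series, mid),
        }
        positive = burned_series.values[burned_series.values > 0]
        for thr, days in ffdi_days.items():
            common = positive.index.intersection(days.values.index)
            if len(common) >= 3 and np.ptp(days.values[common].to_numpy()) > 0:
                fit = trends.fit_burned_vs_ffdi(positive[common], days.values[common])
                fits[f"burned_vs_ffdi{thr:g}"] = _fit_report(fit)
            else:
                logger.info("FFDI>=%g day counts constant; regression skipped", thr)
        return fits

    fits = run_trends()

    tables = {
        "burned_area": burned_series.to_frame(),
        "cause_split": pd.concat(
            {"wildfire": cause_split[0].values, "prescribed": cause_split[1].values}, axis=1
        ),
        "yslf_decades": yslf_decades,
        **{
            f"ffdi_days_ge_{thr:g}": s.values.to_frame()
            for thr, s in ffdi_days.items()
        },
    }
    return ReportBundle(
        config=config,
        burned_series=burned_series,
        cause_split=cause_split,
        megafires=megafires,
        yslf_decades=yslf_decades,
        burned_fraction=burned_fraction,
        ffdi_days=ffdi_days,
        epoch_changes=epoch_changes,
        fits=fits,
        tables=tables,
    )


def write_outputs(bundle: ReportBundle, out_dir) -> Path:
    """Write the bundle as CSV tables + a JSON report + a hash manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in bundle.tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path)
        written.append(path)
    report = {
        "seed": bundle.config.seed,
        "megafire_years_threshold": bundle.megafires.threshold_years,
        "megafire_years_percentile": bundle.megafires.percentile_years,
        "burned_at_least_once_fraction": bundle.burned_fraction,
        "epoch_changes": bundle.epoch_changes,
        "fits": bundle.fits,
    }
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    written.append(report_path)
    manifest = {
        "config": bundle.config.as_dict(),
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in written
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def render_report(bundle: ReportBundle, out_dir) -> list:
    """Render the bundle's headline figures (burned-area series with trend,
    seasonal stack, YSLF decadal means, FFDI day counts) as PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots(figsize=(7, 4))
    s = bundle.burned_series.values
    ax.plot(s.index, s.to_numpy(), "o-", label="burned area")
    lin = bundle.fits.get("burned_area_linear")
    if lin:
        x = s.index.to_numpy(dtype=float)
        ax.plot(x, lin["intercept"] + lin["slope"] * x, "--",
                label=f"linear fit (p={lin['slope_pvalue']:.3f})")
    ax.set_xlabel("fire year (July–June)")
    ax.set_ylabel("burned area (km²)")
    ax.legend()
    fig.tight_layout()
    p = out / "burned_area.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    if bundle.burned_series.seasons is not None:
        fig, ax = plt.subplots(figsize=(7, 4))
        bundle.burned_series.seasons.plot.area(ax=ax)
        ax.set_xlabel("fire year")
        ax.set_ylabel("burned area (km²)")
        fig.tight_layout()
        p = out / "burned_area_seasonal.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    d = bundle.yslf_decades
    ax.errorbar(d["decade"], d["mean_yslf"], yerr=d["sd_yslf"], fmt="s-")
    ax.set_xlabel("decade")
    ax.set_ylabel("mean YSLF (years)")
    fig.tight_layout()
    p = out / "yslf_decades.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(7, 4))
    for thr, s in bundle.ffdi_days.items():
        ax.plot(s.values.index, s.values.to_numpy(), "o-", label=f"FFDI ≥ {thr:g}")
    ax.set_xlabel("fire year")
    ax.set_ylabel("days")
    ax.legend()
    fig.tight_layout()
    p = out / "ffdi_days.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
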