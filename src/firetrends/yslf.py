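"""Years-since-last-wildfire (YSLF) reconstruction from annual fire histories.

A pixel's YSLF is the number of whole years since its most recent recorded
wildfire, reset to 0 in every fire year. At the record origin the YSLF of a
pixel that did not burn that year is unknown; it is initialized by inverse-
transform sampling from the geometric distribution implied by a Bernoulli
fire process at the pixel's observed mean wildfire frequency p:

    F^{-1}(u) = ceil( ln(1 - u) / ln(1 - p) ),   0 < u < 1,

which is exactly the stationary distribution of time-since-last-event
conditional on no event in the initialization year, P(k) = p(1-p)^(k-1) for
k >= 1. Estimated values are incremented year by year until the first
in-record fire resets them, after which the pixel's YSLF is fully observed.
Only pixels with at least one wildfire in the record are eligible; all
others are masked from the analysis. Prescribed burns never reset YSLF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .synthetic import FireHistoryStack

__all__ = [
    "estimate_p",
    "geometric_init",
    "YSLFGrid",
    "reconstruct",
    "decadal_summary",
    "burned_fraction_by_class",
    "annualize_monthly",
]


def estimate_p(history: FireHistoryStack, pixel: tuple[int, int] | None = None):
    """Per-pixel mean wildfire frequency p = fire years / record years.

    Prescribed burns are excluded: p is a wildfire frequency. With ``pixel``
    given, returns a scalar and raises for an ineligible (never-burned)
    pixel; otherwise returns the full p map (0 where ineligible).
    """
    counts = history.wildfire.sum(axis=0)
    p = counts / history.n_years
    if pixel is None:
        return p
    val = float(p[pixel])
    if val == 0.0:
        raise ValueError(f"pixel {pixel} has no wildfire in the record (ineligible)")
    return val


def geometric_init(u, p, bracket: Literal["ceil", "floor", "round"] = "ceil"):
    """Initial YSLF from a uniform draw via the geometric quantile function.

    ceil(ln(1-u)/ln(1-p)), floored at 1. With the default ceiling bracket the
    result is the proper geometric quantile on {1, 2, ...}: a floor bracket
    would map small u to 0, colliding with the burned-this-year code.
    Accepts scalars or arrays; u and p must lie strictly inside (0, 1).
    """
    u_arr = np.asarray(u, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if np.any(u_arr <= 0) or np.any(u_arr >= 1):
        raise ValueError("u must lie strictly in (0, 1)")
    if np.any(p_arr <= 0) or np.any(p_arr >= 1):
        raise ValueError("p must lie strictly in (0, 1)")
    ratio = np.log1p(-u_arr) / np.log1p(-p_arr)
    if bracket == "ceil":
        k = np.ceil(ratio)
    elif bracket == "floor":
        k = np.floor(ratio)
    elif bracket == "round":
        k = np.rint(ratio)
    else:
        raise ValueError(f"unknown bracket convention {bracket!r}")
    k = np.maximum(k, 1.0).astype(np.int64)
    return int(k) if k.ndim == 0 else k


@dataclass
class YSLFGrid:
    """Per-pixel, per-year YSLF surfaces with provenance.

    ``yslf`` is (n_years, nrows, ncols), -1 outside the eligibility mask;
    ``estimated`` flags pixel-years whose value still descends from the
    record-origin initializer draw (it flips to False at the first in-record
    fire); ``eligible`` marks pixels with >= 1 wildfire in the record.
    """

    years: np.ndarray
    yslf: np.ndarray
    estimated: np.ndarray
    eligible: np.ndarray
    p: np.ndarray
    seed: int | None = None

    def year_index(self, year: int) -> int:
        idx = int(year) - int(self.years[0])
        if not 0 <= idx < self.years.size:
            raise ValueError(f"year {year} outside record")
        return idx


def reconstruct(
    history: FireHistoryStack,
    seed: int = 0,
    bracket: Literal["ceil", "floor", "round"] = "ceil",
) -> YSLFGrid:
    """Reconstruct YSLF surfaces for every year of an annual fire history.

    Origin year: pixels burned that year get YSLF 0 (observed); all other
    eligible pixels draw their initial YSLF from the geometric initializer at
    their record-wide wildfire frequency. Subsequent years increment by 1 and
    reset to 0 at recorded fires. Bit-reproducible under a fixed seed; pixels
    whose provenance is observed are seed-independent.
    """
    wf = history.wildfire
    ny = history.n_years
    p = estimate_p(history)
    eligible = p > 0

    yslf = np.full((ny, *history.shape), -1, dtype=np.int32)
    estimated = np.zeros((ny, *history.shape), dtype=bool)

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    burned0 = wf[0]
    init_pixels = eligible & ~burned0
    state = np.zeros(history.shape, dtype=np.int32)
    if np.any(init_pixels):
        # p < 1 on init pixels: a p == 1 pixel burned in the origin year
        u = rng.random(int(init_pixels.sum()))
        state[init_pixels] = geometric_init(u, p[init_pixels], bracket=bracket)
    est_state = init_pixels.copy()

    yslf[0][eligible] = state[eligible]
    estimated[0] = est_state
    for t in range(1, ny):
        state = np.where(wf[t], 0, state + 1)
        est_state &= ~wf[t]
        yslf[t][eligible] = state[eligible]
        estimated[t] = est_state & eligible
    return YSLFGrid(
        years=history.years.copy(),
        yslf=yslf,
        estimated=estimated,
        eligible=eligible,
        p=p,
        seed=seed,
    )


def decadal_summary(
    grid: YSLFGrid,
    decade_start: int,
    weights: np.ndarray | None = None,
    pixel_level: bool = False,
) -> tuple[float, float]:
    """Decadal mean ± SD of YSLF over eligible pixels.

    For each of the decade's 10 years the spatial mean YSLF over eligible
    pixels is computed (optionally area-weighted); the returned mean and SD
    (ddof=1) are taken across those 10 annual means. With ``pixel_level=True``
    the SD is instead the pooled per-pixel-year SD, which is an order of
    magnitude larger.
    """
    if decade_start % 10:
        raise ValueError("decade_start must be a multiple of 10")
    i0 = grid.year_index(decade_start)
    i1 = grid.year_index(decade_start + 9)
    if not np.any(grid.eligible):
        raise ValueError("no eligible pixels (nothing burned in the record)")
    block = grid.yslf[i0 : i1 + 1][:, grid.eligible].astype(float)
    if weights is not None:
        w = np.asarray(weights, float)[grid.eligible]
        annual_means = (block * w).sum(axis=1) / w.sum()
    else:
        annual_means = block.mean(axis=1)
    if pixel_level:
        return float(annual_means.mean()), float(block.std(ddof=1))
    return float(annual_means.mean()), float(annual_means.std(ddof=1))


def burned_fraction_by_class(
    history: FireHistoryStack,
    class_raster: np.ndarray,
    cell_areas: np.ndarray | None = None,
) -> dict:
    """Fraction of each class's pixels (or area) with >= 1 wildfire on record."""
    classes = np.asarray(class_raster)
    if classes.shape != history.shape:
        raise ValueError("class raster shape does not match the fire history grid")
    burned = history.wildfire.any(axis=0)
    wt = np.ones(history.shape) if cell_areas is None else np.asarray(cell_areas, float)
    if wt.shape != history.shape:
        raise ValueError("cell-area raster shape does not match the fire history grid")
    out = {}
    for label in np.unique(classes):
        sel = classes == label
        total = wt[sel].sum()
        out[label.item() if hasattr(label, "item") else label] = (
            float(wt[sel & burned].sum() / total) if total > 0 else float("nan")
        )
    return out


def annualize_monthly(monthly_burned, years: Sequence[int]) -> np.ndarray:
    """Collapse a monthly burned record to annual occurrence: a pixel-year is
    burned iff any of its calendar months burned. Used to extend annual
    agency histories with monthly satellite products.
    """
    by_year = {int(y): None for y in years}
    for m in monthly_burned:
        if int(m.year) in by_year:
            cur = by_year[int(m.year)]
            by_year[int(m.year)] = m.burned.copy() if cur is None else (cur | m.burned)
    missing = [y for y, v in by_year.items() if v is None]
    if missing:
        raise ValueError(f"no monthly data for years {missing}")
    return np.stack([by_year[int(y)] for y in years])
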