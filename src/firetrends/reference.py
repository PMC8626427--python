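"""Published reference values for the Australian forest fire record.

These are printed inputs from the national burned-area products and agency
fire histories (NIAFED, AVHRR-Landgate, NASA-MODIS MCD64A1) used as worked
examples and cross-checks. They are data, not computed outputs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "BURNED_AREA_2019_KM2",
    "STUDY_FOREST_AREA_KM2",
    "YSLF_ELIGIBLE_AREA_KM2",
    "PRESCRIBED_BURN_MEAN_KM2",
    "PRESCRIBED_BURN_SD_KM2",
    "MEGAFIRE_THRESHOLD_KM2",
    "mean_2019_burned_area_km2",
    "prescribed_burn_fraction_pct",
]

#: Independent estimates of the 2019 fire-year (July 2019 – June 2020)
#: forest burned area, km², by product.
BURNED_AREA_2019_KM2 = {
    "agencies_niafed": 71_772.0,
    "avhrr_landgate": 60_345.0,
    "nasa_modis": 54_852.0,
}

#: Total forest study area, km² (National Forest Inventory classes).
STUDY_FOREST_AREA_KM2 = 324_873.0

#: Forest area with at least one recorded wildfire since 1930, km².
YSLF_ELIGIBLE_AREA_KM2 = 155_384.0

#: Mean and inter-annual SD of annual prescribed-burn area, km²/yr (1988–2018).
PRESCRIBED_BURN_MEAN_KM2 = 3_071.0
PRESCRIBED_BURN_SD_KM2 = 732.0

#: Megafire-year burned-area threshold, km² (1 Mha).
MEGAFIRE_THRESHOLD_KM2 = 10_000.0


def mean_2019_burned_area_km2() -> tuple[float, float]:
    """Mean and SD (ddof=1) of the three 2019 burned-area product estimates."""
    v = np.array(list(BURNED_AREA_2019_KM2.values()))
    return float(v.mean()), float(v.std(ddof=1))


def prescribed_burn_fraction_pct() -> float:
    """Mean annual prescribed-burn area as a percent of the forest study area."""
    return 100.0 * PRESCRIBED_BURN_MEAN_KM2 / STUDY_FOREST_AREA_KM2
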