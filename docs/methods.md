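# Methods

## Scope and model

The package analyses multi-decadal wildfire activity on regular geographic
grids. Its state variable is the per-pixel number of years since the last
wildfire (YSLF): 0 in a recorded wildfire year, incremented by one each year
otherwise. The analysis is restricted to *eligible* pixels — those with at
least one recorded wildfire over the record — because only there does the
record constrain the fire regime at all; everything else is masked.
Prescribed burns are tracked as a separate cause layer and never reset YSLF,
since the aim is to characterize the wildfire regime rather than management
activity.

### The geometric initializer

At the record origin the YSLF of a pixel that did not burn that year is
unknown. We initialize it by drawing from the distribution that a stationary
Bernoulli(p) fire process implies for time-since-last-event conditional on
"no event this year": P(k) = p(1 − p)^(k−1) on k = 1, 2, …, sampled by
inverse transform,

    F⁻¹(u) = ⌈ ln(1 − u) / ln(1 − p) ⌉ ,  0 < u < 1 ,

with p estimated per pixel as (wildfire years)/(record years). Three
consequences worth noting:

* **Bracket convention.** The ceiling makes the draw the proper geometric
  quantile on {1, 2, …}. A floor would map small u to 0 and collide with
  the "burned this year" code; we expose `bracket="floor"/"round"` as
  options (both still floored at 1) for sensitivity checks only.
* **p = 1 pixels** (burned every year) necessarily burned in the origin
  year, so the initializer — undefined at p = 1 — is never invoked for them.
* **Conditioning bias.** Restricting to eligible pixels selects for pixels
  with higher-than-average realized fire frequency. On stationary synthetic
  truth the late-record spatial mean YSLF therefore sits *below* the
  unconditional stationary mean (1 − p)/p, markedly so for small p (for
  p = 0.02 over 90 years, ≈ 33 rather than 49 years). Validation therefore
  compares against a Monte-Carlo simulation of the same conditional process,
  not against the closed form.

### Decadal summaries

The decadal mean/SD is computed from the ten annual spatial means over
eligible pixels: the SD expresses year-to-year movement of the landscape
mean (order 0.1–10 years), not the spatial spread between pixels (order
tens of years). A `pixel_level=True` flag gives the pooled per-pixel SD
instead, and a `weights=` argument switches the spatial mean from
pixel-count to area weighting (unweighted is the default).

## Burned-area accounting

* **Fire year**: July–June, labelled by the starting calendar year, so the
  Austral summer (DJF) is never split. Seasons are the Austral calendar
  seasons; autumn + winter = March–August.
* **Union rule**: a fire year's burned area is the sum of cell areas over
  the union of burned∩forest cells; cells burning in several months are
  flagged but counted once. Seasonal areas attribute each cell to the season
  of its *first* burn in the fire year, which keeps the seasonal areas
  summing exactly to the annual union. (With multi-burn cells attributed to
  every burn season instead, seasonal sums would exceed the annual union;
  first-burn attribution preserves the not-recounted accounting.)
* **Incomplete fire years** at the record edges are dropped from aggregated
  series by default, or raise with `drop_incomplete=False`; partial years
  never enter silently.
* **Megafire years** are reported under both common definitions — burned
  area above an absolute threshold (default 10,000 km² = 1 Mha) and the top
  decile of years — separately, with all ties at the percentile cutoff
  included.
* Cell areas use the spherical-Earth quadrangle formula
  R²·Δλ·(sin φ_top − sin φ_bot), R = 6371 km. Majority resampling of the
  forest mask uses strict majority with an exact 50% tie resolving to
  non-forest (the conservative choice for a mask that gates area sums).
  Rasterization marks a cell when its center is inside or on the boundary of
  a perimeter polygon.

## Fire-weather indices

Constants live in one table (`fire_weather.CONSTANTS`) with their sources:
McArthur Mark 5 FFDI as formulated by Noble, Bary & Gill (1980); the metric
Keetch–Byram drought index (0–203.2 mm) with a 5.08 mm per-event
interception allowance; Griffiths (1999) drought factor; C-Haines per
Mills & McCaw (2010); dry lightning as lightning with daily rain < 2.5 mm.
Threshold comparisons (FFDI ≥ 25 "Very High", ≥ 50 "Severe") are inclusive.

Implementation choices:

* KBDI state is carried day to day together with the interception already
  charged to the current rain event (the allowance resets on a dry day);
  evapotranspiration is floored at 0 and the index clamped to [0, 203.2]
  for any input sequence.
* The drought factor's "last significant rain event" is tracked as the most
  recent *day* with rain above 2 mm (single-day events); multi-day event
  pooling is not implemented. The same-day case uses Griffiths' N = 0.8
  floor. A `kbdi_linear` fallback (10·K/203.2) is available as a simple
  monotone stand-in.
* `days_over_threshold` defaults to forming the daily spatial-mean FFDI
  over the forest mask and thresholding that single national series; a
  `per_pixel` mode counts exceedance days per pixel and averages spatially.
  Both are legitimate readings of "days over threshold averaged over
  forests"; the mode is recorded in the output metadata.
* Epoch-change maps are mean(epoch 2) − mean(epoch 1) per pixel over
  calendar years, with a percent-frequency variant for daily flags
  (dry-lightning occurrence).
* KBDI spin-up starts at half the maximum deficit with a 60-day-dry
  assumption unless overridden; the first season of output inherits this
  assumption.

## Trend layer

"Exponential" fits are OLS on ln(value); the growth rate is e^slope − 1 per
unit of the predictor (per year, or per threshold day). Predictors are
centered before fitting and coefficients reported back on the calendar
scale. Zeros are excluded from log fits with a logged count; negative
values are an error. p-values are classical two-sided t-tests without
autocorrelation correction by default (a Newey–West `hac_lags` option
exists). Two numerical conventions:

* For a numerically exact fit (zero residual sum of squares) the t statistic
  is 0/0; we report p = 1 when the slope is also numerically zero — a flat
  series carries no evidence of trend — and p = 0 for an exact non-zero
  slope. R² of a constant response is reported as 0.
* Held-out predictions are exp(a + b·x) with no retransformation
  (smearing) bias correction; predicting beyond the fitted predictor range
  warns rather than errors, because held-out prediction of an unprecedented
  season *is* an extrapolation.

The multivariate regression reports the base-predictor-only R² plus the
incremental R² of each further predictor added cumulatively in the given
order, with the pairwise predictor correlation matrix as the collinearity
diagnostic; a rank-deficient design raises and names the collinear columns.

## Synthetic data

The generators define the validation conditions:

* **Fire histories**: independent Bernoulli(p) wildfire occurrence per
  pixel-year (default p a few percent — decadal fire-return forests), at
  most one truth fire per pixel-year, matching the annual resolution of
  agency records. An optional logistic coupling modulates annual fire odds
  with a supplied fire-weather index; it is off by default so the
  closed-form geometric theory applies. Prescribed burns are a stationary
  process with a normal annual target area (truncated at zero).
* **Weather**: each variable is seasonal-mean + cosine cycle (hottest
  mid-January, RH/rain peaking in winter) + linear trend + Gaussian noise
  split into a domain-wide synoptic term and a per-pixel local term. RH is
  clipped to [0, 100], rain and wind to ≥ 0, and Td850 is generated as T850
  minus a non-negative dewpoint depression so Td850 ≤ T850 holds by
  construction. Lightning days are Bernoulli.
* **Monthly burned product**: each truth fire is assigned one month of its
  fire year by a 12-weight multinomial (mass concentrated in the Austral
  spring/summer), and a small configurable fraction of cells is flagged as
  burning in a second month — the feature that exercises the union rule.
* A single top-level seed spawns independent substreams per generator
  (`numpy.random.SeedSequence`), so all output is bit-reproducible and
  adding one generator never perturbs another.

What the generators do **not** emulate — and hence what passing tests do not
show about real data: spatial contagion and fire spread, burn severity,
spatially correlated fire occurrence, autocorrelated drought sequences,
observational detection error (satellite omission of low-intensity fires),
and changing record quality over time. Tests validate the *accounting and
inference machinery* under known truth, not the realism of any particular
fire regime.

One calendrical subtlety surfaces in exactness tests: the seasonal cosine
has period 365.25 days, which does not cancel identically over calendar
decades, so "trend/step recovered exactly" checks are run with the seasonal
amplitude set to zero (the residual otherwise is a few 0.001 °C, not an
implementation error).

## Problem sizes

Validation uses 100×100 grids over 90-year records for YSLF recovery (five
seeds, three p values, against a 100-replicate Monte-Carlo envelope of an
independently coded oracle), 10⁶ draws for the initializer distribution,
10⁴ replicates for slope-test calibration, and multi-year daily cubes on
small grids for the weather layer — sizes at which the Monte-Carlo errors
of the checked statistics are far smaller than the effects being checked,
while the full suite runs in seconds.

## Known limitations

* Polygon input is GeoJSON (field names configurable); ESRI shapefiles are
  out of scope. Grids are plain geographic lat/lon; the GDA94/WGS84 datum
  difference (< 2 m) is ignored as sub-pixel, and projected coordinate
  systems are not supported.
* Gridded FFDI products used operationally are calibrated against forecast
  networks; this package computes the meter formulas directly from weather
  inputs and will not byte-match such calibrated datasets.
* The drought-factor event model (single-day events, > 2 mm) is a
  simplification of multi-day rain-event pooling.
* No spatial statistics beyond masked means; no survival analysis of fire
  intervals; no attribution modelling.
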