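# firetrends

Analysis toolkit for multi-decadal forest fire activity of the kind studied
in temperate Australia: it reconstructs per-pixel **years since the last
wildfire (YSLF)** from annual agency fire histories, computes gridded
**fire-weather risk factors** (McArthur FFDI with a Keetch–Byram/Griffiths
drought factor, the continuous Haines index, dry-lightning days), aggregates
**burned area** by July–June fire year and Austral season under the
union/not-recounted rule, and fits the **trend and burned-area ~
fire-weather regressions** used to link burned area to changing fire
weather. A synthetic-data module generates fire histories, daily weather
cubes, and monthly burned rasters with known parameters, so every stage can
be validated against ground truth.

Intended users are fire ecologists and climate-impact analysts who want the
accounting conventions of national burned-area records (fire years, seasons,
union areas, cause splits, megafire definitions) and the standard Australian
fire-weather indices as tested, reusable code.

## The core model

A pixel's YSLF resets to 0 in each recorded wildfire year and increments by
1 otherwise. At the record origin (1930 for most agencies) the YSLF of a
pixel that did not burn that year is unknown; it is initialized by
inverse-transform sampling from the geometric distribution implied by a
Bernoulli(p) fire process, with p the pixel's record-wide mean wildfire
frequency:

    F⁻¹(u) = ⌈ ln(1 − u) / ln(1 − p) ⌉ ,   u ~ Uniform(0, 1),

which is exactly the stationary distribution of time-since-last-event given
no event this year, P(k) = p(1 − p)^(k−1), k ≥ 1. Estimated values are
incremented until the first in-record fire resets them, after which the
pixel is fully observed. Only pixels with ≥ 1 wildfire on record enter the
analysis; prescribed burns never reset YSLF.

Fire-weather indices follow their published forms — McArthur Mark 5
(Noble et al. 1980): FFDI = 2·exp(−0.450 + 0.987 ln DF − 0.0345 RH +
0.0338 T + 0.0234 V); Keetch–Byram drought index in mm (0–203.2) with
Griffiths' drought factor; C-Haines per Mills & McCaw (2010); dry lightning
as lightning on a day with < 2.5 mm of rain. "Exponential" trends are OLS on
the log response, so a slope b is a multiplicative e^b per unit — e.g. a 21%
increase in burned area per additional day of FFDI ≥ 25.

## Worked example

Reconstruct YSLF on a stationary synthetic history (100×100 pixels, 90
years, annual fire probability p = 0.05) and summarize by decade:

```python
import numpy as np, pandas as pd
from firetrends import synthetic as sd, yslf, trends

hist = sd.simulate_fire_history(
    sd.FireProcessParams(shape=(100, 100), start_year=1930, end_year=2019,
                         p=0.05, seed=42))
g = yslf.reconstruct(hist, seed=42)
for dec in (1980, 1990, 2000, 2010):
    m, s = yslf.decadal_summary(g, dec)
    print(f"{dec}s: {m:.1f} +/- {s:.1f} years")
```

```
1980s: 20.1 +/- 0.4 years
1990s: 19.2 +/- 0.3 years
2000s: 18.7 +/- 0.1 years
2010s: 18.4 +/- 0.1 years
```

The decadal means settle near the stationary expectation (1 − p)/p = 19
years (slightly below it, because pixels that never burn in 90 years are
excluded); the SD is the spread of the ten annual spatial means within each
decade. A trend fit on a growing burned-area series:

```python
t = np.arange(32.)
series = pd.Series(120 * 1.09**t * np.exp(np.random.default_rng(42).normal(0, .4, 32)),
                   index=np.arange(1988, 2020))
fit = trends.fit_exponential(series)
print(f"growth {100*fit.growth_rate:.1f}%/yr, p={fit.slope_pvalue:.4f}, R2={fit.r_squared:.2f}")
```

```
growth 10.0%/yr, p=0.0000, R2=0.88
```

i.e. the log-linear fit recovers the injected 9%/yr growth to within its
sampling noise, with a strongly significant slope.

The `firetrends` command line wraps the same stages: `firetrends run --seed 1`
executes the full simulate → aggregate → YSLF → fire-weather → trends
pipeline and writes CSV tables, a JSON report, and a manifest hashing every
output back to its (config, seed) pair; `firetrends simulate weather`,
`firetrends yslf`, `firetrends trends` expose individual stages.

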