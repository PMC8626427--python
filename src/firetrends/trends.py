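"""Trend and burned-area ~ fire-weather regression layer.

"Exponential" fits are ordinary least squares on the log response (so a
fitted slope b means a multiplicative factor e^b per unit of the predictor);
a nonlinear least-squares alternative is available behind a flag for
sensitivity checks. Fire-year indices are centered before fitting for
conditioning, and coefficients are reported back on the calendar-year scale.
p-values are classical two-sided OLS t-tests with no autocorrelation
correction by default; a HAC (Newey–West) option is provided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .burned_area import FireYearSeries

__all__ = [
    "TrendFitResult",
    "MultivariateFitResult",
    "fit_linear",
    "fit_exponential",
    "percent_change_halves",
    "fit_burned_vs_ffdi",
    "fit_multivariate",
    "predict_held_out",
    "slope_test_pvalues",
]

logger = logging.getLogger(__name__)


@dataclass
class TrendFitResult:
    """A fitted linear or log-linear (exponential) trend.

    ``slope`` and ``intercept`` are on the fitting scale (log response for
    log-linear models, uncentered x). ``growth_rate`` = e^slope − 1 for
    log-linear fits, i.e. the fractional increase per unit of x.
    ``predict`` returns values on the response scale.
    """

    model: str
    intercept: float
    slope: float
    slope_pvalue: float
    r_squared: float
    n: int
    residuals: np.ndarray
    x_name: str = "year"
    x_values: np.ndarray = field(default_factory=lambda: np.array([]))
    growth_rate: float | None = None
    n_dropped_nonpositive: int = 0

    def linear_predictor(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def predict(self, x):
        eta = self.linear_predictor(x)
        return np.exp(eta) if self.model == "log-linear" else eta

    @property
    def per_unit_multiplier(self) -> float:
        if self.model != "log-linear":
            raise ValueError("multiplier is defined for log-linear fits only")
        return float(np.exp(self.slope))


def _as_xy(series: FireYearSeries | pd.Series) -> tuple[np.ndarray, np.ndarray]:
    s = series.values if isinstance(series, FireYearSeries) else pd.Series(series)
    return s.index.to_numpy(dtype=float), s.to_numpy(dtype=float)


def _ols(y: np.ndarray, x: np.ndarray, hac_lags: int | None = None):
    xc = x - x.mean()
    X = sm.add_constant(xc)
    model = sm.OLS(y, X)
    res = model.fit(cov_type="HAC", cov_kwds={"maxlags": hac_lags}) if hac_lags else model.fit()
    slope = float(res.params[1])
    intercept = float(res.params[0] - slope * x.mean())  # back to uncentered scale
    return res, intercept, slope


def _slope_pvalue(res, y: np.ndarray, slope: float) -> float:
    """Two-sided slope p-value with a convention for numerically exact fits.

    When the residual sum of squares is zero to machine precision the t
    statistic is 0/0; we report 1 for a (numerically) zero slope — a flat
    series carries no evidence of a trend — and 0 for an exact non-zero one.
    """
    scale = max(float(np.ptp(y)), abs(float(np.mean(y))), 1.0)
    sse = float(np.sum(np.asarray(res.resid) ** 2))
    if sse <= (1e-10 * scale) ** 2 * y.size:
        return 1.0 if abs(slope) <= 1e-10 * scale else 0.0
    return float(res.pvalues[1])



def _r_squared(res) -> float:
    """R² guarded for zero total variance (constant response): reported as 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(res.rsquared)
    return r2 if np.isfinite(r2) else 0.0

def fit_linear(
    series: FireYearSeries | pd.Series, hac_lags: int | None = None
) -> TrendFitResult:
    """OLS linear trend of a fire-year series, two-sided t-test on the slope."""
    x, y = _as_xy(series)
    if x.size < 3:
        raise ValueError("need at least 3 points for a trend fit")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor (all fire years identical)")
    res, intercept, slope = _ols(y, x, hac_lags)
    return TrendFitResult(
        model="linear",
        intercept=intercept,
        slope=slope,
        slope_pvalue=_slope_pvalue(res, y, slope),
        r_squared=_r_squared(res),
        n=int(x.size),
        residuals=np.asarray(res.resid),
        x_values=x,
    )


def fit_exponential(
    series: FireYearSeries | pd.Series,
    hac_lags: int | None = None,
    nonlinear: bool = False,
) -> TrendFitResult:
    """Exponential trend: OLS on ln(value) vs fire year.

    Zero values are excluded (with a logged count); negative values are an
    error. ``growth_rate`` = e^slope − 1 is the mean fractional growth per
    year. With ``nonlinear=True`` the curve a·e^{b·x} is instead fitted by
    nonlinear least squares on the response scale (sensitivity option; the
    reported p-value and R² still come from the log-scale OLS).
    """
    x, y = _as_xy(series)
    if np.any(y < 0):
        raise ValueError("negative values cannot enter an exponential fit")
    keep = y > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("fit_exponential: excluded %d zero values from log fit", n_dropped)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 positive points for an exponential fit")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor (all fire years identical)")
    logy = np.log(y)
    res, intercept, slope = _ols(logy, x, hac_lags)
    if nonlinear:
        xm = x.mean()
        popt, _ = optimize.curve_fit(
            lambda t, a, b: a * np.exp(b * (t - xm)), x, y,
            p0=(float(np.exp(res.params[0])), slope), maxfev=10000,
        )
        slope = float(popt[1])
        intercept = float(np.log(popt[0]) - slope * xm)
    return TrendFitResult(
        model="log-linear",
        intercept=intercept,
        slope=slope,
        slope_pvalue=_slope_pvalue(res, logy, slope),
        r_squared=_r_squared(res),
        n=int(x.size),
        residuals=np.asarray(res.resid),
        growth_rate=float(np.expm1(slope)),
        n_dropped_nonpositive=n_dropped,
        x_values=x,
    )


def percent_change_halves(
    series: FireYearSeries | pd.Series, split_year: int
) -> float:
    """Percent change in the mean between record halves: 100·(m2/m1 − 1).

    The first half is fire years strictly before ``split_year``. A six-fold
    mean ("five-fold increase" in common usage) reports as 500%.
    """
    x, y = _as_xy(series)
    first = y[x < split_year]
    second = y[x >= split_year]
    if first.size == 0 or second.size == 0:
        raise ValueError("both halves must be non-empty")
    m1 = first.mean()
    if m1 <= 0:
        raise ValueError("first-half mean must be positive")
    return float(100.0 * (second.mean() / m1 - 1.0))


def fit_burned_vs_ffdi(
    area_series: FireYearSeries | pd.Series,
    days_series: FireYearSeries | pd.Series,
    hac_lags: int | None = None,
) -> TrendFitResult:
    """Exponential regression of burned area on FFDI threshold-day counts.

    ln(area) ~ days; the per-day multiplier e^b is reported through
    ``growth_rate`` (e.g. 0.21 for a 21% increase in burned area per
    additional day at or above the threshold). Series are aligned on their
    common fire years; disjoint series are an error.
    """
    a = (area_series.values if isinstance(area_series, FireYearSeries) else pd.Series(area_series)).astype(float)
    d = (days_series.values if isinstance(days_series, FireYearSeries) else pd.Series(days_series)).astype(float)
    joined = pd.concat({"area": a, "days": d}, axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("series share too few fire years (misaligned inputs?)")
    y = joined["area"].to_numpy()
    x = joined["days"].to_numpy()
    if np.any(y <= 0):
        raise ValueError("burned area must be positive for the log fit")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor (threshold-day counts do not vary)")
    logy = np.log(y)
    res, intercept, slope = _ols(logy, x, hac_lags)
    return TrendFitResult(
        model="log-linear",
        intercept=intercept,
        slope=slope,
        slope_pvalue=_slope_pvalue(res, logy, slope),
        r_squared=_r_squared(res),
        n=int(len(joined)),
        residuals=np.asarray(res.resid),
        growth_rate=float(np.expm1(slope)),
        x_name="days",
        x_values=x,
    )


@dataclass
class MultivariateFitResult:
    """Multivariate ln(area) regression with variance decomposition.

    ``r2_base`` is the R² of the base-predictor-only model; ``delta_r2`` maps
    each further predictor (in addition order) to its incremental R² when
    added cumulatively. ``correlations`` is the pairwise predictor
    correlation matrix (collinearity diagnostic).
    """

    params: pd.Series
    pvalues: pd.Series
    r_squared: float
    r2_base: float
    delta_r2: dict[str, float]
    correlations: pd.DataFrame
    n: int
    base_predictor: str

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(data[self.params.index.drop("const")], has_constant="add")
        return np.exp(X.to_numpy() @ self.params.to_numpy())


def fit_multivariate(
    data: pd.DataFrame,
    response: str = "area",
    predictors: tuple[str, ...] = ("ffdi25_days", "ffdi50_days", "c_haines", "dry_lightning_days"),
    base_predictor: str | None = None,
) -> MultivariateFitResult:
    """OLS of ln(response) on fire-weather predictors with ΔR² accounting.

    Fits the base predictor alone, then adds the remaining predictors one at
    a time (in the given order), recording each incremental R². Predictor
    collinearity is reported as the pairwise correlation matrix; a
    rank-deficient design raises and names the offending columns.
    """
    predictors = tuple(p for p in predictors if p in data.columns)
    if not predictors:
        raise ValueError("no predictors found in data")
    if data[list(predictors) + [response]].isna().any().any():
        raise ValueError("missing values in regression data")
    n = len(data)
    if n <= len(predictors) + 1:
        raise ValueError("need n > predictors + 1 observations")
    y = np.log(data[response].to_numpy(dtype=float))
    X_full = data[list(predictors)].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X_full]))
    if rank < len(predictors) + 1:
        corr = np.corrcoef(X_full, rowvar=False)
        pairs = [
            (predictors[i], predictors[j])
            for i in range(len(predictors))
            for j in range(i + 1, len(predictors))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear predictors: {pairs or list(predictors)}")

    base = base_predictor or predictors[0]
    order = [base] + [p for p in predictors if p != base]
    r2 = {}
    last = None
    for k in range(1, len(order) + 1):
        X = sm.add_constant(data[order[:k]].to_numpy(dtype=float))
        last = sm.OLS(y, X).fit()
        r2[order[k - 1]] = float(last.rsquared)
    delta = {
        name: r2[name] - (list(r2.values())[i - 1] if i else 0.0)
        for i, name in enumerate(order)
        if i > 0
    }
    params = pd.Series(last.params, index=["const"] + order)
    pvalues = pd.Series(last.pvalues, index=["const"] + order)
    return MultivariateFitResult(
        params=params,
        pvalues=pvalues,
        r_squared=float(last.rsquared),
        r2_base=r2[base],
        delta_r2=delta,
        correlations=data[list(predictors)].corr(),
        n=n,
        base_predictor=base,
    )


def predict_held_out(
    fit: TrendFitResult, predictor_value: float, guard: float = 0.0
) -> float:
    """Point prediction for a held-out year on the response scale.

    For log-linear fits this is exp(a + b·x) with no retransformation bias
    correction (the convention documented in docs/methods.md). A predictor
    outside the training range (stretched by ``guard`` as a fraction of the
    range) emits an extrapolation warning rather than an error — predicting
    an unprecedented season is exactly such an extrapolation.
    """
    x = float(predictor_value)
    if fit.x_values.size:
        lo, hi = fit.x_values.min(), fit.x_values.max()
        pad = guard * (hi - lo)
        if x < lo - pad or x > hi + pad:
            warnings.warn(
                f"predictor {x:g} outside the fitted range [{lo:g}, {hi:g}]; "
                "prediction is an extrapolation",
                stacklevel=2,
            )
    return float(fit.predict(x))


def slope_test_pvalues(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Vectorized two-sided OLS slope t-test over replicate rows of y.

    ``y`` is (n_reps, n); ``x`` is (n,). Returns one p-value per row,
    identical to :func:`fit_linear`'s ``slope_pvalue`` (used for the
    type-I-error calibration of the trend layer at simulation scale).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    slopes = y @ xc / sxx
    fitted = y.mean(axis=1, keepdims=True) + slopes[:, None] * xc
    sse = np.sum((y - fitted) ** 2, axis=1)
    se = np.sqrt(sse / (n - 2) / sxx)
    tstat = slopes / se
    return 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
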