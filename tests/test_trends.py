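"""Trend layer: exact recoveries, test calibration, regression accounting."""

import numpy as np
import pandas as pd
import pytest

from firetrends.trends import (
    fit_burned_vs_ffdi,
    fit_exponential,
    fit_linear,
    fit_multivariate,
    percent_change_halves,
    predict_held_out,
    slope_test_pvalues,
)

YEARS = np.arange(1988, 2020)


def series(values, years=None):
    years = YEARS[: len(values)] if years is None else years
    return pd.Series(np.asarray(values, float), index=years[: len(values)])


class TestFitLinear:
    def test_exact_line_recovered(self):
        t = np.arange(32.0)
        fit = fit_linear(series(2 * t + 1, YEARS))
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope_pvalue == 0.0
        np.testing.assert_allclose(fit.predict(YEARS), 2 * t + 1, atol=1e-8)

    def test_constant_series_has_no_trend_evidence(self):
        fit = fit_linear(series(np.full(20, 7.0)))
        assert fit.slope == pytest.approx(0.0, abs=1e-10)
        assert fit.slope_pvalue == 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_linear(series([1.0, 2.0]))

    def test_type_one_error_near_nominal(self, rng):
        """Under the null, the slope t-test rejects ~5% of the time at alpha=0.05."""
        n, reps = 30, 10_000
        y = rng.normal(size=(reps, n))
        x = np.arange(n, dtype=float)
        pvals = slope_test_pvalues(y, x)
        rate = (pvals < 0.05).mean()
        assert 0.04 < rate < 0.06

    def test_vectorized_pvalues_match_fit_linear(self, rng):
        n = 25
        y = rng.normal(size=(3, n)) + rng.normal(scale=0.1) * np.arange(n)
        x = np.arange(n, dtype=float)
        pv = slope_test_pvalues(y, x)
        for i in range(3):
            f = fit_linear(pd.Series(y[i], index=1990 + x.astype(int)))
            assert pv[i] == pytest.approx(f.slope_pvalue, rel=1e-10)


class TestFitExponential:
    def test_exact_growth_rate_recovered(self):
        t = np.arange(32.0)
        fit = fit_exponential(series(100 * 1.14**t, YEARS))
        assert fit.growth_rate == pytest.approx(0.14, abs=1e-12)
        assert fit.slope_pvalue == 0.0

    def test_constant_series_zero_growth(self):
        fit = fit_exponential(series(np.full(10, 42.0)))
        assert fit.growth_rate == pytest.approx(0.0, abs=1e-12)
        assert fit.slope_pvalue == 1.0

    def test_zeros_excluded_with_count(self):
        vals = np.full(10, 5.0)
        vals[[2, 6]] = 0.0
        fit = fit_exponential(series(vals))
        assert fit.n == 8
        assert fit.n_dropped_nonpositive == 2

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            fit_exponential(series([1.0, -2.0, 3.0]))

    def test_scale_equivariance_of_growth_rate(self, rng):
        vals = np.exp(rng.normal(size=20)) * 50
        base = fit_exponential(series(vals)).growth_rate
        for c in (0.01, 3.7, 1e4):
            assert fit_exponential(series(c * vals)).growth_rate == pytest.approx(base, rel=1e-9)

    def test_simulation_recovers_known_rate(self, rng):
        """Log-linear fits on lognormal-noise growth series are unbiased
        within 1% absolute over 1000 replicates (n=32, sigma=0.3)."""
        true_rate = 0.14
        t = np.arange(32.0)
        reps = 1000
        logy = np.log(100.0) + np.log1p(true_rate) * t + rng.normal(0, 0.3, (reps, 32))
        xc = t - t.mean()
        slopes = logy @ xc / np.sum(xc**2)
        rates = np.expm1(slopes)
        assert abs(rates.mean() - true_rate) < 0.01
        # spot-check the vectorized oracle against the package fit
        f = fit_exponential(series(np.exp(logy[0]), YEARS))
        assert f.growth_rate == pytest.approx(rates[0], rel=1e-9)

    def test_nonlinear_option_agrees_on_noiseless_data(self):
        t = np.arange(20.0)
        fit = fit_exponential(series(100 * 1.1**t), nonlinear=True)
        assert fit.growth_rate == pytest.approx(0.1, abs=1e-8)


class TestPercentChange:
    def test_matches_definition(self):
        s = series([2.0] * 7 + [9.0] * 7, np.arange(1988, 2002))
        assert percent_change_halves(s, 1995) == pytest.approx(350.0)

    def test_equal_means_zero(self):
        s = series([5.0] * 10)
        assert percent_change_halves(s, 1993) == pytest.approx(0.0)

    def test_sixfold_is_500pct(self):
        s = series([1.0] * 5 + [6.0] * 5)
        assert percent_change_halves(s, 1993) == pytest.approx(500.0)

    def test_zero_first_half_rejected(self):
        s = series([0.0] * 5 + [6.0] * 5)
        with pytest.raises(ValueError):
            percent_change_halves(s, 1993)


class TestBurnedVsFFDI:
    def test_exact_multiplier_recovered(self, rng):
        days = series(rng.integers(0, 25, 31).astype(float), YEARS)
        area = series(50 * 1.21 ** days.to_numpy(), YEARS)
        fit = fit_burned_vs_ffdi(area, days)
        assert 100 * fit.growth_rate == pytest.approx(21.0, abs=1e-9)
        assert fit.per_unit_multiplier == pytest.approx(1.21, abs=1e-10)

    def test_constant_predictor_rejected(self):
        days = series(np.full(10, 4.0))
        area = series(np.linspace(10, 100, 10))
        with pytest.raises(ValueError, match="constant"):
            fit_burned_vs_ffdi(area, days)

    def test_misaligned_series_rejected(self):
        area = series(np.linspace(10, 100, 10), np.arange(1988, 1998))
        days = series(np.arange(10.0), np.arange(2010, 2020))
        with pytest.raises(ValueError, match="fire years"):
            fit_burned_vs_ffdi(area, days)

    def test_noisy_multiplier_within_simulation_envelope(self, rng):
        """With lognormal noise (sigma=0.3, n=31) the estimated per-day rate
        stays inside a pre-computed Monte-Carlo envelope around 21%."""
        days = rng.integers(0, 25, 31).astype(float)
        xc = days - days.mean()
        sxx = np.sum(xc**2)
        # envelope: slope SE = sigma/sqrt(sxx); 4 SE in rate terms
        se_rate = 1.21 * 0.3 / np.sqrt(sxx)
        for seed in range(5):
            noise = np.random.default_rng(seed).normal(0, 0.3, 31)
            area = 50 * 1.21**days * np.exp(noise)
            fit = fit_burned_vs_ffdi(series(area, YEARS), series(days, YEARS))
            assert abs(fit.per_unit_multiplier - 1.21) < 4 * se_rate


class TestMultivariate:
    def make_data(self, rng, n=32):
        ffdi25 = rng.uniform(5, 30, n)
        ffdi50 = rng.uniform(0, 8, n)
        ch = rng.uniform(4, 12, n)
        dl = rng.uniform(0, 20, n)
        return pd.DataFrame(
            {"ffdi25_days": ffdi25, "ffdi50_days": ffdi50, "c_haines": ch, "dry_lightning_days": dl},
            index=np.arange(1988, 1988 + n),
        )

    def test_ffdi_only_signal_gives_negligible_delta_r2(self, rng):
        data = self.make_data(rng)
        data["area"] = 30 * np.exp(0.2 * data["ffdi25_days"] + rng.normal(0, 0.1, len(data)))
        res = fit_multivariate(data)
        assert res.r2_base > 0.9
        assert all(d < 0.02 for d in res.delta_r2.values())

    def test_orthogonal_predictors_recover_variance_shares(self, rng):
        n = 4000
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        data = pd.DataFrame({"ffdi25_days": a, "c_haines": b}, index=np.arange(n))
        data["area"] = np.exp(1.0 * a + 1.0 * b + rng.normal(0, 1.0, n))
        res = fit_multivariate(data, predictors=("ffdi25_days", "c_haines"))
        # each orthogonal predictor contributes ~1/3 of log-variance
        assert res.r2_base == pytest.approx(1 / 3, abs=0.05)
        assert res.delta_r2["c_haines"] == pytest.approx(1 / 3, abs=0.05)

    def test_r2_nondecreasing_as_predictors_added(self, rng):
        data = self.make_data(rng)
        data["area"] = np.exp(rng.normal(3, 0.5, len(data)))
        res = fit_multivariate(data)
        assert res.r_squared >= res.r2_base - 1e-12
        assert all(d >= -1e-12 for d in res.delta_r2.values())

    def test_duplicate_predictor_rejected(self, rng):
        data = self.make_data(rng)
        data["dup"] = data["ffdi25_days"]
        data["area"] = np.exp(rng.normal(3, 0.5, len(data)))
        with pytest.raises(ValueError, match="collinear"):
            fit_multivariate(data, predictors=("ffdi25_days", "dup"))


class TestPredictHeldOut:
    def test_log_linear_prediction_is_exp_of_linear_predictor(self, rng):
        days = series(rng.uniform(2, 20, 20))
        area = series(40 * 1.15 ** days.to_numpy() * np.exp(rng.normal(0, 0.2, 20)))
        fit = fit_burned_vs_ffdi(area, days)
        x = 10.0
        assert predict_held_out(fit, x) == pytest.approx(
            np.exp(fit.intercept + fit.slope * x)
        )

    def test_prediction_at_mean_is_geometric_mean_of_fitted(self, rng):
        days = series(rng.uniform(2, 20, 20))
        area = series(40 * 1.15 ** days.to_numpy() * np.exp(rng.normal(0, 0.2, 20)))
        fit = fit_burned_vs_ffdi(area, days)
        xbar = days.mean()
        pred = predict_held_out(fit, xbar)
        # OLS identity: the fit passes through (x̄, ȳ) on the log scale
        geo_mean = np.exp(np.mean(np.log(area.to_numpy()) - fit.residuals))
        fitted_geo = np.exp(np.mean(fit.linear_predictor(days.to_numpy())))
        assert pred == pytest.approx(fitted_geo, rel=1e-10)
        assert pred == pytest.approx(geo_mean, rel=1e-10)

    def test_extrapolation_warns(self, rng):
        days = series(rng.uniform(2, 20, 20))
        area = series(40 * 1.15 ** days.to_numpy())
        fit = fit_burned_vs_ffdi(area, days)
        with pytest.warns(UserWarning, match="extrapolation"):
            predict_held_out(fit, 60.0)
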