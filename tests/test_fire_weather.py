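"""Fire-weather indices: KBDI bounds, drought factor, FFDI and C-Haines
formulas and monotonicity, dry lightning, day counts and epoch changes."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from firetrends.fire_weather import (
    CONSTANTS,
    KBDI_MAX_MM,
    chaines,
    compute_indices,
    days_over_threshold,
    drought_factor,
    dry_lightning,
    epoch_change,
    epoch_frequency_change_pct,
    ffdi,
    kbdi_series,
    kbdi_update,
)
from firetrends.synthetic import WeatherGenParams, simulate_weather


class TestKBDI:
    def test_heavy_rain_saturates_to_zero(self):
        q, _ = kbdi_update(150.0, 300.0, 5.0, 1000.0)
        assert q == pytest.approx(0.0, abs=0.5)  # small same-day ET increment

    def test_prolonged_drought_approaches_cap(self):
        rain = np.zeros(3000)
        tmax = np.full(3000, 40.0)
        series = kbdi_series(rain[:, None], tmax[:, None], 500.0, kbdi0=0.0)
        assert series[-1, 0] == pytest.approx(KBDI_MAX_MM, abs=1e-6)

    def test_dry_day_increment_matches_closed_form(self):
        c = CONSTANTS["kbdi"]
        q0, tmax, annual = 100.0, 30.0, 800.0
        expected_et = (
            (c["max_mm"] - q0)
            * (c["et1"] * np.exp(c["et2"] * tmax + c["et3"]) - c["et4"])
            * 1e-3
            / (1 + c["et5"] * np.exp(-c["et6"] * annual))
        )
        q1, _ = kbdi_update(q0, 0.0, tmax, annual)
        assert q1 - q0 == pytest.approx(expected_et, rel=1e-12)

    def test_interception_allowance_within_event(self):
        # day 1 of an event: first 5.08 mm intercepted
        q1, carry = kbdi_update(100.0, 4.0, 0.0, 800.0)
        assert q1 == pytest.approx(100.0, abs=0.2)  # nothing effective yet
        # day 2 same event: allowance mostly used up
        q2, _ = kbdi_update(q1, 4.0, 0.0, 800.0, interception_carry=carry)
        assert q2 == pytest.approx(q1 - (4.0 - (5.08 - 4.0)), abs=0.2)

    def test_bounded_on_adversarial_sequences(self, rng):
        rain = rng.choice([0.0, 0.1, 2.0, 60.0, 300.0], size=(1500, 4))
        tmax = rng.uniform(-10, 50, size=(1500, 4))
        series = kbdi_series(rain, tmax, 700.0)
        assert (series >= 0).all() and (series <= KBDI_MAX_MM).all()

    def test_negative_rain_rejected(self):
        with pytest.raises(ValueError):
            kbdi_update(10.0, -1.0, 20.0, 800.0)


class TestDroughtFactor:
    def test_right_after_large_rain_is_small(self):
        assert drought_factor(10.0, 0, 80.0) < 1.0

    def test_long_drought_at_kbdi_cap_reaches_ten(self):
        assert drought_factor(KBDI_MAX_MM, 100, 0.0) == 10.0

    def test_mid_range_matches_formula_oracle(self):
        k, n, p_evt = 80.0, 10, 12.0
        x = n**1.3 / (n**1.3 + p_evt - 2)
        xlim = 75 / (270.525 - 1.267 * k)
        x = min(x, xlim)
        expected = min(
            10.0,
            10.5 * (1 - np.exp(-(k + 30) / 40)) * (41 * x**2 + x) / (40 * x**2 + x + 1),
        )
        assert drought_factor(k, n, p_evt) == pytest.approx(expected, rel=1e-12)

    def test_nondecreasing_in_days_since_rain(self):
        vals = [drought_factor(60.0, n, 20.0) for n in range(0, 60, 3)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_linear_fallback(self):
        assert drought_factor(KBDI_MAX_MM / 2, 5, 5.0, method="kbdi_linear") == 5.0


class TestFFDI:
    def test_zero_drought_factor_maps_to_zero(self):
        assert ffdi(35.0, 20.0, 30.0, 0.0) == 0.0

    def test_wind_increment_doubles_index(self):
        # e^(0.0234 * 29.6) = 1.999...: +29.6 km/h doubles FFDI
        base = ffdi(30.0, 30.0, 10.0, 8.0)
        faster = ffdi(30.0, 30.0, 39.6, 8.0)
        assert faster / base == pytest.approx(np.exp(0.0234 * 29.6), rel=1e-12)
        assert faster / base == pytest.approx(2.0, abs=2e-3)

    def test_monotonicity_at_1000_random_states(self, rng):
        n = 1000
        t = rng.uniform(-5, 48, n)
        rh = rng.uniform(0, 100, n)
        v = rng.uniform(0, 90, n)
        df = rng.uniform(0.5, 10, n)
        base = ffdi(t, rh, v, df)
        assert (ffdi(t + 1, rh, v, df) > base).all()
        assert (ffdi(t, rh, np.minimum(v + 5, 1e9), df) > base).all()
        assert (ffdi(t, np.maximum(rh - 1, 0), v, df) >= base).all()
        assert (ffdi(t, rh, v, np.minimum(df * 1.1, 10)) > base).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ffdi(30.0, 120.0, 10.0, 5.0)
        with pytest.raises(ValueError):
            ffdi(30.0, 50.0, -1.0, 5.0)


class TestCHaines:
    def test_saturated_zero_lapse_case(self):
        ch, ca, cb = chaines(10.0, 10.0, 10.0, components=True)
        assert (ca, cb, ch) == (-2.0, -1.0, -3.0)

    def test_dewpoint_depression_capped_at_30(self):
        assert chaines(20.0, 5.0, -15.0) == chaines(20.0, 5.0, -40.0)

    def test_mid_range_hand_computation(self):
        # CA = 0.5*(20-5) - 2 = 5.5; DD = 15 -> CB = 4; CH = 9.5
        assert chaines(20.0, 5.0, 5.0) == pytest.approx(9.5)

    def test_cb_excess_above_five_is_halved(self):
        # DD = 24 -> raw CB = 7 -> 5 + (7-5)/2 = 6; CA = -2
        assert chaines(10.0, 24.0, -14.0, components=True)[2] == pytest.approx(6.0)

    def test_component_dependencies(self, rng):
        t8 = rng.uniform(0, 25, 50)
        t7 = rng.uniform(-10, 15, 50)
        dd = rng.uniform(0, 40, 50)
        _, ca, cb = chaines(t8, t7, t8 - dd, components=True)
        # CA depends only on the 850-700 lapse; CB only on the dewpoint depression
        _, ca2, cb2 = chaines(t8 + 5, t7 + 5, t8 + 5 - dd, components=True)
        np.testing.assert_allclose(ca2, ca)
        np.testing.assert_allclose(cb2, cb)

    def test_dewpoint_above_temperature_rejected(self):
        with pytest.raises(ValueError, match="dewpoint"):
            chaines(10.0, 5.0, 12.0)


class TestDryLightning:
    @pytest.mark.parametrize(
        "lightning,rain,expected",
        [(True, 1.0, True), (True, 3.0, False), (False, 0.0, False), (True, 2.5, False)],
    )
    def test_threshold_rule(self, lightning, rain, expected):
        assert dry_lightning(lightning, rain) is expected

    def test_dry_lightning_subset_of_lightning(self, rng):
        lightning = rng.random(500) < 0.3
        rain = rng.exponential(2.0, 500)
        dl = dry_lightning(lightning, rain)
        assert not (dl & ~lightning).any()


def _daily_da(values, start="2000-07-01"):
    values = np.asarray(values, float)
    time = pd.date_range(start, periods=values.shape[0], freq="D")
    return xr.DataArray(
        values[:, None, None],
        coords={"time": time, "lat": [0.0], "lon": [0.0]},
        dims=("time", "lat", "lon"),
    )


class TestDaysOverThreshold:
    def test_counts_from_constructed_series(self):
        time = pd.date_range("2000-07-01", "2001-06-30", freq="D")
        vals = np.zeros(time.size)
        vals[:4] = [10, 26, 50, 70]
        da = _daily_da(vals)
        da = da.assign_coords(time=time)
        s25 = days_over_threshold(da, None, 25)
        s50 = days_over_threshold(da, None, 50)
        assert s25.values[2000] == 3
        assert s50.values[2000] == 2

    def test_threshold_nesting(self):
        cube = simulate_weather(WeatherGenParams(shape=(3, 3), seed=2), range(2000, 2004))
        idx = compute_indices(cube)
        c25 = days_over_threshold(idx["ffdi"], None, 25).values
        c50 = days_over_threshold(idx["ffdi"], None, 50).values
        assert (c50 <= c25).all()

    def test_incomplete_year_raises_when_strict(self):
        da = _daily_da(np.zeros(100))
        with pytest.raises(ValueError, match="incomplete"):
            days_over_threshold(da, None, 25, drop_incomplete=False)
        assert len(days_over_threshold(da, None, 25)) == 0


class TestEpochChange:
    def test_injected_step_recovered_exactly_at_zero_noise(self):
        time = pd.date_range("1980-01-01", "2019-12-31", freq="D")
        vals = np.where(time.year >= 2000, 21.0, 20.0)
        da = _daily_da(vals, start="1980-01-01").assign_coords(time=time)
        change = epoch_change(da, (1980, 1999), (2000, 2019))
        assert float(change[0, 0]) == pytest.approx(1.0, abs=1e-12)

    def test_missing_years_rejected(self):
        da = _daily_da(np.zeros(366), start="2000-01-01")
        with pytest.raises(ValueError, match="missing"):
            epoch_change(da, (1980, 1999), (2000, 2019))

    def test_doubled_flag_frequency_is_100pct(self):
        time = pd.date_range("1980-01-01", "2016-12-31", freq="D")
        flags = np.where(time.year >= 2000, (time.dayofyear % 5 == 0), (time.dayofyear % 10 == 0))
        da = _daily_da(flags.astype(float), start="1980-01-01").assign_coords(time=time)
        pct = epoch_frequency_change_pct(da, (1980, 1999), (2000, 2016))
        assert float(pct[0, 0]) == pytest.approx(100.0, abs=3.0)

    def test_stationary_climate_change_near_zero(self):
        cube = simulate_weather(WeatherGenParams(shape=(4, 4), seed=13), range(1990, 2010))
        change = epoch_change(cube["tmax"], (1990, 1999), (2000, 2009))
        # null sampling envelope: synoptic sd 4, ~3653 days per epoch with
        # shared synoptic noise -> SE of epoch-mean difference ~ 0.094
        assert float(np.abs(change).max()) < 4 * 0.094


class TestComputeIndices:
    def test_output_variables_and_invariants(self):
        cube = simulate_weather(WeatherGenParams(shape=(3, 3), seed=5), [2000, 2001])
        idx = compute_indices(cube)
        assert set(idx.data_vars) == {"kbdi", "drought_factor", "ffdi", "c_haines", "dry_lightning"}
        assert float(idx["kbdi"].min()) >= 0 and float(idx["kbdi"].max()) <= KBDI_MAX_MM
        assert float(idx["drought_factor"].min()) >= 0
        assert float(idx["drought_factor"].max()) <= 10
        assert float(idx["ffdi"].min()) >= 0
        dl = idx["dry_lightning"].to_numpy()
        assert not (dl & ~cube["lightning"].to_numpy()).any()

    def test_missing_variable_rejected(self):
        cube = simulate_weather(WeatherGenParams(shape=(2, 2), seed=5), [2000]).drop_vars("wind")
        with pytest.raises(ValueError, match="wind"):
            compute_indices(cube)
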