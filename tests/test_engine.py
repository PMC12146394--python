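"""Daily process model: phenology, stress, interception, and season runs."""

import datetime as dt
import math

import numpy as np
import pytest

import peppersim as ps
from peppersim.engine import (
    SimState,
    hargreaves_pet,
    ndilution_coeffs,
    realized_harvest_index,
)

PLANTING = dt.date(2022, 5, 3)


class TestHeatUnits:
    @pytest.mark.parametrize(
        "tmax,tmin,expected",
        [
            (30, 20, 15.0),   # mean 25, base 10
            (12, 4, 0.0),     # mean below base
            (40, 34, 20.0),   # mean 37 capped at TB - TG
        ],
    )
    def test_values(self, tmax, tmin, expected):
        assert ps.heat_units(tmax, tmin, TG=10, TB=30) == pytest.approx(expected)

    def test_rejects_inverted_cardinal_temperatures(self):
        with pytest.raises(ValueError):
            ps.heat_units(30, 20, TG=30, TB=10)


class TestTemperatureStress:
    def test_anchors(self):
        assert ps.temperature_stress(30, 10, 30) == pytest.approx(1.0)
        assert ps.temperature_stress(10, 10, 30) == 0.0
        assert ps.temperature_stress(20, 10, 30) == pytest.approx(math.sin(math.pi / 4))

    @pytest.mark.parametrize("tavg", [-5, 9.9, 50.1, 60])
    def test_zero_outside_viable_range(self, tavg):
        assert ps.temperature_stress(tavg, 10, 30) == 0.0

    def test_bounded(self):
        for t in np.linspace(-10, 60, 141):
            assert 0.0 <= ps.temperature_stress(float(t), 10, 30) <= 1.0


class TestInterception:
    def test_limits(self):
        assert ps.intercepted_par(20, 0) == 0.0
        assert ps.intercepted_par(0, 3) == 0.0
        assert ps.intercepted_par(20, 1e6) == pytest.approx(10.0)

    def test_beer_law_value(self):
        expected = 0.5 * 18 * (1 - math.exp(-0.65 * 2.0))
        assert ps.intercepted_par(18, 2.0, 0.65) == pytest.approx(expected)


class TestNDilutionCurve:
    @pytest.mark.parametrize("anchors", [
        (0.03, 0.007, 0.003),
        (0.03, 0.003, 0.001),
        (0.03, 0.006, 0.003),
    ])
    def test_anchors_hit(self, anchors):
        bn1, bn2, bn3 = anchors
        assert ps.optimal_n_fraction(0.0, *anchors) == pytest.approx(bn1, rel=1e-9)
        assert ps.optimal_n_fraction(1.0, *anchors) == pytest.approx(bn3, rel=1e-9)

    def test_midseason_close_for_all_registry_sets(self, all_greenhouse_sets):
        for p in all_greenhouse_sets:
            got = ps.optimal_n_fraction(0.5, p.BN1, p.BN2, p.BN3)
            assert got == pytest.approx(p.BN2, rel=0.10)

    def test_nonincreasing(self):
        vals = [ps.optimal_n_fraction(h, 0.03, 0.007, 0.003) for h in np.linspace(0, 1.2, 60)]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_rejects_non_monotone_anchors(self):
        with pytest.raises(ValueError):
            ndilution_coeffs(0.003, 0.007, 0.03)


def _fresh_state(**over):
    base = dict(
        day_index=0, date=PLANTING - dt.timedelta(days=1), cum_hu=0.0, hui=0.0,
        lai=0.0, biomass=0.0, plant_n=0.0, soil_water=1e6, ts=1.0, ws=1.0, ns=1.0,
    )
    base.update(over)
    return SimState(**base)


class TestStepDay:
    def test_no_radiation_no_growth(self, phr18_control, unlimited_management):
        state = _fresh_state(lai=1.5, biomass=500.0)
        wx = ps.DailyWeather(PLANTING, 35, 25, 0.0, 0.0)
        new = ps.step_day(state, wx, phr18_control, unlimited_management)
        assert new.biomass == state.biomass

    def test_cold_day_halts_development_and_growth(self, phr18_control, unlimited_management):
        state = _fresh_state(lai=1.5, biomass=500.0)
        wx = ps.DailyWeather(PLANTING, 12, 4, 18.0, 0.0)  # mean 8 < TG=10
        new = ps.step_day(state, wx, phr18_control, unlimited_management)
        assert new.cum_hu == state.cum_hu
        assert new.ts == 0.0
        assert new.biomass == state.biomass

    def test_unstressed_gain_matches_hand_computation(self, phr18_control, unlimited_management):
        p = phr18_control
        state = _fresh_state(cum_hu=600.0, hui=600.0 / p.PHU, lai=2.0,
                             biomass=4000.0, plant_n=60.0)
        wx = ps.DailyWeather(PLANTING, 35, 25, 18.0, 0.0)  # mean 30 = TB
        new = ps.step_day(state, wx, p, unlimited_management)
        assert (new.ts, new.ws, new.ns) == (1.0, 1.0, 1.0)
        expected = p.WA * 0.5 * 18.0 * (1 - math.exp(-p.k_ext * new.lai))
        assert new.biomass - state.biomass == pytest.approx(expected, rel=1e-12)

    def test_date_mismatch_rejected(self, phr18_control, unlimited_management):
        state = _fresh_state()
        wx = ps.DailyWeather(PLANTING + dt.timedelta(days=5), 30, 20, 18, 0)
        with pytest.raises(ValueError, match="does not follow"):
            ps.step_day(state, wx, phr18_control, unlimited_management)


class TestRunSeason:
    def test_dark_season_yields_nothing(self, phr18_control, unlimited_management):
        wx = ps.greenhouse_series(35, 25, PLANTING, 120, srad_mean=0.0, seed=0)
        res = ps.run_season(phr18_control, wx, unlimited_management)
        assert res.yield_ == 0.0 and res.final_biomass == 0.0

    def test_unstressed_matches_interception_oracle(
        self, phr18_control, optimal_wx, unlimited_management
    ):
        p = phr18_control
        res = ps.run_season(p, optimal_wx, unlimited_management)
        assert res.matured
        # independent oracle: re-sum Beer's-law interception over the LAI trajectory
        ipar = 0.5 * 18.0 * (1 - np.exp(-p.k_ext * res.daily["lai"].to_numpy()))
        assert res.final_biomass * 1000 == pytest.approx(p.WA * ipar.sum(), rel=1e-6)

    def test_biomass_conservation_under_stress(self, field_wx, field_management):
        # re-sum daily gains WA * IPAR * REG from the recorded trajectory
        p = ps.get_parameter_set("PHR18", "control", "field").with_updates(PHU=1700)
        res = ps.run_season(p, field_wx, field_management)
        d = res.daily
        season = field_wx.window(field_management.planting_date).frame.iloc[: len(d)]
        reg = np.minimum.reduce([d["ts"].to_numpy(), d["ws"].to_numpy(), d["ns"].to_numpy()])
        ipar = 0.5 * season["srad"].to_numpy() * (1 - np.exp(-p.k_ext * d["lai"].to_numpy()))
        assert res.final_biomass * 1000 == pytest.approx((p.WA * ipar * reg).sum(), rel=1e-9)
        assert (np.diff(d["biomass"].to_numpy()) >= -1e-12).all()

    def test_stress_factors_bounded(self, field_wx, field_management):
        p = ps.get_parameter_set("PHR23", "heat", "field").with_updates(PHU=1700)
        res = ps.run_season(p, field_wx, field_management)
        for col in ("ts", "ws", "ns"):
            vals = res.daily[col].to_numpy()
            assert (vals >= 0).all() and (vals <= 1).all()

    def test_lai_unimodal_with_decline_at_dlai(self, field_wx, field_management):
        p = ps.get_parameter_set("PHR18", "control", "field").with_updates(PHU=1700)
        res = ps.run_season(p, field_wx, field_management)
        d = res.daily
        lai = d["lai"].to_numpy()
        growing = d["hui"].to_numpy() <= p.DLAI
        assert (np.diff(lai[growing]) >= -1e-12).all()
        assert (np.diff(lai[~growing]) <= 1e-12).all()
        assert growing.any() and (~growing).any()

    def test_yield_is_harvest_index_times_biomass_at_maturity(
        self, phr18_control, optimal_wx, unlimited_management
    ):
        res = ps.run_season(phr18_control, optimal_wx, unlimited_management)
        assert res.matured
        assert res.yield_ / res.final_biomass == pytest.approx(phr18_control.HI)
        assert res.yield_ <= res.final_biomass

    def test_midseason_harvest_scales_index(self):
        assert realized_harvest_index(1.0, 0.57, 0.3) == pytest.approx(0.57)
        assert realized_harvest_index(0.3, 0.57, 0.3) == 0.0
        assert realized_harvest_index(0.65, 0.57, 0.3) == pytest.approx(0.57 * 0.5)

    def test_short_weather_rejected(self, phr18_control, unlimited_management):
        wx = ps.greenhouse_series(35, 25, PLANTING, 5, seed=0)
        with pytest.raises(ValueError, match="at least 10"):
            ps.run_season(phr18_control, wx, unlimited_management)

    def test_pet_positive_in_season(self):
        assert hargreaves_pet(25.0, 20.0) > 0
        assert hargreaves_pet(-20.0, 5.0) == 0.0


@pytest.fixture(scope="module")
def shift_setup():
    wx = ps.synth_field_weather("central", [2022], seed=9)
    p = ps.get_parameter_set("PHR18", "control", "field").with_updates(PHU=1800)
    m = ps.ManagementSpec(planting_date=dt.date(2022, 4, 25))
    return p, wx, m


class TestMaturityShift:

    def test_zero_delta_zero_shift(self, shift_setup):
        assert ps.maturity_shift(*shift_setup, 0.0) == 0

    def test_warming_advances_maturity(self, shift_setup):
        s3 = ps.maturity_shift(*shift_setup, 3.0)
        s5 = ps.maturity_shift(*shift_setup, 5.0)
        assert s5 > 0
        assert s5 >= s3 >= 0


class TestNitrogenSchedule:
    def test_warming_outruns_calendar_fertigation(self):
        """With a binding calendar-released N supply and identical parameters,
        a warming-accelerated crop accrues more N-stress days."""
        base_days, warm_days = [], []
        p = ps.get_parameter_set("PHR18", "control", "field").with_updates(PHU=1700)
        for year in range(2014, 2024):
            wx = ps.synth_field_weather("central", [year], seed=year)
            m = ps.ManagementSpec(planting_date=dt.date(year, 4, 25), n_supply=55.0)
            base_days.append(ps.run_season(p, wx, m, record=False).n_stress_days)
            warm_days.append(
                ps.run_season(p, ps.apply_delta(wx, 5.0), m, record=False).n_stress_days)
        assert np.mean(warm_days) > np.mean(base_days)
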