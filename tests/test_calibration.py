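"""Kjeldahl N, harvest index, curve fitting, and yield-matching searches."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import peppersim as ps
from peppersim.calibration import fit_lai_curve, fresh_to_dry_areal
from peppersim.study_data import GREENHOUSE_MASS_TABLE


class TestKjeldahl:
    @pytest.mark.parametrize(
        "ml_sample,ml_blank,normality,mass,expected",
        [
            (10, 0, 0.1, 1, 14.01),
            (10, 0, 0.1, 2, 7.005),
            (5, 5, 0.1, 1, 0.0),
        ],
    )
    def test_equation(self, ml_sample, ml_blank, normality, mass, expected):
        rec = ps.TitrationRecord(ml_sample, ml_blank, normality, mass)
        assert ps.kjeldahl_total_n(rec) == pytest.approx(expected)

    def test_titration_fault_detected(self):
        with pytest.raises(ValueError, match="titration fault"):
            ps.kjeldahl_total_n(ps.TitrationRecord(1.0, 2.0, 0.1, 1.0))

    def test_bad_sample_mass(self):
        with pytest.raises(ValueError):
            ps.TitrationRecord(10, 0, 0.1, 0.0)

    @given(
        delta=st.floats(0.1, 50),
        normality=st.floats(0.01, 1.0),
        mass=st.floats(0.1, 10),
    )
    @settings(max_examples=200)
    def test_linear_in_volume_difference_and_normality(self, delta, normality, mass):
        base = ps.kjeldahl_total_n(ps.TitrationRecord(delta, 0, normality, mass))
        doubled = ps.kjeldahl_total_n(ps.TitrationRecord(2 * delta, 0, normality, mass))
        stronger = ps.kjeldahl_total_n(ps.TitrationRecord(delta, 0, 2 * normality, mass))
        assert doubled == pytest.approx(2 * base, rel=1e-12)
        assert stronger == pytest.approx(2 * base, rel=1e-12)

    @given(true_n=st.floats(0, 100), mass=st.floats(0.1, 10))
    @settings(max_examples=200)
    def test_inverse_of_titration_generator(self, true_n, mass):
        rec = ps.gen_titration(true_n, mass, hcl_normality=0.1, blank=1.0)
        assert ps.kjeldahl_total_n(rec) == pytest.approx(true_n, abs=1e-9)


class TestHarvestIndex:
    @pytest.mark.parametrize(
        "fruit,total,expected",
        [v[cond][:2][::-1] + (v[cond][2],)
         for v in GREENHOUSE_MASS_TABLE.values() for cond in ("control", "heat")],
    )
    def test_reproduces_trial_table(self, fruit, total, expected):
        assert ps.harvest_index(fruit, total) == expected

    def test_limits_and_errors(self):
        assert ps.harvest_index(0, 100) == 0.0
        with pytest.raises(ValueError):
            ps.harvest_index(1, 0)
        with pytest.raises(ValueError):
            ps.harvest_index(10, 5)


class TestLaiCurveFit:
    def _curve_points(self, xs, dmla=3.8, codes=(10.19, 50.95)):
        c = ps.solve_scurve(ps.decode_point_code(codes[0], "percent"),
                            ps.decode_point_code(codes[1], "percent"))
        return [(float(x), float(dmla * ps.scurve_eval(x, c))) for x in xs]

    def test_noiseless_two_point_roundtrip(self):
        pts = self._curve_points([0.10, 0.50])
        c1, c2 = fit_lai_curve(pts, dmla=3.8)
        assert c1 == pytest.approx(10.19, abs=0.01)
        assert c2 == pytest.approx(50.95, abs=0.01)

    def test_noiseless_dense_series_roundtrip(self):
        pts = self._curve_points([0.05, 0.10, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        c1, c2 = fit_lai_curve(pts, dmla=3.8)
        assert c1 == pytest.approx(10.19, abs=0.01)
        assert c2 == pytest.approx(50.95, abs=0.01)

    def test_moderate_noise_recovers_x_digits(self):
        """LAI noise sd 0.2: median absolute x-digit error over 200 seeds < 5."""
        xs = [0.05, 0.10, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
        clean = self._curve_points(xs)
        errs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            noisy = [(x, float(np.clip(l + rng.normal(0, 0.2), 0.01, 3.79)))
                     for x, l in clean]
            c1, c2 = fit_lai_curve(noisy, dmla=3.8)
            errs.append(max(abs(int(c1) - 10), abs(int(c2) - 50)))
        assert np.median(errs) < 5

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 2"):
            fit_lai_curve([(0.1, 0.5)], dmla=3.8)

    def test_lai_above_ceiling_rejected(self):
        with pytest.raises(ValueError, match="exceed DMLA"):
            fit_lai_curve([(0.1, 0.5), (0.5, 4.5)], dmla=3.8)


class TestEstimateBN:
    def _obs(self, day, total_n):
        return ps.TrialObservation("PHR18", "control", day, 1000.0, 300.0, 2.0,
                                   total_n=total_n)

    def test_known_fractions_recovered(self):
        # dry biomass 100 g and 200 g with known fractions 0.006 / 0.003
        obs = [self._obs(35, 0.6), self._obs(75, 0.6)]
        bn2, bn3 = ps.estimate_bn(obs, [100.0, 200.0], huis=[0.5, 1.0])
        assert (bn2, bn3) == (0.006, 0.003)

    def test_zero_nitrogen_gives_zero_fraction(self):
        obs = [self._obs(35, 0.0), self._obs(75, 0.0)]
        assert ps.estimate_bn(obs, [100.0, 200.0]) == (0.0, 0.0)

    def test_stage_order_enforced(self):
        obs = [self._obs(75, 0.5), self._obs(35, 0.5)]
        with pytest.raises(ValueError, match="increasing day order"):
            ps.estimate_bn(obs, [100.0, 200.0])

    def test_zero_biomass_rejected(self):
        obs = [self._obs(35, 0.5), self._obs(75, 0.5)]
        with pytest.raises(ValueError, match="positive"):
            ps.estimate_bn(obs, [0.0, 200.0])


@pytest.fixture(scope="module")
def recovery_setup():
    wx = ps.synth_field_weather("central", [2022], seed=17)
    m = ps.ManagementSpec(planting_date=dt.date(2022, 4, 25))
    p = ps.get_parameter_set("PHR18", "control", "field")
    return p, wx, m


class TestYieldMatchingSearches:
    def test_phu_recovery_from_engine_target(self, recovery_setup):
        p, wx, m = recovery_setup
        true_phu = 1800.0
        target = ps.run_season(p.with_updates(PHU=true_phu), wx, m, record=False).yield_
        got = ps.estimate_phu(p, wx, m, target, search=(1500, 2200, 50))
        assert abs(got - true_phu) <= 50

    def test_phu_tie_breaks_to_smaller(self, recovery_setup):
        p, wx, m = recovery_setup
        y1 = ps.run_season(p.with_updates(PHU=1800.0), wx, m, record=False).yield_
        y2 = ps.run_season(p.with_updates(PHU=1850.0), wx, m, record=False).yield_
        midpoint = 0.5 * (y1 + y2)  # equidistant from both candidates
        assert ps.estimate_phu(p, wx, m, midpoint, search=(1800, 1850, 50)) == 1800

    @pytest.mark.parametrize("search", [(2000, 1000, 50), (1000, 2000, 0)])
    def test_malformed_search_ranges(self, recovery_setup, search):
        p, wx, m = recovery_setup
        with pytest.raises(ValueError, match="malformed"):
            ps.estimate_phu(p, wx, m, 8.0, search=search)

    def test_wa_recovery_from_engine_target(self, recovery_setup):
        p_gh = ps.get_parameter_set("PHR18", "control", "greenhouse")
        _, wx, m = recovery_setup
        target = ps.run_season(
            p_gh.with_updates(WA=27.0, setting="field"), wx, m, record=False).yield_
        got = ps.estimate_wa_field(p_gh, wx, m, target, search=(20, 35, 0.5))
        assert abs(got - 27.0) <= 0.5

    def test_yield_monotone_in_wa(self, recovery_setup):
        p, wx, m = recovery_setup
        yields = [ps.run_season(p.with_updates(WA=wa), wx, m, record=False).yield_
                  for wa in (20.0, 25.0, 30.0, 35.0)]
        assert all(b >= a - 1e-9 for a, b in zip(yields, yields[1:]))

    def test_empty_grid_rejected(self, recovery_setup):
        p, wx, m = recovery_setup
        with pytest.raises(ValueError, match="malformed"):
            ps.estimate_wa_field(p, wx, m, 8.0, search=(40, 15, 0.5))


class TestFreshToDry:
    @pytest.mark.parametrize("fresh,moisture,density,expected", [
        (1000.0, 90.0, 1.0, 1.0),
        (500.0, 100.0, 3.0, 0.0),
        (326.0, 87.0, 2.7, 326 * 0.13 * 2.7 * 0.01),
    ])
    def test_unit_conversion(self, fresh, moisture, density, expected):
        assert fresh_to_dry_areal(fresh, moisture, density) == pytest.approx(expected)

    def test_linear_in_density(self):
        one = fresh_to_dry_areal(800, 85, 1.5)
        assert fresh_to_dry_areal(800, 85, 3.0) == pytest.approx(2 * one)

    def test_moisture_bounds(self):
        with pytest.raises(ValueError):
            fresh_to_dry_areal(100, 101, 1)
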