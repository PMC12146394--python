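"""Daily-timestep process-based pepper growth model.

The model follows the classic RUE (radiation-use-efficiency) architecture:
degree-day phenology drives a heat-unit index HUI in [0, 1]; leaf area
develops along a two-point S-curve of HUI up to a population-limited
maximum and declines after the DLAI fraction of the season; Beer's law
converts LAI to intercepted photosynthetically active radiation; potential
daily biomass gain is WA (kg ha-1 per MJ m-2) times intercepted PAR; and
the realized gain is scaled by REG, the minimum of the day's temperature,
water, and nitrogen stress factors.  Yield is a harvest index applied to
final above-ground biomass, ramping linearly with HUI from flowering so
mid-season harvests carry a proportionally smaller index.

Supporting processes are intentionally minimal: a single-layer plant-
available soil-water bucket with radiation-based Hargreaves evaporative
demand (canopy transpiration plus bare-soil evaporation) and optional
auto-irrigation, and a nitrogen supply released on a calendar fertigation
schedule against an exponential N-dilution demand curve anchored at the
BN1/BN2/BN3 fractions.  Because N release follows the calendar while crop
demand follows heat units, a warming-accelerated crop can outrun its
fertigation schedule — the mechanism behind increased N-stress days in
warming scenarios.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import pandas as pd

from .params import CropParameterSet, population_factor
from .weather import WeatherSeries, apply_delta

__all__ = [
    "ManagementSpec",
    "SimState",
    "SimResult",
    "heat_units",
    "temperature_stress",
    "intercepted_par",
    "ndilution_coeffs",
    "optimal_n_fraction",
    "hargreaves_pet",
    "step_day",
    "run_season",
    "maturity_shift",
    "STRESS_DAY_THRESHOLD",
]

#: a day counts as stressed when the factor drops below this
STRESS_DAY_THRESHOLD = 0.9

#: relative plant-available soil water below which supply limits transpiration
_CRIT_SW_FRAC = 0.5

#: latent heat of vaporization, MJ kg-1 (converts MJ m-2 to mm of water)
_LAMBDA = 2.45


@dataclass
class ManagementSpec:
    """Planting, density, irrigation and fertility management for one season."""

    planting_date: dt.date
    density: float = 2.5                 # plants m-2
    irrigation_trigger: float = 0.85     # irrigate when water-stress factor < trigger (0 = rainfed)
    irrigation_depth: float = 25.0       # mm per event
    soil_capacity: float = 80.0          # mm plant-available water in the root zone
    initial_soil_water: float = 30.0     # mm at transplanting (pre-monsoon spring soil)
    n_supply: float = 120.0              # kg ha-1 plant-available N, season total
    n_release_days: int = 150            # fertigation schedule: supply released linearly over this window

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValueError(f"plant density must be positive, got {self.density}")
        if not 0.0 <= self.irrigation_trigger <= 1.0:
            raise ValueError(
                f"irrigation trigger must lie in [0, 1], got {self.irrigation_trigger}"
            )
        if self.soil_capacity <= 0 or self.initial_soil_water < 0:
            raise ValueError("soil capacity must be positive and initial water non-negative")


@dataclass
class SimState:
    """End-of-day engine state."""

    day_index: int
    date: dt.date
    cum_hu: float
    hui: float
    lai: float
    biomass: float          # kg ha-1 above-ground dry
    plant_n: float          # kg ha-1
    soil_water: float       # mm
    ts: float
    ws: float
    ns: float
    irrigation_applied: float = 0.0   # mm cumulative
    w_stress_days: int = 0
    n_stress_days: int = 0
    # internal carry-overs
    lai_at_decline: float = field(default=0.0, repr=False)
    n_taken: float = field(default=0.0, repr=False)


@dataclass
class SimResult:
    """A season's daily trajectory plus summary quantities."""

    daily: pd.DataFrame
    maturity_date: dt.date
    matured: bool
    final_biomass: float     # Mg ha-1 dry
    yield_: float            # Mg ha-1 dry
    total_irrigation: float  # mm
    w_stress_days: int
    n_stress_days: int
    params: CropParameterSet
    management: ManagementSpec

    def summary(self) -> dict:
        return {
            "maturity_date": self.maturity_date.isoformat(),
            "matured": self.matured,
            "final_biomass_Mg_ha": round(float(self.final_biomass), 3),
            "yield_Mg_ha": round(float(self.yield_), 3),
            "total_irrigation_mm": round(float(self.total_irrigation), 1),
            "w_stress_days": self.w_stress_days,
            "n_stress_days": self.n_stress_days,
        }


def heat_units(tmax: float, tmin: float, TG: float, TB: float) -> float:
    """Degree days from the daily mean, base TG, capped at TB - TG."""
    if not TG < TB:
        raise ValueError(f"TG ({TG}) must be below TB ({TB})")
    hu = 0.5 * (tmax + tmin) - TG
    return min(max(hu, 0.0), TB - TG)


def temperature_stress(tavg: float, TG: float, TB: float) -> float:
    """Sine-shaped temperature stress: 0 at TG, 1 at the optimum TB.

    ``sin((pi/2) * (tavg-TG)/(TB-TG))`` clamped to [0, 1] for relative
    temperatures in [0, 2]; zero outside (no growth below base temperature
    or beyond symmetric supra-optimal heat).
    """
    if not TG < TB:
        raise ValueError(f"TG ({TG}) must be below TB ({TB})")
    r = (tavg - TG) / (TB - TG)
    if r <= 0.0 or r >= 2.0:
        return 0.0
    return min(1.0, max(0.0, math.sin(0.5 * math.pi * r)))


def intercepted_par(srad: float, lai: float, k_ext: float = 0.65) -> float:
    """Beer's-law intercepted PAR (MJ m-2); PAR is half of global radiation."""
    if srad < 0 or lai < 0:
        raise ValueError("srad and lai must be non-negative")
    return 0.5 * srad * (1.0 - math.exp(-k_ext * lai))


def ndilution_coeffs(BN1: float, BN2: float, BN3: float) -> tuple[float, float, float]:
    """Coefficients (a, b, c) of the N-dilution curve ``a + b*exp(-c*hui)``.

    Exact at hui=0 (BN1) and hui=1 (BN3).  The midseason anchor BN2 is hit
    exactly when representable — which requires BN2-BN3 < BN1-BN2, i.e. the
    curve is convex — and by least squares on the residual at hui=0.5
    otherwise.
    """
    if not BN1 >= BN2 >= BN3 > 0:
        raise ValueError(f"anchors must satisfy BN1 >= BN2 >= BN3 > 0, got {BN1}, {BN2}, {BN3}")
    if BN1 == BN3:
        return BN1, 0.0, 1.0
    if BN1 == BN2:
        # flat start then drop: steepest admissible decline
        c = 50.0
    else:
        u = (BN2 - BN3) / (BN1 - BN2)   # = exp(-c/2) when exactly representable
        if 0.0 < u < 1.0:
            c = -2.0 * math.log(u)
        else:
            # not representable: minimize the squared midseason residual
            from scipy.optimize import minimize_scalar

            def resid(cc: float) -> float:
                e = math.exp(-cc)
                b = (BN1 - BN3) / (1.0 - e)
                a = BN1 - b
                return (a + b * math.exp(-0.5 * cc) - BN2) ** 2

            c = minimize_scalar(resid, bounds=(1e-3, 50.0), method="bounded").x
    e = math.exp(-c)
    b = (BN1 - BN3) / (1.0 - e)
    a = BN1 - b
    return a, b, c


def optimal_n_fraction(hui: float, BN1: float, BN2: float, BN3: float) -> float:
    """Optimal (non-stressed) N mass fraction of biomass at development stage hui."""
    if hui < 0:
        raise ValueError(f"hui must be non-negative, got {hui}")
    a, b, c = ndilution_coeffs(BN1, BN2, BN3)
    return a + b * math.exp(-c * min(hui, 1.0))


def hargreaves_pet(tavg: float, srad: float) -> float:
    """Radiation-based Hargreaves reference evapotranspiration (mm day-1)."""
    return max(0.0, 0.0135 * (tavg + 17.8) * srad / _LAMBDA)


def realized_harvest_index(hui: float, HI: float, hui_flower: float) -> float:
    """HI ramps linearly from 0 at flowering (hui_flower) to HI at maturity."""
    x = (min(hui, 1.0) - hui_flower) / (1.0 - hui_flower)
    return HI * min(1.0, max(0.0, x))


def step_day(state: SimState, wx, p: CropParameterSet, m: ManagementSpec) -> SimState:
    """Advance the engine one day.

    Order of computation: (1) heat units and HUI; (2) stress factors and
    REG = min(ts, ws, ns); (3) LAI growth along the S-curve (or post-DLAI
    decline); (4) biomass gain WA * IPAR * REG; (5) N uptake against the
    dilution curve from the fertigation pool; (6) soil-water bucket with
    evaporative demand and auto-irrigation.
    """
    if wx.date != state.date + dt.timedelta(days=1):
        raise ValueError(
            f"weather date {wx.date} does not follow state date {state.date}"
        )
    new = _StepImpl(p, m).run(state, wx.tmax, wx.tmin, wx.srad, wx.precip, wx.date)
    return new


class _StepImpl:
    """Per-run cache of curve coefficients; keeps the daily loop cheap."""

    def __init__(self, p: CropParameterSet, m: ManagementSpec):
        self.p = p
        self.m = m
        self.lai_coeffs = p.lai_curve()
        self.popf = population_factor(m.density, *p.ppl_points())
        self.n_a, self.n_b, self.n_c = ndilution_coeffs(p.BN1, p.BN2, p.BN3)

    def f_lai(self, hui: float) -> float:
        c = self.lai_coeffs
        return hui / (hui + math.exp(c.l1 - c.l2 * hui)) if hui > 0 else 0.0

    def n_frac(self, hui: float) -> float:
        return self.n_a + self.n_b * math.exp(-self.n_c * min(hui, 1.0))

    def run(self, s: SimState, tmax, tmin, srad, precip, date) -> SimState:
        p, m = self.p, self.m
        tavg = 0.5 * (tmax + tmin)
        # (1) phenology
        hui_prev = s.hui
        hu = heat_units(tmax, tmin, p.TG, p.TB)
        cum_hu = s.cum_hu + hu
        hui = cum_hu / p.PHU
        # (2) stress factors from start-of-day state
        ts = temperature_stress(tavg, p.TG, p.TB)
        ws = min(1.0, max(0.0, s.soil_water / (_CRIT_SW_FRAC * m.soil_capacity)))
        demand_frac = self.n_frac(hui_prev)
        if s.biomass > 1.0:
            ns = min(1.0, max(0.0, s.plant_n / (demand_frac * s.biomass)))
        else:
            ns = 1.0
        reg = min(ts, ws, ns)
        # (3) leaf area
        lai_at_decline = s.lai_at_decline
        if hui <= p.DLAI:
            dlai_pot = p.DMLA * self.popf * (self.f_lai(hui) - self.f_lai(hui_prev))
            lai = s.lai + max(0.0, dlai_pot) * reg
            lai_at_decline = lai
        else:
            frac = max(0.0, (1.0 - min(hui, 1.0)) / (1.0 - p.DLAI))
            lai = min(s.lai, lai_at_decline * frac)
        # (4) biomass
        ipar = intercepted_par(srad, lai, p.k_ext)
        biomass = s.biomass + p.WA * ipar * reg
        # (5) nitrogen: fertigation pool released on a calendar schedule, so a
        # heat-accelerated crop can outrun its supply
        released = m.n_supply * min(1.0, (s.day_index + 1) / m.n_release_days)
        available = max(0.0, released - s.n_taken)
        demand = max(0.0, self.n_frac(hui) * biomass - s.plant_n)
        uptake = min(demand, available)
        plant_n = s.plant_n + uptake
        n_taken = s.n_taken + uptake
        # (6) soil-water bucket
        sw = s.soil_water + precip
        pet = hargreaves_pet(tavg, srad)
        transp = pet * (1.0 - math.exp(-p.k_ext * lai)) * ws
        soil_evap = pet * math.exp(-p.k_ext * lai) * min(1.0, sw / m.soil_capacity)
        sw = max(0.0, sw - transp - soil_evap)
        irrigation = s.irrigation_applied
        if m.irrigation_trigger > 0 and ws < m.irrigation_trigger:
            sw += m.irrigation_depth
            irrigation += m.irrigation_depth
        sw = min(sw, m.soil_capacity)
        return SimState(
            day_index=s.day_index + 1,
            date=date,
            cum_hu=cum_hu,
            hui=hui,
            lai=lai,
            biomass=biomass,
            plant_n=plant_n,
            soil_water=sw,
            ts=ts,
            ws=ws,
            ns=ns,
            irrigation_applied=irrigation,
            w_stress_days=s.w_stress_days + (1 if ws < STRESS_DAY_THRESHOLD else 0),
            n_stress_days=s.n_stress_days + (1 if ns < STRESS_DAY_THRESHOLD else 0),
            lai_at_decline=lai_at_decline,
            n_taken=n_taken,
        )


def run_season(
    p: CropParameterSet,
    wx: WeatherSeries,
    m: ManagementSpec,
    record: bool = True,
) -> SimResult:
    """Simulate one season from planting until HUI >= 1 or weather runs out.

    Yield (Mg ha-1 dry) is the realized harvest index — ramping linearly
    with HUI from ``hui_flower`` — applied to final above-ground biomass.
    ``record=False`` skips building the daily DataFrame (used by grid
    searches).
    """
    season = wx.window(m.planting_date)
    if len(season) < 10:
        raise ValueError(
            f"weather covers only {len(season)} days from planting "
            f"{m.planting_date}; at least 10 required"
        )
    impl = _StepImpl(p, m)
    f = season.frame
    tmax = f["tmax"].to_numpy()
    tmin = f["tmin"].to_numpy()
    srad = f["srad"].to_numpy()
    precip = f["precip"].to_numpy()
    dates = f["date"].dt.date.to_numpy()

    state = SimState(
        day_index=0, date=dates[0] - dt.timedelta(days=1),
        cum_hu=0.0, hui=0.0, lai=0.0, biomass=0.0, plant_n=0.0,
        soil_water=min(m.initial_soil_water, m.soil_capacity),
        ts=1.0, ws=1.0, ns=1.0,
    )
    rows = [] if record else None
    matured = False
    last_date = dates[0]
    for i in range(len(f)):
        state = impl.run(state, tmax[i], tmin[i], srad[i], precip[i], dates[i])
        last_date = dates[i]
        if record:
            rows.append(
                (state.date, state.cum_hu, state.hui, state.lai, state.biomass,
                 state.plant_n, state.soil_water, state.ts, state.ws, state.ns,
                 state.irrigation_applied)
            )
        if state.hui >= 1.0:
            matured = True
            break
    daily = (
        pd.DataFrame(
            rows,
            columns=["date", "cum_hu", "hui", "lai", "biomass", "plant_n",
                     "soil_water", "ts", "ws", "ns", "irrigation"],
        )
        if record
        else pd.DataFrame()
    )
    final_biomass = state.biomass / 1000.0  # kg -> Mg ha-1
    hi_real = realized_harvest_index(state.hui, p.HI, p.hui_flower)
    return SimResult(
        daily=daily,
        maturity_date=last_date,
        matured=matured,
        final_biomass=final_biomass,
        yield_=hi_real * final_biomass,
        total_irrigation=state.irrigation_applied,
        w_stress_days=state.w_stress_days,
        n_stress_days=state.n_stress_days,
        params=p,
        management=m,
    )


def maturity_shift(
    p: CropParameterSet,
    wx: WeatherSeries,
    m: ManagementSpec,
    delta_t: float,
) -> int:
    """Days by which warming by ``delta_t`` advances physiological maturity.

    Positive when the perturbed run matures earlier.  If either run fails to
    mature within the weather series, its end-of-season date is used (the
    run's ``matured`` flag records this).
    """
    base = run_season(p, wx, m, record=False)
    if not base.matured:
        raise ValueError("baseline run does not reach maturity within the weather series")
    pert = run_season(p, apply_delta(wx, delta_t), m, record=False)
    return (base.maturity_date - pert.maturity_date).days
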