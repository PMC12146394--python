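"""Synthetic study inputs: greenhouse-trial observations with realistic
dispersion, Kjeldahl titration records, and engine-backed pseudo-measured
site yields.

Every generator is seeded and deterministic.  The trial generator samples
the engine's own trajectory at the trial's measurement days and adds
Gaussian noise whose default standard deviations are the medians of the
printed dispersion of the greenhouse trial; invariant violations are
clamped (not resampled) so seeds stay stable.  These data emulate the
structure and noise of the real campaign, not its biology — recovery tests
against them demonstrate internal consistency of the calibration chain,
not field validity.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from statistics import median

import numpy as np

from .calibration import SiteYieldRecord, TitrationRecord, TrialObservation, N_MOLAR_MASS
from .engine import ManagementSpec, realized_harvest_index, run_season
from .params import CropParameterSet
from .scenarios import SiteSpec
from .study_data import TRIAL_DISPERSION
from .weather import WeatherSeries, synth_field_weather

__all__ = [
    "TrialDesign",
    "DEFAULT_NOISE_SD",
    "gen_trial",
    "gen_titration",
    "gen_site_yields",
]

#: default per-variable noise sd: median of the printed trial dispersion
DEFAULT_NOISE_SD = {k: float(median(v)) for k, v in TRIAL_DISPERSION.items()}

#: measurement schedule of the second trial year (days after treatment start)
DEFAULT_MEASUREMENT_DAYS = (1, 3, 5, 7, 9, 13, 15, 17, 19, 21, 23, 25, 37, 49, 63, 77)

_MOISTURE_MEAN = 86.0  # % fresh basis, typical of the trial


@dataclass
class TrialDesign:
    """Layout and noise model of a synthetic greenhouse trial."""

    accessions: tuple[str, ...] = ("PHR18", "PHR23")
    conditions: tuple[str, ...] = ("control", "heat")
    measurement_days: tuple[int, ...] = DEFAULT_MEASUREMENT_DAYS
    replicates: int = 3
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise standard deviations must be non-negative")


def _state_to_observation(
    accession: str, condition: str, day: int, row, p: CropParameterSet, density: float,
) -> dict:
    """Map one engine day to the trial's per-plant measurement scale."""
    dry_g_per_plant = row.biomass * 0.1 / density     # kg/ha -> g/m2 -> g/plant
    total_fresh = dry_g_per_plant / (1.0 - _MOISTURE_MEAN / 100.0)
    fruit_fresh = realized_harvest_index(row.hui, p.HI, p.hui_flower) * total_fresh
    f = row.hui / (row.hui + np.exp(p.lai_curve().l1 - p.lai_curve().l2 * row.hui)) \
        if row.hui > 0 else 0.0
    return {
        "accession": accession,
        "condition": condition,
        "day_after_treatment": day,
        "total_fresh_mass": total_fresh,
        "fruit_fresh_mass": fruit_fresh,
        "lai": row.lai,
        "height": 20.0 + 115.0 * f,     # cm, simple development allometry
        "stem_thickness": 8.0 + 12.0 * f,
        "moisture": _MOISTURE_MEAN,
        "total_n": row.plant_n * 0.1 / density,
    }


def gen_trial(
    design: TrialDesign,
    p: CropParameterSet,
    wx: WeatherSeries,
    management: ManagementSpec | None = None,
) -> list[TrialObservation]:
    """Synthetic trial observations for one parameter set.

    Runs the engine over ``wx`` from its first day, samples the trajectory
    at the design's measurement days, and adds seeded Gaussian noise.
    With all-zero noise, observations lie exactly on the trajectory.
    """
    if max(design.measurement_days) > len(wx):
        raise ValueError(
            f"measurement day {max(design.measurement_days)} beyond the "
            f"{len(wx)}-day weather series"
        )
    m = management or ManagementSpec(
        planting_date=wx.start(), density=2.7,
        irrigation_trigger=0.95, n_supply=300.0,
    )
    res = run_season(p, wx, m)
    daily = res.daily.set_index(res.daily.index + 1)  # day-after-treatment index
    rng = np.random.default_rng(design.seed)
    sd = design.noise_sd
    out: list[TrialObservation] = []
    for day in design.measurement_days:
        if day not in daily.index:
            raise ValueError(f"measurement day {day} beyond simulated season ({len(daily)} days)")
        base = _state_to_observation(p.accession, p.condition, day,
                                     daily.loc[day], p, m.density)
        for _ in range(design.replicates):
            total = base["total_fresh_mass"] + rng.normal(0, sd.get("total_fresh_g", 0))
            fruit = base["fruit_fresh_mass"] + rng.normal(0, sd.get("fruit_fresh_g", 0))
            lai = base["lai"] + rng.normal(0, sd.get("lai", 0))
            height = base["height"] + rng.normal(0, sd.get("height_cm", 0))
            stem = base["stem_thickness"] + rng.normal(0, sd.get("stem_mm", 0))
            moist = base["moisture"] + rng.normal(0, sd.get("moisture_pct", 0))
            total_n = base["total_n"] + rng.normal(0, sd.get("total_n_g", 0))
            # clamp to the record's invariants rather than resampling
            total = max(0.0, total)
            out.append(TrialObservation(
                accession=base["accession"],
                condition=base["condition"],
                day_after_treatment=day,
                total_fresh_mass=total,
                fruit_fresh_mass=float(np.clip(fruit, 0.0, total)),
                lai=max(0.0, lai),
                height=max(0.0, height),
                stem_thickness=max(0.0, stem),
                moisture=float(np.clip(moist, 0.0, 100.0)),
                total_n=max(0.0, total_n),
            ))
    return out


def gen_titration(
    true_n_g_per_kg: float,
    sample_mass: float,
    hcl_normality: float = 0.1,
    blank: float = 0.0,
    seed: int = 0,
    noise_sd_ml: float = 0.0,
) -> TitrationRecord:
    """Titration record whose noiseless analysis returns ``true_n_g_per_kg``.

    Inverts the Kjeldahl equation:
    ``ml_sample = blank + true_n * mass / (normality * 14.01)``.
    """
    if true_n_g_per_kg < 0:
        raise ValueError(f"true N must be non-negative, got {true_n_g_per_kg}")
    if sample_mass <= 0 or hcl_normality <= 0 or blank < 0:
        raise ValueError("sample mass and normality must be positive, blank non-negative")
    ml = blank + true_n_g_per_kg * sample_mass / (hcl_normality * N_MOLAR_MASS)
    if noise_sd_ml > 0:
        ml += float(np.random.default_rng(seed).normal(0.0, noise_sd_ml))
    if ml < 0:
        raise ValueError("parameters imply a negative titration volume")
    return TitrationRecord(ml_sample=ml, ml_blank=blank,
                           hcl_normality=hcl_normality, sample_mass=sample_mass)


def gen_site_yields(
    sites: list[SiteSpec],
    true_phu: dict[str, float],
    p: CropParameterSet,
    noise_sd: float = 0.0,
    seed: int = 0,
    year: int = 2022,
    management: ManagementSpec | None = None,
) -> list[SiteYieldRecord]:
    """Engine-backed pseudo-measured site yields for calibration recovery.

    Each site's 'measured' yield is the engine yield at that site's true PHU
    plus seeded Gaussian noise (clamped positive).
    """
    rng = np.random.default_rng(seed)
    out = []
    for i, site in enumerate(sites):
        wx = site.weather
        if wx is None:
            wx = synth_field_weather(site.latitude_band, [year],
                                     seed=int(rng.integers(0, 2**31)))
        m = management or ManagementSpec(planting_date=dt.date(year, 4, 25))
        res = run_season(p.with_updates(PHU=true_phu[site.site_id]), wx, m, record=False)
        measured = res.yield_ + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        out.append(SiteYieldRecord(
            site_id=site.site_id, province=site.province, year=year,
            measured_yield=max(0.05, measured), measured_sd=noise_sd,
        ))
    return out
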