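"""Parameter-derivation procedures: Kjeldahl total nitrogen, harvest index,
N-fraction anchors, leaf-area-curve fitting, and yield-matching grid
searches for site heat-unit requirements (PHU) and field radiation-use
efficiency (WA).

The grid searches wrap the growth engine: they minimize the absolute
difference between the simulated and measured season yield over a candidate
grid, breaking ties toward the smaller candidate; the calibration target is
the yield itself, not phenology dates (the surveys recorded yields).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import ManagementSpec, run_season
from .params import CropParameterSet, SCurvePoint, encode_point_code, scurve_eval, SCurveCoeffs
from .weather import WeatherSeries

__all__ = [
    "TitrationRecord",
    "TrialObservation",
    "SiteYieldRecord",
    "kjeldahl_total_n",
    "harvest_index",
    "fit_lai_curve",
    "estimate_bn",
    "estimate_phu",
    "estimate_wa_field",
    "fresh_to_dry_areal",
]

#: molar mass of nitrogen, g mol-1
N_MOLAR_MASS = 14.01


@dataclass(frozen=True)
class TitrationRecord:
    """One Kjeldahl back-titration: HCl volumes (mL), normality (eq L-1), sample mass (g)."""

    ml_sample: float
    ml_blank: float
    hcl_normality: float
    sample_mass: float

    def __post_init__(self) -> None:
        if self.sample_mass <= 0:
            raise ValueError(f"sample mass must be positive, got {self.sample_mass}")
        if self.ml_sample < 0 or self.ml_blank < 0:
            raise ValueError("titration volumes must be non-negative")


@dataclass(frozen=True)
class TrialObservation:
    """One measured greenhouse-trial record (per-plant masses in g)."""

    accession: str
    condition: str
    day_after_treatment: int
    total_fresh_mass: float
    fruit_fresh_mass: float
    lai: float
    height: float = float("nan")          # cm
    stem_thickness: float = float("nan")  # mm
    moisture: float = 86.0                # % fresh basis
    total_n: float = float("nan")         # g plant-1

    def __post_init__(self) -> None:
        if self.fruit_fresh_mass > self.total_fresh_mass:
            raise ValueError(
                f"fruit mass {self.fruit_fresh_mass} exceeds total mass {self.total_fresh_mass}"
            )
        if not 0.0 <= self.moisture <= 100.0:
            raise ValueError(f"moisture must lie in [0, 100] %, got {self.moisture}")


@dataclass
class SiteYieldRecord:
    """Measured (and optionally simulated) dry yield at one site-year, Mg ha-1."""

    site_id: str
    province: str
    year: int
    measured_yield: float
    measured_sd: float = 0.0
    simulated_yield: float | None = None

    def __post_init__(self) -> None:
        if self.measured_yield <= 0:
            raise ValueError(f"measured yield must be positive, got {self.measured_yield}")
        if self.simulated_yield is not None and self.simulated_yield <= 0:
            raise ValueError(f"simulated yield must be positive, got {self.simulated_yield}")


def kjeldahl_total_n(t: TitrationRecord) -> float:
    """Total nitrogen (g N per kg sample) from a Kjeldahl back-titration.

    ``(ml_sample - ml_blank) * normality * 14.01 / sample_mass``: titre
    volume (mL) times normality (eq L-1) gives milliequivalents, times the
    14.01 mg per meq molar mass of N gives mg N, divided by the sample mass
    (g) gives mg g-1, i.e. g N per kg.
    """
    if t.ml_sample < t.ml_blank:
        raise ValueError(
            f"sample titre {t.ml_sample} mL below blank {t.ml_blank} mL: titration fault"
        )
    return (t.ml_sample - t.ml_blank) * t.hcl_normality * N_MOLAR_MASS / t.sample_mass


def harvest_index(fruit_mass: float, total_mass: float) -> float:
    """Fruit mass over total above-ground mass, rounded to 2 decimals."""
    if total_mass <= 0:
        raise ValueError(f"total mass must be positive, got {total_mass}")
    if fruit_mass < 0 or fruit_mass > total_mass:
        raise ValueError(f"fruit mass {fruit_mass} must lie in [0, {total_mass}]")
    return round(fruit_mass / total_mass, 2)


def fit_lai_curve(
    points: list[tuple[float, float]],
    dmla: float,
    dlai: float = 0.99,
) -> tuple[float, float]:
    """Fit the leaf-area S-curve to (season-fraction, LAI) data; return point-codes.

    LAI is normalized by ``dmla``, the linearized curve
    ``ln(x*(1-y)/y) = l1 - l2*x`` is fit by least squares over growth-phase
    points (season fraction <= ``dlai``), and the fitted curve is re-encoded
    as two point-codes: at the observed abscissa closest to 10 % of the
    season, and at the abscissa whose fitted ordinate is closest to 95 % of
    maximum.  Noiseless two-point input reproduces its generating codes.
    """
    if any(lai > dmla for _, lai in points):
        bad = [(x, lai) for x, lai in points if lai > dmla]
        raise ValueError(f"LAI observations exceed DMLA={dmla}: {bad}")
    usable = [
        (x, lai / dmla)
        for x, lai in points
        if 0.0 < x <= dlai and 0.0 < lai / dmla < 1.0
    ]
    if len(usable) < 2 or len({x for x, _ in usable}) < 2:
        raise ValueError(
            f"need >= 2 growth-phase points with distinct season fractions, got {len(usable)}"
        )
    xs = np.array([x for x, _ in usable])
    ys = np.array([y for _, y in usable])
    z = np.log(xs * (1.0 - ys) / ys)
    A = np.column_stack([np.ones_like(xs), -xs])
    (l1, l2), *_ = np.linalg.lstsq(A, z, rcond=None)
    if l2 <= 0:
        raise ValueError("fitted LAI curve is non-increasing (l2 <= 0); data inconsistent")
    coeffs = SCurveCoeffs(l1=float(l1), l2=float(l2))
    fitted = np.clip(scurve_eval(xs, coeffs), 0.01, 0.99)
    # canonical abscissae: early anchor near 10 % of season, plateau anchor near 95 %
    i1 = int(np.argmin(np.abs(xs - 0.10)))
    later = np.where(xs > xs[i1])[0]
    if len(later) == 0:
        raise ValueError("no usable point later than the early anchor")
    i2 = int(later[np.argmin(np.abs(fitted[later] - 0.95))])
    c1 = encode_point_code(SCurvePoint(xs[i1], round(float(fitted[i1]), 2)), "percent")
    c2 = encode_point_code(SCurvePoint(xs[i2], round(float(fitted[i2]), 2)), "percent")
    return c1, c2


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def estimate_bn(
    observations: list[TrialObservation],
    biomass_dry: list[float],
    huis: list[float] | None = None,
) -> tuple[float, float]:
    """Midseason and maturity N fractions (BN2, BN3) from staged harvests.

    Each stage contributes ``total_n / biomass_dry`` (both per plant, g).
    The stage whose heat-unit index is nearest 0.5 supplies BN2; nearest
    1.0 supplies BN3.  When ``huis`` is omitted, stages are mapped to HUI by
    ``day / max(day)``.  Fractions are reported to 3 significant figures.
    """
    if len(observations) < 2 or len(observations) != len(biomass_dry):
        raise ValueError("need >= 2 stages with matching biomass values")
    days = [o.day_after_treatment for o in observations]
    if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
        raise ValueError(f"stages must be in strictly increasing day order, got {days}")
    if any(b <= 0 for b in biomass_dry):
        raise ValueError("dry biomass must be positive at every stage")
    if huis is None:
        huis = [d / max(days) for d in days]
    fracs = [o.total_n / b for o, b in zip(observations, biomass_dry)]
    i_mid = int(np.argmin([abs(h - 0.5) for h in huis]))
    i_mat = int(np.argmin([abs(h - 1.0) for h in huis]))
    return _round_sig(fracs[i_mid]), _round_sig(fracs[i_mat])


def _grid_search(
    objective,
    search: tuple[float, float, float],
    label: str,
) -> float:
    lo, hi, step = search
    if not (lo < hi and step > 0):
        raise ValueError(f"malformed {label} search range (lo={lo}, hi={hi}, step={step})")
    best_val, best_loss = None, math.inf
    cand = lo
    while cand <= hi + 1e-9:
        loss = objective(cand)
        if loss < best_loss:  # strict: ties keep the earlier (smaller) candidate
            best_val, best_loss = cand, loss
        cand += step
    if best_val is None or not math.isfinite(best_loss):
        raise ValueError(f"no {label} candidate produced a finite yield error")
    return best_val


def estimate_phu(
    p: CropParameterSet,
    wx: WeatherSeries,
    m: ManagementSpec,
    measured_yield: float,
    search: tuple[float, float, float] = (1200.0, 3500.0, 50.0),
) -> float:
    """Site heat-unit requirement by matching simulated to measured yield.

    Grid search over PHU minimizing ``|simulated - measured|``; ties break
    toward the smaller PHU.
    """

    def objective(phu: float) -> float:
        try:
            res = run_season(p.with_updates(PHU=phu), wx, m, record=False)
        except ValueError:
            return math.inf
        return abs(res.yield_ - measured_yield)

    return _grid_search(objective, search, "PHU")


def estimate_wa_field(
    p_greenhouse: CropParameterSet,
    wx: WeatherSeries,
    m: ManagementSpec,
    measured_yield: float,
    search: tuple[float, float, float] = (15.0, 40.0, 0.5),
) -> float:
    """Field radiation-use efficiency by matching simulated to measured yield."""

    def objective(wa: float) -> float:
        try:
            res = run_season(p_greenhouse.with_updates(WA=wa, setting="field"),
                             wx, m, record=False)
        except ValueError:
            return math.inf
        return abs(res.yield_ - measured_yield)

    return _grid_search(objective, search, "WA")


def fresh_to_dry_areal(fresh_mass: float, moisture: float, density: float) -> float:
    """Per-plant fresh mass (g) to areal dry yield (Mg ha-1).

    ``fresh * (1 - moisture/100) * density * 0.01`` — 100 g dry m-2 is
    1 Mg ha-1.
    """
    if not 0.0 <= moisture <= 100.0:
        raise ValueError(f"moisture must lie in [0, 100] %, got {moisture}")
    if fresh_mass < 0 or density < 0:
        raise ValueError("fresh mass and density must be non-negative")
    return fresh_mass * (1.0 - moisture / 100.0) * density * 0.01
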