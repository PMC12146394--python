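"""Crop parameter sets and the S-curve point-code machinery.

The growth engine describes canopy development with a two-parameter logistic
S-curve ``f(x) = x / (x + exp(l1 - l2*x))`` anchored by two printed
"point-codes".  A point-code packs an (x, y) pair into one decimal number:
the integer part is the abscissa (percent of growing season for leaf-area
codes, plants per square metre for population codes) and the two fractional
digits are the ordinate as a percent of maximum.  ``10.19`` therefore means
"at 10 % of the season the canopy has reached 19 % of its maximum LAI".

The registry shipped with the package holds the four calibrated parameter
sets (accessions PHR18 and PHR23, each under greenhouse control and heat
conditions) plus the field adjustments (reduced radiation-use efficiency and
earlier leaf-area decline) used for open-field simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "SCurvePoint",
    "SCurveCoeffs",
    "CropParameterSet",
    "decode_point_code",
    "encode_point_code",
    "solve_scurve",
    "scurve_eval",
    "population_factor",
    "get_parameter_set",
    "load_registry",
    "ACCESSIONS",
    "CONDITIONS",
]

ACCESSIONS = ("PHR18", "PHR23")
CONDITIONS = ("control", "heat")


@dataclass(frozen=True)
class SCurvePoint:
    """One anchor of an S-curve: fraction-of-maximum ``y`` at abscissa ``x``."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not self.x > 0:
            raise ValueError(f"S-curve point abscissa must be positive, got {self.x}")
        if not 0.0 < self.y < 1.0:
            raise ValueError(f"S-curve point ordinate must lie in (0, 1), got {self.y}")


@dataclass(frozen=True)
class SCurveCoeffs:
    """Shape coefficients of ``f(x) = x / (x + exp(l1 - l2*x))``."""

    l1: float
    l2: float


def decode_point_code(code: float, x_scale: Literal["percent", "absolute"]) -> SCurvePoint:
    """Unpack a point-code into an :class:`SCurvePoint`.

    ``code=10.19, x_scale='percent'`` -> ``(x=0.10, y=0.19)``;
    ``code=4.99, x_scale='absolute'`` -> ``(x=4.0, y=0.99)``.
    """
    if code <= 0:
        raise ValueError(f"point code must be positive, got {code}")
    # Work in integer hundredths so 10.19 cannot decode as (10, 0.18999...).
    hundredths = round(code * 100)
    x_int, y_hundredths = divmod(hundredths, 100)
    if y_hundredths == 0:
        raise ValueError(
            f"point code {code} has zero fractional digits; y=0 is not an admissible ordinate"
        )
    x = x_int / 100.0 if x_scale == "percent" else float(x_int)
    return SCurvePoint(x=x, y=y_hundredths / 100.0)


def encode_point_code(p: SCurvePoint, x_scale: Literal["percent", "absolute"]) -> float:
    """Inverse of :func:`decode_point_code` (to the codec's 2-digit precision)."""
    x_int = round(p.x * 100) if x_scale == "percent" else round(p.x)
    y_hundredths = round(p.y * 100)
    if y_hundredths <= 0 or y_hundredths >= 100:
        raise ValueError(f"ordinate {p.y} not representable as two fractional digits")
    return x_int + y_hundredths / 100.0


def solve_scurve(p1: SCurvePoint, p2: SCurvePoint) -> SCurveCoeffs:
    """Coefficients of the S-curve passing exactly through two points.

    The form linearizes as ``ln(x*(1-y)/y) = l1 - l2*x``, so two points give
    a 2x2 linear system.
    """
    if p1.x == p2.x:
        raise ValueError("S-curve points must have distinct abscissae")
    if not (p1.x < p2.x and p1.y < p2.y):
        raise ValueError("S-curve points must be strictly increasing in both coordinates")
    z1 = math.log(p1.x * (1.0 - p1.y) / p1.y)
    z2 = math.log(p2.x * (1.0 - p2.y) / p2.y)
    l2 = (z1 - z2) / (p2.x - p1.x)
    l1 = z1 + l2 * p1.x
    if l2 <= 0:
        raise ValueError(
            f"points {p1}, {p2} imply a non-increasing curve (l2={l2:.4g} <= 0)"
        )
    return SCurveCoeffs(l1=l1, l2=l2)


def scurve_eval(x, c: SCurveCoeffs):
    """Evaluate the S-curve; ``f(0)=0`` and f is strictly increasing for x>0.

    Accepts scalars or numpy arrays.
    """
    x = np.asarray(x, dtype=float)
    out = x / (x + np.exp(c.l1 - c.l2 * x))
    return float(out) if out.ndim == 0 else out


def population_factor(density: float, ppl1: SCurvePoint, ppl2: SCurvePoint) -> float:
    """Fraction of maximum LAI attainable at a given plant density.

    The population S-curve through the two decoded PPL points, evaluated at
    ``density`` (plants per square metre).  Multiplies DMLA in the engine.
    """
    if density < 0:
        raise ValueError(f"plant density must be non-negative, got {density}")
    if density == 0:
        return 0.0
    return min(1.0, scurve_eval(density, solve_scurve(ppl1, ppl2)))


@dataclass(frozen=True)
class CropParameterSet:
    """Everything the daily engine needs for one accession x condition.

    Units: WA in kg ha-1 per MJ m-2 intercepted PAR; TB/TG in C; PHU in
    C day; HI, DMLA, DLAI, N fractions dimensionless.
    """

    accession: str
    condition: str
    WA: float
    HI: float
    TB: float
    TG: float
    DMLA: float
    dlap1_code: float
    dlap2_code: float
    ppl1_code: float
    ppl2_code: float
    CNY: float
    BN1: float
    BN2: float
    BN3: float
    PHU: float
    DLAI: float = 0.99
    k_ext: float = 0.65
    hui_flower: float = 0.30
    setting: str = "greenhouse"

    def __post_init__(self) -> None:
        if not self.TG < self.TB:
            raise ValueError(f"TG ({self.TG}) must be below TB ({self.TB})")
        if not 0.0 < self.HI <= 1.0:
            raise ValueError(f"HI must lie in (0, 1], got {self.HI}")
        if not self.BN1 >= self.BN2 >= self.BN3 > 0:
            raise ValueError(
                f"N-fraction anchors must satisfy BN1 >= BN2 >= BN3 > 0, "
                f"got {self.BN1}, {self.BN2}, {self.BN3}"
            )
        if not self.PHU > 0:
            raise ValueError(f"PHU must be positive, got {self.PHU}")
        if not 0.0 < self.DLAI <= 1.0:
            raise ValueError(f"DLAI must lie in (0, 1], got {self.DLAI}")
        d1, d2 = self.dlap_points()
        if not (d1.x < d2.x and d1.y < d2.y):
            raise ValueError(
                f"decoded DLAP points must increase in both coordinates: {d1}, {d2}"
            )

    def dlap_points(self) -> tuple[SCurvePoint, SCurvePoint]:
        return (
            decode_point_code(self.dlap1_code, "percent"),
            decode_point_code(self.dlap2_code, "percent"),
        )

    def ppl_points(self) -> tuple[SCurvePoint, SCurvePoint]:
        return (
            decode_point_code(self.ppl1_code, "absolute"),
            decode_point_code(self.ppl2_code, "absolute"),
        )

    def lai_curve(self) -> SCurveCoeffs:
        return solve_scurve(*self.dlap_points())

    def with_updates(self, **kwargs) -> "CropParameterSet":
        return replace(self, **kwargs)


def _registry_text(path: str | None) -> str:
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            return fh.read()
    return resources.files("peppersim.data").joinpath("parameters.yaml").read_text("utf-8")


def load_registry(path: str | None = None) -> dict:
    """Load the parameter registry (packaged YAML, or a user-supplied file)."""
    reg = yaml.safe_load(_registry_text(path))
    if not isinstance(reg, dict) or "sets" not in reg:
        raise ValueError("parameter registry must be a mapping with a 'sets' key")
    return reg


def get_parameter_set(
    accession: str,
    condition: str,
    setting: Literal["greenhouse", "field"] = "greenhouse",
    registry: dict | None = None,
) -> CropParameterSet:
    """Fetch a calibrated parameter set.

    ``setting='field'`` applies the open-field adjustments: WA scaled by the
    field/greenhouse RUE ratio established in the field calibration
    experiment (27/33, rounded to 2 decimals) and DLAI lowered to 0.9
    because field crops are harvested once leaf area declines.
    """
    reg = registry if registry is not None else load_registry()
    sets = reg["sets"]
    if accession not in sets or condition not in sets.get(accession, {}):
        valid = sorted(
            f"{a}/{c}" for a, conds in sets.items() for c in conds
        )
        raise KeyError(
            f"unknown parameter set {accession!r}/{condition!r}; valid keys: {valid}"
        )
    if setting not in ("greenhouse", "field"):
        raise ValueError(f"setting must be 'greenhouse' or 'field', got {setting!r}")
    row = sets[accession][condition]
    defaults = reg.get("defaults", {})
    wa = float(row["WA"])
    dlai = float(defaults.get("dlai_greenhouse", 0.99))
    if setting == "field":
        num = float(defaults.get("field_wa_ratio_num", 27))
        den = float(defaults.get("field_wa_ratio_den", 33))
        wa = round(wa * num / den, 2)
        dlai = float(defaults.get("dlai_field", 0.9))
    return CropParameterSet(
        accession=accession,
        condition=condition,
        WA=wa,
        HI=float(row["HI"]),
        TB=float(row["TB"]),
        TG=float(row["TG"]),
        DMLA=float(row["DMLA"]),
        dlap1_code=float(row["DLAP1"]),
        dlap2_code=float(row["DLAP2"]),
        ppl1_code=float(row["PPL1"]),
        ppl2_code=float(row["PPL2"]),
        CNY=float(row["CNY"]),
        BN1=float(row["BN1"]),
        BN2=float(row["BN2"]),
        BN3=float(row["BN3"]),
        PHU=float(row["PHU"]),
        DLAI=dlai,
        k_ext=float(defaults.get("k_ext", 0.65)),
        hui_flower=float(defaults.get("hui_flower", 0.30)),
        setting=setting,
    )
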