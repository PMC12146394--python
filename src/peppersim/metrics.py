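"""Derived statistics and report shaping: percent differences,
measured/simulated ratios, goodness-of-fit statistics (RMSE, PBIAS, R2),
and the per-site warming-scenario yield table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FitStats",
    "ScenarioReport",
    "percent_difference",
    "ratio",
    "fit_stats",
    "scenario_table",
]


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def percent_difference(control_value: float, treatment_value: float) -> int:
    """Integer percent change of treatment relative to control.

    Rounded half away from zero (so -31.5 % reports as -32, not -31).
    """
    if control_value == 0:
        raise ValueError("control value must be non-zero")
    return _round_half_away(100.0 * (treatment_value - control_value) / control_value)


def ratio(measured: float, simulated: float) -> float:
    """Measured over simulated, rounded to 2 decimals."""
    if simulated == 0:
        raise ValueError("simulated value must be non-zero")
    return round(measured / simulated, 2)


@dataclass(frozen=True)
class FitStats:
    """Goodness of fit between measured and simulated values.

    ``pbias`` keeps its sign internally (positive = model underestimates);
    report the magnitude via ``abs_pbias``.  ``r2`` is the squared Pearson
    correlation; it is ``nan`` (and ``r2_defined`` False) when either margin
    has zero variance.
    """

    rmse: float
    pbias: float
    r2: float
    n: int

    @property
    def abs_pbias(self) -> float:
        return abs(self.pbias)

    @property
    def r2_defined(self) -> bool:
        return not math.isnan(self.r2)


def fit_stats(pairs: list[tuple[float, float]]) -> FitStats:
    """RMSE, percent bias and squared Pearson correlation of (measured, simulated) pairs."""
    if len(pairs) < 1:
        raise ValueError("need at least one (measured, simulated) pair")
    m = np.array([p[0] for p in pairs], dtype=float)
    s = np.array([p[1] for p in pairs], dtype=float)
    rmse = float(np.sqrt(np.mean((m - s) ** 2)))
    if np.sum(m) == 0:
        raise ValueError("measured values sum to zero; PBIAS undefined")
    pbias = float(100.0 * np.sum(m - s) / np.sum(m))
    if len(pairs) >= 2 and np.std(m) > 0 and np.std(s) > 0:
        r2 = float(np.corrcoef(m, s)[0, 1] ** 2)
    else:
        r2 = float("nan")
    return FitStats(rmse=rmse, pbias=pbias, r2=r2, n=len(pairs))


@dataclass
class ScenarioReport:
    """Per-site reference yields vs simulated yields under uniform warming.

    One row per site; each warming level carries the simulated yield and the
    integer percent change versus the reference, formatted the conventional
    way as ``yield(percent)``, e.g. ``4.88(-35)``.
    """

    accession: str
    deltas: list[float]
    rows: list[dict] = field(default_factory=list)

    def add_row(self, province: str, city: str, reference: float,
                scenario_yields: dict[float, float]) -> None:
        row = {"province": province, "city": city, "reference": reference}
        for d in self.deltas:
            y = scenario_yields[d]
            row[d] = (y, percent_difference(reference, y))
        self.rows.append(row)

    @staticmethod
    def format_cell(yield_value: float, pct: int) -> str:
        return f"{yield_value:.2f}({pct:+d})".replace("(+", "(").replace("(-", "(-")

    def to_frame(self) -> pd.DataFrame:
        out = []
        for row in self.rows:
            rec = {
                "province": row["province"],
                "city": row["city"],
                "reference_Mg_ha": round(row["reference"], 2),
            }
            for d in self.deltas:
                y, pct = row[d]
                rec[f"+{d:g}C"] = self.format_cell(y, pct)
            out.append(rec)
        return pd.DataFrame(out)

    def to_text(self) -> str:
        f = self.to_frame()
        widths = {c: max(len(c), *(len(str(v)) for v in f[c])) for c in f.columns}
        lines = ["  ".join(c.ljust(widths[c]) for c in f.columns)]
        for _, r in f.iterrows():
            lines.append("  ".join(str(r[c]).ljust(widths[c]) for c in f.columns))
        return "\n".join(lines)


def scenario_table(
    baseline: dict[str, float],
    scenarios: dict[float, dict[str, float]],
    accession: str = "",
    site_meta: dict[str, tuple[str, str]] | None = None,
) -> ScenarioReport:
    """Assemble a :class:`ScenarioReport` from per-site yield maps.

    ``baseline`` maps site -> reference yield; ``scenarios`` maps warming
    delta -> site -> yield.  Every scenario must cover every baseline site.
    ``site_meta`` optionally maps site -> (province, city).
    """
    deltas = sorted(scenarios)
    for d in deltas:
        missing = sorted(set(baseline) - set(scenarios[d]))
        if missing:
            raise KeyError(f"scenario +{d:g}C missing sites: {missing}")
    report = ScenarioReport(accession=accession, deltas=deltas)
    for site in baseline:
        province, city = (site_meta or {}).get(site, ("", site))
        report.add_row(
            province, city, baseline[site],
            {d: scenarios[d][site] for d in deltas},
        )
    return report
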