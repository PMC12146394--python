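"""Daily weather series: CSV I/O, greenhouse schedules, a stochastic
Korean-like open-field generator, and warming perturbations.

The engine consumes only daily Tmax, Tmin, global solar radiation and
precipitation.  The open-field generator is deliberately simple — a seasonal
sinusoid for mean temperature with AR(1) anomalies, a clear-sky radiation
curve damped on rain days, and a seeded occurrence/amount precipitation
process — because its only role is to exercise the engine and the scenario
machinery with realistic Korean seasonality, not to emulate any station.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DailyWeather",
    "WeatherSeries",
    "Climatology",
    "LATITUDE_BANDS",
    "greenhouse_series",
    "synth_field_weather",
    "apply_delta",
    "read_weather_csv",
    "write_weather_csv",
]

_COLUMNS = ["date", "tmax", "tmin", "srad", "precip"]


@dataclass(frozen=True)
class DailyWeather:
    """One day of driving weather (temperatures C, srad MJ m-2 d-1, precip mm)."""

    date: dt.date
    tmax: float
    tmin: float
    srad: float
    precip: float

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValueError(f"{self.date}: tmax {self.tmax} < tmin {self.tmin}")
        if self.srad < 0:
            raise ValueError(f"{self.date}: negative solar radiation {self.srad}")
        if self.precip < 0:
            raise ValueError(f"{self.date}: negative precipitation {self.precip}")


@dataclass
class WeatherSeries:
    """An ordered, gap-free run of daily weather for one site."""

    frame: pd.DataFrame
    site: str = "unnamed"
    provenance: str = "observed"

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in _COLUMNS if c not in f.columns]
        if missing:
            raise ValueError(f"weather frame missing columns: {missing}")
        if len(f) == 0:
            raise ValueError("weather series is empty")
        f = f[_COLUMNS].reset_index(drop=True).copy()
        f["date"] = pd.to_datetime(f["date"])
        deltas = f["date"].diff().dropna()
        if len(deltas) and not (deltas == pd.Timedelta(days=1)).all():
            bad = int(np.argmax((deltas != pd.Timedelta(days=1)).to_numpy())) + 1
            raise ValueError(
                f"weather dates must be consecutive days; break at row {bad} "
                f"({f['date'].iloc[bad].date()})"
            )
        bad_rows = f.index[f["tmax"] < f["tmin"]]
        if len(bad_rows):
            i = int(bad_rows[0])
            raise ValueError(
                f"tmax < tmin at row {i} ({f['date'].iloc[i].date()}): "
                f"{f['tmax'].iloc[i]} < {f['tmin'].iloc[i]}"
            )
        if (f["srad"] < 0).any() or (f["precip"] < 0).any():
            raise ValueError("srad and precip must be non-negative")
        self.frame = f

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.Series:
        return self.frame["date"]

    def start(self) -> dt.date:
        return self.frame["date"].iloc[0].date()

    def end(self) -> dt.date:
        return self.frame["date"].iloc[-1].date()

    def window(self, start: dt.date, end: dt.date | None = None) -> "WeatherSeries":
        """Sub-series from ``start`` through ``end`` (inclusive)."""
        f = self.frame
        mask = f["date"] >= pd.Timestamp(start)
        if end is not None:
            mask &= f["date"] <= pd.Timestamp(end)
        sub = f.loc[mask]
        if len(sub) == 0:
            raise ValueError(f"no weather between {start} and {end} for site {self.site}")
        return WeatherSeries(sub, site=self.site, provenance=self.provenance)

    def records(self):
        for row in self.frame.itertuples(index=False):
            yield DailyWeather(
                date=row.date.date(), tmax=row.tmax, tmin=row.tmin,
                srad=row.srad, precip=row.precip,
            )


def greenhouse_series(
    day_set: float,
    night_set: float,
    start: dt.date,
    n_days: int,
    jitter_sd: float = 0.0,
    srad_mean: float = 18.0,
    seed: int = 0,
) -> WeatherSeries:
    """Setpoint-controlled greenhouse weather.

    Daily Tmax/Tmin equal the day/night setpoints plus independent Gaussian
    jitter (ventilation imperfection), truncated so tmax >= tmin.  Radiation
    is a constant ``srad_mean`` and precipitation zero (crops are fertigated).
    """
    if jitter_sd < 0:
        raise ValueError(f"jitter_sd must be non-negative, got {jitter_sd}")
    if day_set <= night_set:
        raise ValueError(f"day setpoint {day_set} must exceed night setpoint {night_set}")
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    rng = np.random.default_rng(seed)
    tmax = day_set + (rng.normal(0.0, jitter_sd, n_days) if jitter_sd > 0 else np.zeros(n_days))
    tmin = night_set + (rng.normal(0.0, jitter_sd, n_days) if jitter_sd > 0 else np.zeros(n_days))
    tmin = np.minimum(tmin, tmax)
    dates = pd.date_range(start, periods=n_days, freq="D")
    frame = pd.DataFrame(
        {"date": dates, "tmax": tmax, "tmin": tmin,
         "srad": np.full(n_days, float(srad_mean)), "precip": np.zeros(n_days)}
    )
    return WeatherSeries(frame, site="greenhouse", provenance="greenhouse-synthetic")


@dataclass(frozen=True)
class Climatology:
    """Seasonal parameters of the synthetic open-field generator.

    The deterministic skeleton is
    ``tmean(doy) = (tmean_jan+tmean_jul)/2 + amp*cos(2*pi*(doy-peak_doy)/365.25)``
    with ``amp=(tmean_jul-tmean_jan)/2``; tmax/tmin sit half a diurnal range
    above/below it.  AR(1) anomalies (sd ``anomaly_sd``, lag-1 correlation
    ``anomaly_rho``) are shared by tmax and tmin.  Radiation follows a
    clear-sky seasonal curve damped by ``rain_srad_factor`` on rain days;
    precipitation is Bernoulli occurrence with seasonal probability peaking
    at the summer monsoon, exponential amounts.
    """

    tmean_jan: float
    tmean_jul: float
    diurnal_range: float = 9.0
    peak_doy: int = 197          # mid-July temperature peak
    anomaly_sd: float = 2.2
    anomaly_rho: float = 0.7
    srad_summer: float = 22.0
    srad_winter: float = 8.0
    srad_noise: float = 0.10     # relative sd of day-to-day radiation noise
    rain_srad_factor: float = 0.45
    rain_prob_summer: float = 0.60   # monsoon-season wet-day probability
    rain_prob_winter: float = 0.12
    rain_peak_doy: int = 205
    rain_mean_summer: float = 20.0   # mm per wet day at the monsoon peak
    rain_mean_winter: float = 3.0

    def tmean(self, doy: np.ndarray) -> np.ndarray:
        mid = 0.5 * (self.tmean_jan + self.tmean_jul)
        amp = 0.5 * (self.tmean_jul - self.tmean_jan)
        return mid + amp * np.cos(2 * np.pi * (doy - self.peak_doy) / 365.25)

    def expected_tmax(self, doy: np.ndarray) -> np.ndarray:
        return self.tmean(doy) + 0.5 * self.diurnal_range

    def expected_tmax_peak(self) -> float:
        return self.tmean_jul + 0.5 * self.diurnal_range


# Synthetic stand-ins for Korean pepper-growing regions: the mountainous
# northeast is cooler, the southern coast milder and wetter.
LATITUDE_BANDS: dict[str, Climatology] = {
    "northern": Climatology(tmean_jan=-5.5, tmean_jul=23.5, diurnal_range=10.0),
    "central": Climatology(tmean_jan=-2.5, tmean_jul=25.5, diurnal_range=9.0),
    "southern": Climatology(tmean_jan=0.5, tmean_jul=26.5, diurnal_range=8.0,
                            rain_mean_summer=23.0),
}


def synth_field_weather(
    latitude_band: str,
    years: list[int],
    seed: int = 0,
    climatology: Climatology | None = None,
) -> WeatherSeries:
    """Generate whole calendar years of synthetic open-field weather.

    Reproducible: the same (band, years, seed, climatology) always yields an
    identical series.
    """
    if not years:
        raise ValueError("years must be non-empty")
    if climatology is None:
        try:
            climatology = LATITUDE_BANDS[latitude_band]
        except KeyError:
            raise KeyError(
                f"unknown latitude band {latitude_band!r}; "
                f"known bands: {sorted(LATITUDE_BANDS)}"
            ) from None
    c = climatology
    rng = np.random.default_rng(seed)
    frames = []
    for year in sorted(years):
        dates = pd.date_range(dt.date(year, 1, 1), dt.date(year, 12, 31), freq="D")
        n = len(dates)
        doy = dates.dayofyear.to_numpy(dtype=float)
        base = c.tmean(doy)
        # AR(1) anomalies shared by tmax/tmin (synoptic-scale variability)
        anom = np.zeros(n)
        if c.anomaly_sd > 0:
            innov_sd = c.anomaly_sd * np.sqrt(1 - c.anomaly_rho**2)
            eps = rng.normal(0.0, innov_sd, n)
            anom[0] = rng.normal(0.0, c.anomaly_sd)
            for i in range(1, n):
                anom[i] = c.anomaly_rho * anom[i - 1] + eps[i]
        tmean = base + anom
        tmax = tmean + 0.5 * c.diurnal_range
        tmin = tmean - 0.5 * c.diurnal_range
        # precipitation: seasonal Bernoulli occurrence + exponential amounts.
        # The squared seasonal weight concentrates rain in the summer monsoon
        # (jangma) and leaves spring comparatively dry, as in Korea.
        season = 0.5 * (1 + np.cos(2 * np.pi * (doy - c.rain_peak_doy) / 365.25))
        monsoon = season**2
        p_wet = c.rain_prob_winter + (c.rain_prob_summer - c.rain_prob_winter) * monsoon
        wet = rng.random(n) < p_wet
        mean_amt = c.rain_mean_winter + (c.rain_mean_summer - c.rain_mean_winter) * monsoon
        precip = np.where(wet, rng.exponential(1.0, n) * mean_amt, 0.0)
        # radiation: clear-sky seasonal curve (solstice peak), cloud damping
        solar_season = 0.5 * (1 + np.cos(2 * np.pi * (doy - 172) / 365.25))
        srad = c.srad_winter + (c.srad_summer - c.srad_winter) * solar_season
        if c.srad_noise > 0:
            srad = srad * np.clip(1 + rng.normal(0.0, c.srad_noise, n), 0.3, 1.7)
        srad = np.where(wet, srad * c.rain_srad_factor, srad)
        frames.append(pd.DataFrame(
            {"date": dates, "tmax": tmax, "tmin": tmin, "srad": srad, "precip": precip}
        ))
    frame = pd.concat(frames, ignore_index=True)
    return WeatherSeries(frame, site=latitude_band, provenance="field-synthetic")


def apply_delta(series: WeatherSeries, delta_t: float) -> WeatherSeries:
    """Uniform warming: add ``delta_t`` to every Tmax and Tmin.

    Radiation and precipitation are unchanged; dates and length preserved.
    """
    f = series.frame.copy()
    f["tmax"] = f["tmax"] + delta_t
    f["tmin"] = f["tmin"] + delta_t
    return WeatherSeries(f, site=series.site, provenance="perturbed")


def read_weather_csv(path) -> WeatherSeries:
    """Read the package's weather CSV dialect (``date,tmax,tmin,srad,precip``).

    Lines starting with ``#`` (provenance headers) are ignored.
    """
    frame = pd.read_csv(path, comment="#")
    if len(frame) == 0:
        raise ValueError(f"{path}: weather file contains no data rows")
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing weather columns {missing}")
    return WeatherSeries(frame, site=str(path), provenance="observed")


def write_weather_csv(series: WeatherSeries, path, header_comment: str | None = None) -> None:
    f = series.frame.copy()
    f["date"] = f["date"].dt.strftime("%Y-%m-%d")
    for c in ("tmax", "tmin", "srad", "precip"):
        f[c] = f[c].round(2)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        f.to_csv(fh, index=False)
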