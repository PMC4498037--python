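"""Weather ingestion, synthetic weather generation, reference evapotranspiration
and daily thermal-time accrual.

Two reference-evapotranspiration models are provided: the daily FAO-56
Penman–Monteith equation (used when net radiation, wind and humidity are
available) and the Hargreaves–Samani temperature-based model with a locally
calibrated exponent on the diurnal range.  Thermal time is accrued on the
daily mean temperature above a base temperature, capped at a maximum
temperature and zeroed at a cut-off temperature.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

logger = logging.getLogger(__name__)

#: Solar constant, MJ m-2 min-1 (FAO-56 convention).
GSC = 0.0820
#: Conversion from MJ m-2 day-1 to mm day-1 of evaporation equivalent.
MJ_TO_MM = 0.408


@dataclass(frozen=True)
class Site:
    """A simulation site.

    Parameters
    ----------
    latitude : float
        Degrees north (negative south). Must lie in [-90, 90].
    altitude : float
        Metres above sea level; enters the psychrometric constant.
    et0_model : str
        ``"penman_monteith"`` or ``"hargreaves"``.
    e_h : float
        Hargreaves exponent on the diurnal temperature range. The canonical
        value is 0.5; local calibrations may lower it (0.372 for a southern
        Italian plain).
    """

    latitude: float
    altitude: float = 0.0
    et0_model: str = "hargreaves"
    e_h: float = 0.5

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise DomainError(f"latitude {self.latitude} outside [-90, 90]")
        if self.e_h <= 0:
            raise DomainError("Hargreaves exponent e_h must be > 0")
        if self.et0_model not in ("penman_monteith", "hargreaves"):
            raise ConfigurationError(f"unknown ET0 model {self.et0_model!r}")


@dataclass(frozen=True)
class DailyWeather:
    """One day of meteorology at a site.

    Units: temperatures degC, rain mm/day, net radiation MJ m-2 day-1,
    wind speed at 2 m in m/s, relative humidities in percent.
    """

    date: dt.date
    tmin: float
    tmax: float
    rain: float
    rad_net: float | None = None
    wind2: float | None = None
    rhmin: float | None = None
    rhmax: float | None = None

    def __post_init__(self):
        if self.tmax < self.tmin:
            raise DomainError(f"{self.date}: tmax {self.tmax} < tmin {self.tmin}")
        if self.rain < 0:
            raise DomainError(f"{self.date}: negative rain {self.rain}")
        if (
            self.rhmin is not None
            and self.rhmax is not None
            and self.rhmin > self.rhmax
        ):
            raise DomainError(f"{self.date}: rhmin > rhmax")

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmin + self.tmax)

    def has_penman_fields(self) -> bool:
        return None not in (self.rad_net, self.wind2, self.rhmin, self.rhmax)


@dataclass(frozen=True)
class ThermalParams:
    """Cardinal temperatures for degree-day accrual (degC).

    ``tbase`` — base temperature below which no thermal time accrues;
    ``t_m1`` — maximum temperature at which accrual saturates;
    ``t_m2`` — cut-off temperature at/above which accrual is zero.
    """

    tbase: float = 10.0
    t_m1: float = 33.0
    t_m2: float = 38.0

    def __post_init__(self):
        if not self.tbase < self.t_m1 < self.t_m2:
            raise DomainError(
                f"require tbase < t_m1 < t_m2, got {self.tbase}, {self.t_m1}, {self.t_m2}"
            )


def extraterrestrial_radiation(site: Site, doy: int) -> float:
    """Daily extraterrestrial radiation Ra (MJ m-2 day-1), FAO-56 astronomy.

    ``doy`` is the day of year in [1, 366].
    """
    if not 1 <= doy <= 366:
        raise DomainError(f"day of year {doy} outside [1, 366]")
    phi = math.radians(site.latitude)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    # sunset hour angle; clip for polar day/night
    x = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))
    ra = (
        24.0 * 60.0 / math.pi
        * GSC
        * dr
        * (ws * math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta) * math.sin(ws))
    )
    return max(ra, 0.0)


def et0_hargreaves(w: DailyWeather, ra: float, e_h: float = 0.5) -> float:
    """Hargreaves–Samani reference evapotranspiration (mm/day).

    ET0 = 0.0023 * (0.408*Ra) * (Tmean + 17.8) * (Tmax - Tmin)**e_h,
    clipped at zero. ``e_h`` is the exponent on the diurnal range
    (canonically 0.5, locally calibratable).
    """
    if w.tmax < w.tmin:
        raise DomainError("tmax < tmin")
    et0 = 0.0023 * (MJ_TO_MM * ra) * (w.tmean + 17.8) * (w.tmax - w.tmin) ** e_h
    return max(et0, 0.0)


def _svp(t: float) -> float:
    """Saturation vapour pressure (kPa) at air temperature t (degC)."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def et0_penman_monteith(w: DailyWeather, site: Site) -> float:
    """Daily FAO-56 Penman–Monteith reference evapotranspiration (mm/day).

    Requires net radiation, 2-m wind speed and min/max relative humidity;
    soil heat flux is taken as zero at the daily step.
    """
    if not w.has_penman_fields():
        raise ConfigurationError(
            "Penman-Monteith needs rad_net, wind2, rhmin and rhmax; "
            "fall back to the Hargreaves model for this series"
        )
    t = w.tmean
    pressure = 101.3 * ((293.0 - 0.0065 * site.altitude) / 293.0) ** 5.26
    gamma = 0.000665 * pressure
    delta = 4098.0 * _svp(t) / (t + 237.3) ** 2
    es = 0.5 * (_svp(w.tmax) + _svp(w.tmin))
    ea = (_svp(w.tmin) * w.rhmax + _svp(w.tmax) * w.rhmin) / 200.0
    num = 0.408 * delta * w.rad_net + gamma * 900.0 / (t + 273.0) * w.wind2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * w.wind2)
    return max(num / den, 0.0)


def et0(w: DailyWeather, site: Site) -> float:
    """Reference ET0 for one day, dispatching on the site's model choice.

    Falls back (with a logged notice) to Hargreaves when the Penman–Monteith
    inputs are missing.
    """
    if site.et0_model == "penman_monteith":
        if w.has_penman_fields():
            return et0_penman_monteith(w, site)
        logger.info(
            "%s: Penman-Monteith inputs missing, falling back to Hargreaves", w.date
        )
    ra = extraterrestrial_radiation(site, w.date.timetuple().tm_yday)
    return et0_hargreaves(w, ra, site.e_h)


def thermal_time(w: DailyWeather, p: ThermalParams) -> float:
    """Growing degree-days accrued on one day (degC d).

    Based on the daily mean temperature: zero at/below the base temperature
    and at/above the cut-off; otherwise linear above the base, capped at the
    maximum temperature.
    """
    if w.tmax < w.tmin:
        raise DomainError("tmax < tmin")
    tmean = w.tmean
    if tmean <= p.tbase or tmean >= p.t_m2:
        return 0.0
    return min(tmean, p.t_m1) - p.tbase


# ---------------------------------------------------------------------------
# Synthetic weather generation


@dataclass(frozen=True)
class SeasonProfile:
    """Climatology for the synthetic weather generator.

    The daily mean temperature follows an annual sinusoid
    ``mean_temp + amplitude * cos(2*pi*(doy - peak_doy)/365.25)`` plus a
    Gaussian daily anomaly; the diurnal range is split symmetrically around
    the mean.  Rain is an intermittent process: wet days occur with
    probability ``rain_freq`` and wet-day depth is exponential with mean
    ``rain_mean`` (mm).
    """

    start: dt.date
    mean_temp: float
    amplitude: float
    diurnal_range: float = 12.0
    noise_sd: float = 1.8
    rain_freq: float = 0.12
    rain_mean: float = 6.0
    peak_doy: int = 197

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0.0 <= self.rain_freq <= 1.0:
            raise ConfigurationError("rain_freq must be in [0, 1]")
        if self.rain_mean < 0 or self.amplitude < 0 or self.diurnal_range < 0:
            raise ConfigurationError("rain_mean, amplitude, diurnal_range must be >= 0")


def mediterranean_profile(start: dt.date = dt.date(2005, 5, 10)) -> SeasonProfile:
    """Mediterranean lowland climatology (southern-Italian plain style):
    annual mean ~16.5 degC, strong seasonality, dry summers."""
    return SeasonProfile(
        start=start, mean_temp=16.5, amplitude=9.5, diurnal_range=12.0,
        noise_sd=1.8, rain_freq=0.12, rain_mean=6.0, peak_doy=197,
    )


def subtropical_profile(start: dt.date = dt.date(1996, 3, 15)) -> SeasonProfile:
    """Humid-subtropical climatology (Florida style): warm annual mean,
    damped seasonality, frequent convective rain."""
    return SeasonProfile(
        start=start, mean_temp=21.5, amplitude=7.0, diurnal_range=11.0,
        noise_sd=1.6, rain_freq=0.25, rain_mean=8.0, peak_doy=200,
    )


def generate_synthetic_weather(
    site: Site, profile: SeasonProfile, n_days: int, seed: int
) -> list[DailyWeather]:
    """Generate a reproducible daily weather series from a season profile.

    Guarantees tmax >= tmin and rain >= 0 on every day; the long-run mean
    temperature converges to the profile mean.
    """
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    days = []
    half = 0.5 * profile.diurnal_range
    for i in range(n_days):
        date = profile.start + dt.timedelta(days=i)
        doy = date.timetuple().tm_yday
        seasonal = profile.mean_temp + profile.amplitude * math.cos(
            2.0 * math.pi * (doy - profile.peak_doy) / 365.25
        )
        anomaly = rng.normal(0.0, profile.noise_sd) if profile.noise_sd > 0 else 0.0
        tmean = seasonal + anomaly
        wet = rng.random() < profile.rain_freq if profile.rain_freq > 0 else False
        rain = float(rng.exponential(profile.rain_mean)) if wet else 0.0
        days.append(
            DailyWeather(date=date, tmin=tmean - half, tmax=tmean + half, rain=rain)
        )
    return days


# ---------------------------------------------------------------------------
# Weather file IO

_REQUIRED_COLS = ("date", "tmin", "tmax", "rain")
_OPTIONAL_COLS = ("rad_net", "wind2", "rhmin", "rhmax")


def read_weather(path) -> list[DailyWeather]:
    """Read a delimited weather file (header ``date,tmin,tmax,rain[,...]``,
    ISO dates) into a list of :class:`DailyWeather`."""
    frame = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLS if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"weather file missing columns: {missing}")
    days = []
    for row in frame.itertuples(index=False):
        kwargs = {}
        for col in _OPTIONAL_COLS:
            if col in frame.columns:
                val = getattr(row, col)
                kwargs[col] = None if pd.isna(val) else float(val)
        days.append(
            DailyWeather(
                date=pd.Timestamp(row.date).date(),
                tmin=float(row.tmin),
                tmax=float(row.tmax),
                rain=float(row.rain),
                **kwargs,
            )
        )
    return days


def weather_frame(days: Iterable[DailyWeather]) -> pd.DataFrame:
    """Tabulate a weather series as a DataFrame (inverse of :func:`read_weather`)."""
    return pd.DataFrame([dataclasses.asdict(d) for d in days])


def write_weather(days: Sequence[DailyWeather], path) -> None:
    frame = weather_frame(days)
    # drop all-empty optional columns for tidy files
    for col in _OPTIONAL_COLS:
        if frame[col].isna().all():
            frame = frame.drop(columns=col)
    frame.to_csv(path, index=False)
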