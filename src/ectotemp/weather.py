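"""Synthetic hourly weather and near-ground microclimate generation.

Produces hourly forcing series with the statistical structure a
ground-level ectotherm heat-budget model needs: a diurnal and seasonal
air-temperature cycle with autocorrelated noise, clear-sky solar geometry
attenuated by a persistent cloudiness process, near-ground air and
ground-surface temperatures derived from fixed transfer rules, a reduced
wind speed at organism height, and stochastic precipitation with a
controllable dry-day fraction.

The module also builds paired "coarse vs. observed" series by applying a
smooth monotone distortion plus noise to a generated series
(:func:`distort_series`), so that distribution-mapping bias correction can
be tested by parameter recovery.

All temperatures are °C, radiation W/m², wind m/s, precipitation mm/h.
Timestamps are naive local civil time on an hourly grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "WeatherConfig",
    "MICROCLIMATE_COLUMNS",
    "solar_position",
    "generate_weather",
    "distort_series",
    "distort_precip",
    "write_weather_csv",
    "read_weather_csv",
]

#: Column order of a microclimate forcing table.
MICROCLIMATE_COLUMNS = [
    "timestamp",
    "T_air_2m",
    "T_air_ground",
    "T_ground",
    "wind_organism",
    "S_direct",
    "S_diffuse",
    "e_sky",
    "precip",
    "solar_elevation",
]

# Near-ground transfer rules (fixed, documented):
#   T_air_ground = T_air_2m + K_RAD_AIR * S_total - K_NIGHT_AIR * clear_night
#   T_ground     = T_air_2m + K_RAD_GROUND * S_total - K_NIGHT_GROUND * clear_night
# so T_ground >= T_air_2m whenever S_total > 0 (daytime) by construction.
K_RAD_AIR = 0.006  # °C per W/m² of total shortwave
K_RAD_GROUND = 0.012
K_NIGHT_AIR = 1.5  # °C drop on clear (cloud < 0.3) night hours
K_NIGHT_GROUND = 3.0

#: Log-profile reduction from 2 m wind to organism height (~1 cm in grass).
WIND_REDUCTION = 0.30

#: Clear-sky maximum horizontal irradiance at 90° solar elevation.
CLEAR_SKY_MAX = 1000.0

#: Diffuse fraction of total shortwave: clear sky -> overcast.
DIFFUSE_CLEAR = 0.15
DIFFUSE_OVERCAST = 1.0

#: Effective sky longwave emissivity: clear sky -> overcast.
E_SKY_CLEAR = 0.70
E_SKY_OVERCAST = 0.95

# AR(1) noise structure (hourly steps).
AR1_TEMP = 0.95  # air-temperature noise persistence
TEMP_NOISE_SD = 1.5  # stationary SD of air-temperature noise, °C
AR1_WIND = 0.90
WIND_NOISE_SD = 0.40  # stationary SD of log-wind noise


@dataclass(frozen=True)
class WeatherConfig:
    """Configuration of the synthetic weather generator.

    Defaults emulate the climate of a coastal meadow at ~43°N with a
    May–July mean air temperature of 16.4 °C.
    """

    latitude: float = 43.3
    longitude: float = -5.7
    start_date: date = field(default_factory=lambda: date(2019, 5, 1))
    end_date: date = field(default_factory=lambda: date(2019, 7, 31))
    seed: int = 0
    mean_daily_Tair: float = 16.4  # May–July mean of T_air_2m, °C
    diurnal_amplitude: float = 5.0  # half-range of the diurnal cycle, °C
    seasonal_amplitude: float = 6.0  # half-range of the annual cycle, °C
    cloud_persistence: float = 0.8  # AR(1) coefficient of cloudiness
    dry_day_fraction: float = 0.55  # target proportion of days with no rain
    mean_wind_2m: float = 2.5  # m/s
    utc_offset: float = 0.0  # civil time = UTC + offset, hours

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError("start_date must not be after end_date")
        if not 0.0 <= self.dry_day_fraction <= 1.0:
            raise ValueError("dry_day_fraction must be in [0, 1]")
        if not 0.0 <= self.cloud_persistence < 1.0:
            raise ValueError("cloud_persistence must be in [0, 1)")
        if self.diurnal_amplitude < 0 or self.seasonal_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")


def solar_position(timestamp, latitude: float, longitude: float,
                   utc_offset: float = 0.0):
    """Solar elevation angle (degrees) for local civil timestamps.

    Standard astronomical formulae: solar declination from day-of-year,
    hour angle from local solar time (civil time corrected for longitude
    and the equation of time). Accepts scalars or array-likes.
    """
    ts = pd.DatetimeIndex(np.atleast_1d(pd.to_datetime(timestamp)))
    doy = ts.dayofyear.to_numpy(dtype=float)
    hour = (ts.hour + ts.minute / 60.0 + ts.second / 3600.0).to_numpy(dtype=float)

    # Solar declination (Cooper's formula), degrees.
    decl = 23.45 * np.sin(np.deg2rad(360.0 * (284.0 + doy) / 365.0))
    # Equation of time, minutes.
    b = np.deg2rad(360.0 * (doy - 81.0) / 364.0)
    eot = 9.87 * np.sin(2 * b) - 7.53 * np.cos(b) - 1.5 * np.sin(b)
    # Local solar time, hours.
    solar_time = hour - utc_offset + longitude / 15.0 + eot / 60.0
    hour_angle = np.deg2rad(15.0 * (solar_time - 12.0))

    lat = np.deg2rad(latitude)
    d = np.deg2rad(decl)
    sin_elev = np.sin(lat) * np.sin(d) + np.cos(lat) * np.cos(d) * np.cos(hour_angle)
    elev = np.rad2deg(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))
    return elev[0] if np.isscalar(timestamp) or not np.iterable(timestamp) else elev


def _seasonal_shape(doy: np.ndarray) -> np.ndarray:
    """Annual temperature cycle shape: minimum mid-January, maximum mid-July."""
    return -np.cos(2.0 * np.pi * (doy - 19.0) / 365.25)


# Mean of the seasonal shape over May 1 – Jul 31 (doy 121..212, non-leap),
# used so that config.mean_daily_Tair is the May–July mean by construction.
_MAYJUL_SHAPE_MEAN = float(np.mean(_seasonal_shape(np.arange(121, 213, dtype=float))))


def generate_weather(config: WeatherConfig) -> pd.DataFrame:
    """Generate an hourly microclimate forcing table.

    Returns a DataFrame with :data:`MICROCLIMATE_COLUMNS`; fully
    reproducible given ``config.seed``. A degenerate date range yields an
    empty frame.
    """
    rng = np.random.default_rng(config.seed)
    index = pd.date_range(
        start=pd.Timestamp(config.start_date),
        end=pd.Timestamp(config.end_date) + pd.Timedelta(hours=23),
        freq="h",
    )
    n = len(index)
    if n == 0:
        return pd.DataFrame(columns=MICROCLIMATE_COLUMNS)

    doy = index.dayofyear.to_numpy(dtype=float)
    hour = index.hour.to_numpy(dtype=float)

    elev = solar_position(index, config.latitude, config.longitude,
                          config.utc_offset)
    sin_elev = np.clip(np.sin(np.deg2rad(elev)), 0.0, None)
    s_clear = CLEAR_SKY_MAX * sin_elev

    # Cloudiness: latent Gaussian AR(1) mapped through a probit to [0, 1].
    cloud_latent = _ar1(rng, n, config.cloud_persistence, 1.0)
    from scipy.stats import norm

    cloud = norm.cdf(cloud_latent)

    s_total = s_clear * (1.0 - 0.75 * cloud)
    diffuse_frac = DIFFUSE_CLEAR + (DIFFUSE_OVERCAST - DIFFUSE_CLEAR) * cloud
    s_diffuse = s_total * diffuse_frac
    s_direct = s_total - s_diffuse
    e_sky = np.clip(E_SKY_CLEAR + (E_SKY_OVERCAST - E_SKY_CLEAR) * cloud, None, 1.0)

    # 2 m air temperature: seasonal + diurnal + AR(1) noise. The seasonal
    # component is centred so the May–July mean equals mean_daily_Tair.
    t_seasonal = config.mean_daily_Tair + config.seasonal_amplitude * (
        _seasonal_shape(doy) - _MAYJUL_SHAPE_MEAN
    )
    t_diurnal = -config.diurnal_amplitude * np.cos(2.0 * np.pi * (hour - 15.0) / 24.0)
    t_noise = _ar1(rng, n, AR1_TEMP, TEMP_NOISE_SD)
    t_air_2m = t_seasonal + t_diurnal + t_noise

    clear_night = ((sin_elev <= 0.0) & (cloud < 0.3)).astype(float)
    t_air_ground = t_air_2m + K_RAD_AIR * s_total - K_NIGHT_AIR * clear_night
    t_ground = t_air_2m + K_RAD_GROUND * s_total - K_NIGHT_GROUND * clear_night

    log_wind_noise = _ar1(rng, n, AR1_WIND, WIND_NOISE_SD)
    wind_2m = config.mean_wind_2m * np.exp(log_wind_noise - WIND_NOISE_SD**2 / 2.0)
    wind_organism = WIND_REDUCTION * wind_2m

    precip = _generate_precip(rng, index, config.dry_day_fraction)

    return pd.DataFrame(
        {
            "timestamp": index,
            "T_air_2m": t_air_2m,
            "T_air_ground": t_air_ground,
            "T_ground": t_ground,
            "wind_organism": wind_organism,
            "S_direct": s_direct,
            "S_diffuse": s_diffuse,
            "e_sky": e_sky,
            "precip": precip,
            "solar_elevation": np.asarray(elev, dtype=float),
        }
    )


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series of length n with marginal SD ``sd``."""
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    return x


def _generate_precip(rng: np.random.Generator, index: pd.DatetimeIndex,
                     dry_day_fraction: float) -> np.ndarray:
    """Hourly precipitation (mm/h): Bernoulli wet days, gamma daily totals
    spread over a random block of 1–6 hours."""
    n = len(index)
    n_days = n // 24  # index always spans whole days (00:00–23:00)
    precip = np.zeros(n)
    for i in range(n_days):
        if rng.random() < dry_day_fraction:
            continue
        total = rng.gamma(shape=0.8, scale=6.0)  # mean ~4.8 mm per wet day
        n_hours = int(rng.integers(1, 7))
        start = int(rng.integers(0, 24 - n_hours + 1))
        wet = slice(24 * i + start, 24 * i + start + n_hours)
        precip[wet] += total / n_hours
    return precip


def _check_monotone_warp(coeffs: np.ndarray, lo: float, hi: float) -> None:
    grid = np.linspace(lo, hi, 512)
    deriv = np.polynomial.polynomial.polyval(grid, np.polynomial.polynomial.polyder(coeffs))
    if np.any(deriv <= 0.0):
        raise ValueError("warp must be strictly increasing over the data range")


def distort_series(observed, warp_coeffs, noise_sd: float, seed: int) -> np.ndarray:
    """Create a coarse ("reanalysis-like") series from an observed one.

    ``warp_coeffs`` are polynomial coefficients in ascending order
    (e.g. ``[2, 1.1]`` for 1.1·x + 2); the warp must be strictly monotone
    increasing over the data range. Gaussian noise with SD ``noise_sd`` is
    added on top.
    """
    obs = np.asarray(observed, dtype=float)
    coeffs = np.asarray(warp_coeffs, dtype=float)
    _check_monotone_warp(coeffs, float(np.nanmin(obs)), float(np.nanmax(obs)))
    rng = np.random.default_rng(seed)
    warped = np.polynomial.polynomial.polyval(obs, coeffs)
    if noise_sd > 0:
        warped = warped + rng.normal(0.0, noise_sd, size=obs.shape)
    return warped


def distort_precip(observed_daily, drizzle_fraction: float, seed: int,
                   drizzle_max: float = 0.5) -> np.ndarray:
    """Add spurious drizzle to a fraction of observed-dry days.

    Emulates the wet-day bias of coarse climate products, which rain too
    often: each observed-dry day independently receives a small positive
    total with probability ``drizzle_fraction``.
    """
    obs = np.asarray(observed_daily, dtype=float)
    if np.any(obs < 0):
        raise ValueError("precipitation must be non-negative")
    rng = np.random.default_rng(seed)
    out = obs.copy()
    dry = obs == 0.0
    hit = dry & (rng.random(obs.shape) < drizzle_fraction)
    out[hit] = rng.uniform(0.05, drizzle_max, size=int(hit.sum()))
    return out


def write_weather_csv(frame: pd.DataFrame, path) -> None:
    """Write a forcing table as CSV with ISO-8601 timestamps; missing
    values become empty fields."""
    out = frame.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, na_rep="")


def read_weather_csv(path) -> pd.DataFrame:
    """Read a forcing table written by :func:`write_weather_csv`."""
    frame = pd.read_csv(path)
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    return frame
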