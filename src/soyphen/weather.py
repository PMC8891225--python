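"""Synthetic daily weather for contrasting growing seasons.

Two archetypes are provided: ``hot_dry`` (warm, sunny, low humidity and
little rain — the kind of season in which drought symptoms develop quickly)
and ``cool_humid`` (cooler, cloudier, wetter — symptoms develop slowly).
Each day is drawn around a smooth seasonal cycle with AR(1)-correlated
anomalies, so consecutive days are realistically persistent.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WeatherConfig", "ARCHETYPES", "simulate_weather", "validate_weather"]

WEATHER_COLUMNS = ["date", "tmin", "tmax", "rh_mean", "radiation", "wind2m", "precip"]


@dataclass(frozen=True)
class WeatherConfig:
    """Seasonal means around which daily values are drawn.

    ``t_mean`` is the midsummer daily mean temperature (degC), ``t_range`` the
    diurnal tmax-tmin spread, ``rad_peak`` the midsummer clear-ish-sky mean
    radiation (MJ m-2 d-1), ``rain_prob`` the daily probability of rain and
    ``rain_mean`` the mean depth (mm) of a rainy day.
    """

    t_mean: float
    t_range: float
    rh_mean: float
    rad_peak: float
    wind_mean: float
    rain_prob: float
    rain_mean: float


ARCHETYPES: dict[str, WeatherConfig] = {
    "hot_dry": WeatherConfig(
        t_mean=20.5, t_range=11.0, rh_mean=62.0, rad_peak=23.0,
        wind_mean=2.0, rain_prob=0.18, rain_mean=4.0,
    ),
    "cool_humid": WeatherConfig(
        t_mean=16.5, t_range=9.0, rh_mean=78.0, rad_peak=17.0,
        wind_mean=2.4, rain_prob=0.38, rain_mean=5.5,
    ),
}


def validate_weather(df: pd.DataFrame) -> None:
    """Check the daily-weather invariants, raising ValueError on violation."""
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weather table missing columns: {missing}")
    if (df["tmax"] < df["tmin"]).any():
        raise ValueError("tmax < tmin on some days")
    if ((df["rh_mean"] < 0) | (df["rh_mean"] > 100)).any():
        raise ValueError("rh_mean outside [0, 100]")
    if (df["precip"] < 0).any() or (df["radiation"] < 0).any():
        raise ValueError("negative precipitation or radiation")


def simulate_weather(
    season_archetype: str,
    start: _dt.date,
    n_days: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate ``n_days`` of daily weather from ``start``.

    The same seed drives both archetypes through identical anomaly draws, so
    paired hot_dry / cool_humid seasons differ only by their seasonal means
    — convenient for paired-season comparisons.
    """
    if n_days <= 0:
        raise ValueError("date range must span at least one day")
    try:
        cfg = ARCHETYPES[season_archetype]
    except KeyError:
        raise ValueError(
            f"unknown archetype {season_archetype!r}; choose from {sorted(ARCHETYPES)}"
        ) from None

    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy()
    # seasonal cycle peaking ~20 July (doy 201)
    season = np.cos(2 * np.pi * (doy - 201) / 365.0)

    # AR(1) temperature anomalies (3-day persistence scale)
    eps = rng.normal(0.0, 1.0, n_days)
    anom = np.empty(n_days)
    anom[0] = eps[0]
    phi = 0.7
    for i in range(1, n_days):
        anom[i] = phi * anom[i - 1] + np.sqrt(1 - phi**2) * eps[i]

    tmean = cfg.t_mean - 6.0 * (1 - season) / 2.0 + 2.2 * anom
    half_range = np.maximum(cfg.t_range / 2.0 + rng.normal(0, 1.0, n_days), 1.0)
    tmin = tmean - half_range
    tmax = tmean + half_range

    wet = rng.random(n_days) < cfg.rain_prob
    precip = np.where(wet, rng.exponential(cfg.rain_mean, n_days), 0.0)
    cloud = np.clip(np.where(wet, 0.6, 0.15) + rng.normal(0, 0.1, n_days), 0.0, 0.9)
    rad = np.maximum(cfg.rad_peak * (0.45 + 0.55 * season) * (1 - cloud), 0.5)
    rh = np.clip(cfg.rh_mean + 10.0 * wet - 3.0 * anom + rng.normal(0, 4.0, n_days), 20.0, 100.0)
    wind = np.maximum(rng.gamma(4.0, cfg.wind_mean / 4.0, n_days), 0.2)

    df = pd.DataFrame(
        {
            "date": dates.date,
            "tmin": np.round(tmin, 2),
            "tmax": np.round(tmax, 2),
            "rh_mean": np.round(rh, 1),
            "radiation": np.round(rad, 2),
            "wind2m": np.round(wind, 2),
            "precip": np.round(precip, 2),
        }
    )
    validate_weather(df)
    return df
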