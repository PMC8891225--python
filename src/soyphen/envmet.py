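"""Environmental indices: thermal time, FAO-56 ET0, water deficit and CWSI.

Thermal time (growing degree days, GDD) is the developmental clock for the
whole pipeline: plot time series are expressed in cumulative GDD from the
sowing date of the plot's growth group.  Reference evapotranspiration (ET0)
follows the FAO-56 Penman-Monteith formulation for daily data with soil heat
flux G = 0.  The cumulative water deficit (CWD) accumulates ET0 - P from a
fixed start of season.  The crop water stress index (CWSI) rescales the
canopy-air temperature difference between a non-stressed (lower) and a
non-transpiring (upper) baseline.

Conventions
-----------
* GDD uses a base temperature of 10 degC and a cap of 30 degC by default
  (conventional soybean values; both configurable).
* In the net-longwave term of ET0 the cloudiness factor
  ``1.35 Rs/Rso - 0.35`` is clipped to [0, 1] (relative shortwave Rs/Rso is
  first capped at 1), so a fully dark day contributes no radiative demand.
* CWSI is clamped to [0, 1].
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

__all__ = [
    "gdd_daily",
    "thermal_time",
    "et0_penman_monteith",
    "cumulative_water_deficit",
    "cwsi",
    "estimate_baselines",
    "build_env_table",
]

DEFAULT_TBASE = 10.0
DEFAULT_TCAP = 30.0


def gdd_daily(tmin, tmax, tbase: float = DEFAULT_TBASE, tcap: float = DEFAULT_TCAP):
    """Daily growing degree days with capped-average accumulation.

    ``max(0, (min(tmax, tcap) + min(tmin, tcap)) / 2 - tbase)``; works on
    scalars or arrays.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin")
    g = np.maximum(0.0, (np.minimum(tmax, tcap) + np.minimum(tmin, tcap)) / 2.0 - tbase)
    return float(g) if g.ndim == 0 else g


def thermal_time(
    weather: pd.DataFrame,
    sowing_date: _dt.date,
    tbase: float = DEFAULT_TBASE,
    tcap: float = DEFAULT_TCAP,
) -> pd.Series:
    """Cumulative GDD from ``sowing_date``, indexed by date.

    The axis starts at 0 on the sowing date (the sowing day's heat sum is
    credited at the end of that day).
    """
    dates = pd.to_datetime(weather["date"])
    mask = dates.dt.date >= sowing_date
    g = gdd_daily(weather.loc[mask, "tmin"], weather.loc[mask, "tmax"], tbase, tcap)
    cum = pd.Series(np.cumsum(g), index=dates[mask].dt.date, name="gdd_cum")
    return cum


def _svp(t):
    """Saturation vapour pressure (kPa) at air temperature t (degC)."""
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def et0_penman_monteith(
    weather: pd.DataFrame,
    latitude: float,
    elevation: float = 10.0,
    albedo: float = 0.23,
) -> pd.Series:
    """Daily FAO-56 Penman-Monteith reference evapotranspiration (mm d-1).

    Requires columns date, tmin, tmax, rh_mean, radiation, wind2m.  Actual
    vapour pressure is derived from mean relative humidity; net radiation
    combines shortwave (1 - albedo) absorption with the clipped net-longwave
    term described in the module docstring.
    """
    for col in ("date", "tmin", "tmax", "rh_mean", "radiation", "wind2m"):
        if col not in weather.columns:
            raise ValueError(f"weather table is missing required field '{col}'")
        if weather[col].isna().any():
            raise ValueError(f"weather field '{col}' contains missing values")

    tmin = weather["tmin"].to_numpy(float)
    tmax = weather["tmax"].to_numpy(float)
    rs = weather["radiation"].to_numpy(float)
    u2 = weather["wind2m"].to_numpy(float)
    rh = weather["rh_mean"].to_numpy(float)
    doy = pd.to_datetime(weather["date"]).dt.dayofyear.to_numpy()

    t = (tmax + tmin) / 2.0
    pressure = 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    gamma = 0.000665 * pressure
    delta = 4098.0 * _svp(t) / (t + 237.3) ** 2
    es = (_svp(tmax) + _svp(tmin)) / 2.0
    ea = np.minimum(rh / 100.0 * es, es)

    # extraterrestrial and clear-sky radiation
    phi = np.deg2rad(latitude)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    dec = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(dec), -1.0, 1.0))
    ra = (24.0 * 60.0 / np.pi) * 0.0820 * dr * (
        ws * np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.sin(ws)
    )
    rso = np.maximum((0.75 + 2e-5 * elevation) * ra, 1e-9)

    rns = (1.0 - albedo) * rs
    sigma = 4.903e-9
    tk4 = ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2.0
    cloud_f = np.clip(1.35 * np.clip(rs / rso, 0.0, 1.0) - 0.35, 0.0, 1.0)
    rnl = sigma * tk4 * (0.34 - 0.14 * np.sqrt(ea)) * cloud_f
    rn = rns - rnl

    num = 0.408 * delta * rn + gamma * (900.0 / (t + 273.0)) * u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2)
    et0 = np.maximum(num / den, 0.0)
    return pd.Series(et0, index=pd.to_datetime(weather["date"]).dt.date, name="et0")


def cumulative_water_deficit(
    et0: pd.Series,
    precip: pd.Series,
    start_date: _dt.date | None = None,
) -> pd.Series:
    """Running sum of daily ET0 - P from ``start_date`` (default: 1 April).

    Both series must be indexed by date and aligned; the deficit may go
    negative in wet spells.
    """
    if not et0.index.equals(precip.index):
        raise ValueError("et0 and precip series are not aligned on the same dates")
    idx = pd.Index(et0.index)
    if start_date is None:
        yr = pd.Timestamp(idx[0]).year
        start_date = _dt.date(yr, 4, 1)
    mask = idx >= start_date
    deficit = (et0[mask] - precip[mask]).cumsum()
    deficit.name = "cwd"
    return deficit


def cwsi(tc, ta, dt_ll: float, dt_ul: float):
    """Crop water stress index on [0, 1].

    0 at the non-stressed baseline (canopy-air difference ``dt_ll``), 1 at
    the non-transpiring baseline ``dt_ul``; values outside are clamped.
    """
    if not dt_ul > dt_ll:
        raise ValueError(f"upper baseline ({dt_ul}) must exceed lower baseline ({dt_ll})")
    dt = np.asarray(tc, dtype=float) - np.asarray(ta, dtype=float)
    s = np.clip((dt - dt_ll) / (dt_ul - dt_ll), 0.0, 1.0)
    return float(s) if s.ndim == 0 else s


def estimate_baselines(
    dt_values: pd.Series,
    well_watered_ids,
    q_low: float = 0.05,
    q_high: float = 0.95,
    margin: float = 0.0,
) -> tuple[float, float]:
    """Empirical CWSI baselines for one thermal flight.

    The lower (non-stressed) baseline is a low quantile of the canopy-air
    temperature difference among well-watered plots; the upper
    (non-transpiring) baseline is a high quantile over all plots plus an
    optional safety margin.  ``dt_values`` is indexed by plot id.

    Raises if fewer than 5 well-watered plots are present or if the spread
    is degenerate (suggesting manual baselines instead).
    """
    ww = dt_values.loc[dt_values.index.isin(set(well_watered_ids))]
    if len(ww) < 5:
        raise ValueError("need at least 5 well-watered plots to estimate baselines")
    dt_ll = float(np.quantile(ww.to_numpy(float), q_low))
    dt_ul = float(np.quantile(dt_values.to_numpy(float), q_high)) + margin
    if not dt_ul > dt_ll:
        raise ValueError(
            "degenerate canopy-air temperature spread; supply manual baselines"
        )
    return dt_ll, dt_ul


def build_env_table(
    weather: pd.DataFrame,
    sowing_dates: dict[int, _dt.date],
    latitude: float = 51.0,
    elevation: float = 10.0,
    tbase: float = DEFAULT_TBASE,
    tcap: float = DEFAULT_TCAP,
    cwd_start: _dt.date | None = None,
) -> pd.DataFrame:
    """Per-day environment table: GDD, cumulative GDD per sowing cohort, ET0, CWD."""
    out = pd.DataFrame({"date": pd.to_datetime(weather["date"]).dt.date})
    out["gdd_daily"] = gdd_daily(weather["tmin"], weather["tmax"], tbase, tcap)
    for gp, sow in sorted(sowing_dates.items()):
        tt = thermal_time(weather, sow, tbase, tcap)
        out[f"gdd_cum_gp{gp}"] = out["date"].map(tt).fillna(0.0)
    et0 = et0_penman_monteith(weather, latitude, elevation)
    out["et0"] = et0.to_numpy()
    precip = pd.Series(weather["precip"].to_numpy(float), index=out["date"])
    cwd = cumulative_water_deficit(pd.Series(et0.to_numpy(), index=out["date"]), precip, cwd_start)
    out["cwd"] = out["date"].map(cwd)
    return out
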