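import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from soyphen.envmet import (
    build_env_table,
    cumulative_water_deficit,
    cwsi,
    estimate_baselines,
    et0_penman_monteith,
    gdd_daily,
    thermal_time,
)
from soyphen.weather import simulate_weather, validate_weather


def fao56_reference_et0(day: dt.date, tmin, tmax, rh, rs, u2, lat_deg, z):
    """Independent scalar walk-through of the FAO-56 daily equation list.

    Written directly from the standard (pressure, psychrometric constant,
    slope of the vapour curve, vapour pressures from Tmin/Tmax and RHmean,
    extraterrestrial and clear-sky radiation, net short/longwave with the
    cloudiness factor clipped to [0, 1], G = 0).
    """
    e0 = lambda t: 0.6108 * math.exp(17.27 * t / (t + 237.3))
    p = 101.3 * ((293 - 0.0065 * z) / 293) ** 5.26
    gamma = 0.000665 * p
    tmean = (tmax + tmin) / 2
    delta = 4098 * e0(tmean) / (tmean + 237.3) ** 2
    es = (e0(tmax) + e0(tmin)) / 2
    ea = min(rh / 100 * es, es)
    j = day.timetuple().tm_yday
    phi = math.radians(lat_deg)
    dr = 1 + 0.033 * math.cos(2 * math.pi * j / 365)
    dec = 0.409 * math.sin(2 * math.pi * j / 365 - 1.39)
    ws = math.acos(max(-1, min(1, -math.tan(phi) * math.tan(dec))))
    ra = (
        24 * 60 / math.pi * 0.0820 * dr
        * (ws * math.sin(phi) * math.sin(dec) + math.cos(phi) * math.cos(dec) * math.sin(ws))
    )
    rso = (0.75 + 2e-5 * z) * ra
    rns = 0.77 * rs
    f = 1.35 * min(rs / rso, 1.0) - 0.35
    f = min(max(f, 0.0), 1.0)
    rnl = (
        4.903e-9 * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2
        * (0.34 - 0.14 * math.sqrt(ea)) * f
    )
    rn = rns - rnl
    num = 0.408 * delta * rn + gamma * 900 / (tmean + 273) * u2 * (es - ea)
    return max(num / (delta + gamma * (1 + 0.34 * u2)), 0.0)


class TestWeatherGenerator:
    def test_invariants_and_length(self):
        wx = simulate_weather("hot_dry", dt.date(2018, 4, 1), 180, seed=1)
        assert len(wx) == 180
        validate_weather(wx)  # tmax >= tmin, rh in [0,100], precip/rad >= 0

    def test_seeded_determinism(self):
        a = simulate_weather("cool_humid", dt.date(2019, 4, 1), 90, seed=7)
        b = simulate_weather("cool_humid", dt.date(2019, 4, 1), 90, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_hot_dry_is_warmer_than_cool_humid_on_paired_seeds(self):
        hotter = 0
        for seed in range(100):
            hot = simulate_weather("hot_dry", dt.date(2018, 5, 1), 120, seed=seed)
            cool = simulate_weather("cool_humid", dt.date(2018, 5, 1), 120, seed=seed)
            hotter += (hot["tmax"] + hot["tmin"]).mean() > (cool["tmax"] + cool["tmin"]).mean()
        assert hotter == 100

    def test_unknown_archetype_and_empty_range(self):
        with pytest.raises(ValueError, match="archetype"):
            simulate_weather("tropical", dt.date(2018, 4, 1), 10)
        with pytest.raises(ValueError, match="at least one day"):
            simulate_weather("hot_dry", dt.date(2018, 4, 1), 0)


class TestThermalTime:
    @pytest.mark.parametrize(
        "tmax, tmin, expected", [((25, 15), 10, 10.0), ((8, 4), 10, 0.0), ((36, 20), 10, 15.0)]
    )
    def test_capped_average_rule(self, tmax, tmin, expected):
        hi, lo = tmax
        assert gdd_daily(lo, hi, tbase=tmin, tcap=30.0) == pytest.approx(expected)

    def test_tmax_below_tmin_raises(self):
        with pytest.raises(ValueError):
            gdd_daily(20.0, 10.0)

    def test_cumulative_axis_starts_at_sowing_and_is_nondecreasing(self):
        wx = simulate_weather("hot_dry", dt.date(2018, 4, 1), 120, seed=3)
        tt = thermal_time(wx, dt.date(2018, 4, 20))
        assert tt.index[0] == dt.date(2018, 4, 20)
        assert (np.diff(tt.to_numpy()) >= 0).all()


class TestET0:
    def _frame(self, **kw):
        base = {
            "date": [dt.date(2018, 7, 6)],
            "tmin": [12.3],
            "tmax": [21.5],
            "rh_mean": [68.0],
            "radiation": [22.1],
            "wind2m": [2.8],
            "precip": [0.0],
        }
        base.update(kw)
        return pd.DataFrame(base)

    def test_dark_calm_saturated_day_gives_zero(self):
        wx = self._frame(radiation=[0.0], wind2m=[0.0], rh_mean=[100.0], tmin=[15.0], tmax=[15.0])
        assert et0_penman_monteith(wx, latitude=51.0).iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_fao56_oracle(self, rng):
        """Vectorized implementation vs. scalar standard walk-through, 50 random days."""
        days, rows = [], []
        for i in range(50):
            day = dt.date(2018, 4, 1) + dt.timedelta(days=int(rng.integers(0, 180)))
            tmin = float(rng.uniform(2, 18))
            tmax = tmin + float(rng.uniform(2, 16))
            rh = float(rng.uniform(35, 100))
            rs = float(rng.uniform(0.5, 30))
            u2 = float(rng.uniform(0.2, 6))
            days.append((day, tmin, tmax, rh, rs, u2))
            rows.append(
                {"date": day, "tmin": tmin, "tmax": tmax, "rh_mean": rh,
                 "radiation": rs, "wind2m": u2, "precip": 0.0}
            )
        ours = et0_penman_monteith(pd.DataFrame(rows), latitude=51.0, elevation=10.0)
        for (day, tmin, tmax, rh, rs, u2), got in zip(days, ours):
            want = fao56_reference_et0(day, tmin, tmax, rh, rs, u2, 51.0, 10.0)
            assert got == pytest.approx(want, abs=0.05)

    def test_monotone_in_radiation(self):
        vals = [
            et0_penman_monteith(self._frame(radiation=[r]), latitude=51.0).iloc[0]
            for r in (5.0, 15.0, 25.0)
        ]
        assert vals[0] < vals[1] < vals[2]

    def test_missing_field_is_named(self):
        with pytest.raises(ValueError, match="wind2m"):
            et0_penman_monteith(self._frame().drop(columns="wind2m"), latitude=51.0)


class TestCWD:
    def _series(self, values, start=dt.date(2018, 4, 1)):
        idx = [start + dt.timedelta(days=i) for i in range(len(values))]
        return pd.Series(values, index=idx)

    def test_constant_demand(self):
        cwd = cumulative_water_deficit(self._series([5.0] * 10), self._series([0.0] * 10))
        assert cwd.iloc[-1] == pytest.approx(50.0)

    def test_balanced_budget_is_zero(self):
        et0 = self._series([3.0, 1.0, 4.0])
        assert cumulative_water_deficit(et0, et0.copy()).abs().max() == 0.0

    def test_prefix_sum_oracle(self, rng):
        et0 = self._series(rng.uniform(0, 7, 60))
        p = self._series(rng.exponential(2, 60))
        got = cumulative_water_deficit(et0, p)
        acc, want = 0.0, []
        for e, pr in zip(et0, p):  # brute-force running sum
            acc += e - pr
            want.append(acc)
        np.testing.assert_allclose(got.to_numpy(), want, rtol=1e-12)

    def test_misaligned_dates_raise(self):
        with pytest.raises(ValueError, match="aligned"):
            cumulative_water_deficit(
                self._series([1.0, 2.0]), self._series([1.0, 2.0], start=dt.date(2018, 4, 2))
            )

    def test_hot_dry_deficit_dominates_cool_humid(self):
        sow = {1: dt.date(2018, 4, 20)}
        wins = 0
        for seed in range(20):
            tables = {}
            for arch in ("hot_dry", "cool_humid"):
                wx = simulate_weather(arch, dt.date(2018, 4, 1), 150, seed=seed)
                tables[arch] = build_env_table(wx, sow)["cwd"].iloc[-1]
            wins += tables["hot_dry"] > tables["cool_humid"]
        assert wins == 20


class TestCWSI:
    @pytest.mark.parametrize("dt_obs, expected", [(-2.0, 0.0), (6.0, 1.0), (2.0, 0.5)])
    def test_baseline_scaling(self, dt_obs, expected):
        assert cwsi(25.0 + dt_obs, 25.0, -2.0, 6.0) == pytest.approx(expected)

    def test_clamped_outside_baselines(self):
        assert cwsi(10.0, 25.0, -2.0, 6.0) == 0.0
        assert cwsi(40.0, 25.0, -2.0, 6.0) == 1.0

    def test_inverted_baselines_raise(self):
        with pytest.raises(ValueError):
            cwsi(25.0, 25.0, 6.0, -2.0)

    def test_baseline_estimation_from_separated_groups(self):
        dt_vals = pd.Series(
            [-2.0] * 10 + [6.0] * 10, index=[f"W{i}" for i in range(10)] + [f"S{i}" for i in range(10)]
        )
        ll, ul = estimate_baselines(dt_vals, [f"W{i}" for i in range(10)])
        assert (ll, ul) == (-2.0, 6.0)

    def test_degenerate_spread_raises(self):
        flat = pd.Series([1.0] * 12, index=[f"P{i}" for i in range(12)])
        with pytest.raises(ValueError, match="manual baselines"):
            estimate_baselines(flat, [f"P{i}" for i in range(6)])

    def test_too_few_well_watered_plots(self):
        vals = pd.Series([0.0, 1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcdef"))
        with pytest.raises(ValueError, match="5 well-watered"):
            estimate_baselines(vals, ["a", "b"])
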