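"""Full synthetic-trial scenarios: design + weather + effects + series.

:class:`TrialSimulator` assembles everything the generator modules provide
into a two-season, two-treatment trial that emulates the reference study's
conditions: 359 genotypes in four growth groups (454 plots per field through
check replication), staggered sowing, one hot/dry season with a short
drought and one cool/humid season with a long drought, beta-sigmoid canopy
growth, sigmoid reproductive-stage progression, accelerated senescence and
reduced asymptotic height under drought, sub-30% emergence failures, and
thermal flights following the linear canopy-temperature stress model.

All magnitudes live in :data:`DEFAULT_CONFIG` (a nested dict mirrored by the
YAML config file): treatment multipliers reproduce the reported average
responses (short drought: canopy height x0.89; long drought: x0.71, i.e.
-11% and -29%), sowing densities and plot geometry follow the growth-group
scheme, and the emergence failure rate of 7% matches the scale of the
plots removed by the 30% emergence filter.
"""

from __future__ import annotations

import copy
import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import envmet, weather as _weather
from .design import build_design
from .simulate import (
    CurveConfig,
    EffectConfig,
    NoiseConfig,
    TreatmentEffect,
    simulate_canopy_temperature,
    simulate_curve_params,
    simulate_effects,
    simulate_emergence,
    simulate_plot_series,
)

__all__ = ["DEFAULT_CONFIG", "merge_config", "validate_config", "TrialSimulator", "SimulationOutput"]


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "design": {
        "n_unreplicated": 334,
        "check_classes": [[3, 9], [9, 6], [13, 3]],
        "grid": [6, 9],
        "n_blocks": 9,
    },
    "weather": {"latitude": 51.0, "elevation": 10.0, "n_days": 190},
    "thermal_time": {"tbase": 10.0, "tcap": 30.0},
    # season start is 1 April of the year label; sowing_days are offsets from it
    "years": {
        "2018": {"archetype": "hot_dry", "treatment_effect": "short"},
        "2019": {"archetype": "cool_humid", "treatment_effect": "long"},
    },
    "sowing_days": {1: 19, 2: 31, 3: 37, 4: 40},
    "flight_days": [50, 59, 68, 77, 86, 95, 104, 113, 122, 131, 140, 149, 158, 167, 176],
    "thermal_flight_days": [95, 101, 108, 117],
    "drought_start_day": 82,
    "emergence": {"failure_rate": 0.07},
    "noise": {
        "height": 1.5,
        "cover": 0.015,
        "rstage": 0.15,
        "canopy_temp": 0.25,
        "stress_spread": 0.05,
    },
    "cwsi": {"dt_ll": -4.0, "dt_ul": 6.0, "q_low": 0.05, "q_high": 0.95, "margin": 0.0},
    "senescence": {"onset_gdd": 750.0, "rate_per_gdd": 0.0005},
    "curves": {
        "height": {
            "wmax_mu": {1: 95.0, 2: 90.0, 3: 85.0, 4: 80.0},
            "wmax_sigma2": {"g": 36.0, "block": 4.0, "row": 1.0, "col": 1.0, "e": 16.0},
            "te_mu": {1: 900.0, 2: 860.0, 3: 820.0, 4: 780.0},
            "te_sigma_g": 25.0,
            "tm_frac": 0.45,
        },
        "cover": {
            "wmax_mu": {1: 0.95, 2: 0.95, 3: 0.94, 4: 0.93},
            "wmax_sigma2": {"g": 4e-4, "block": 1e-4, "row": 0.0, "col": 0.0, "e": 4e-4},
            "te_mu": {1: 620.0, 2: 600.0, 3: 580.0, 4: 560.0},
            "te_sigma_g": 20.0,
            "tm_frac": 0.5,
            "wmax_mult_weight": 0.25,
            "shift_weight": 1.0,
        },
        "r_stage": {
            "wmax_mu": {1: 6.5, 2: 6.5, 3: 6.5, 4: 6.5},
            "wmax_sigma2": {"g": 0.01, "block": 0.0, "row": 0.0, "col": 0.0, "e": 0.005},
            "te_mu": {1: 980.0, 2: 940.0, 3: 900.0, 4: 860.0},
            "te_sigma_g": 30.0,
            "tm_frac": 0.5,
            "wmax_mult_weight": 0.0,
            "shift_weight": 1.0,
        },
    },
    "manual_traits": {
        "PLV": {
            "mu": {1: 10.8, 2: 10.8, 3: 10.9, 4: 11.0},
            "sigma2": {"g": 1.8, "block": 0.2, "row": 0.05, "col": 0.05, "e": 0.6},
        },
        "R8": {
            "mu": {1: 1250.0, 2: 1200.0, 3: 1150.0, 4: 1100.0},
            "sigma2": {"g": 4000.0, "block": 300.0, "row": 80.0, "col": 80.0, "e": 900.0},
        },
        "PPS": {
            "mu": {1: 26.0, 2: 25.0, 3: 23.0, 4: 22.0},
            "sigma2": {"g": 6.0, "block": 0.5, "row": 0.1, "col": 0.1, "e": 4.0},
        },
        "SN": {
            "mu": {1: 85.0, 2: 80.0, 3: 72.0, 4: 65.0},
            "sigma2": {"g": 350.0, "block": 30.0, "row": 8.0, "col": 8.0, "e": 160.0},
        },
        "SW": {
            "mu": {1: 14.5, 2: 13.5, 3: 12.5, 4: 11.5},
            "sigma2": {"g": 9.0, "block": 0.7, "row": 0.2, "col": 0.2, "e": 4.0},
        },
    },
    # drought-field-only repeated visual scores; days after treatment start
    "score_traits": {
        "CW": {
            "days": [5, 11, 25],
            "mu": [4.2, 5.1, 3.0],
            "sigma2": {"g": 0.35, "block": 0.05, "row": 0.0, "col": 0.0, "e": 0.35},
        },
        "LSEN": {
            "days": [12, 17, 28],
            "mu": [2.8, 3.3, 4.1],
            "sigma2": {"g": 0.35, "block": 0.05, "row": 0.0, "col": 0.0, "e": 0.35},
        },
    },
    "treatment_effects": {
        "control": {"stress": 0.06},
        "short": {
            "wmax_mult": 0.89,
            "tm_shift": -10.0,
            "te_shift": -30.0,
            "senescence_accel": 1.3,
            "senescence_onset_shift": -60.0,
            "stress": 0.6,
            "trait_mult": {"R8": 1.0, "PPS": 1.02, "SN": 0.83, "SW": 0.84, "PLV": 1.0},
        },
        "long": {
            "wmax_mult": 0.71,
            "tm_shift": -20.0,
            "te_shift": -50.0,
            "senescence_accel": 1.9,
            "senescence_onset_shift": -120.0,
            "stress": 0.7,
            "trait_mult": {"R8": 0.95, "PPS": 0.74, "SN": 0.62, "SW": 0.57, "PLV": 1.0},
        },
    },
}


def merge_config(overrides: dict | None) -> dict:
    """Deep-merge user overrides into the default configuration."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def _merge(base, over, path=""):
        for key, val in over.items():
            if isinstance(val, dict) and isinstance(base.get(key), dict):
                _merge(base[key], val, f"{path}{key}.")
            else:
                base[key] = copy.deepcopy(val)

    if overrides:
        _merge(cfg, overrides)
    return cfg


def validate_config(cfg: dict) -> None:
    """Reject unknown top-level or second-level keys, naming the offender."""

    def _check(defaults, given, path=""):
        for key in given:
            if key not in defaults:
                raise ValueError(f"unknown configuration key: '{path}{key}'")

    _check(DEFAULT_CONFIG, cfg)
    for section in ("design", "weather", "thermal_time", "emergence", "noise", "cwsi", "senescence"):
        if section in cfg and isinstance(cfg[section], dict):
            _check(DEFAULT_CONFIG[section], cfg[section], f"{section}.")


def _effect_config(entry: dict) -> EffectConfig:
    mu = entry["mu"]
    if isinstance(mu, dict):
        mu = {int(k): float(v) for k, v in mu.items()}
    s2 = entry.get("sigma2", {})
    return EffectConfig(
        mu=mu,
        sigma2_g=float(s2.get("g", 1.0)),
        sigma2_block=float(s2.get("block", 0.0)),
        sigma2_row=float(s2.get("row", 0.0)),
        sigma2_col=float(s2.get("col", 0.0)),
        sigma2_e=float(s2.get("e", 1.0)),
    )


def _curve_config(entry: dict) -> CurveConfig:
    s2 = entry.get("wmax_sigma2", {})
    wmax = EffectConfig(
        mu={int(k): float(v) for k, v in entry["wmax_mu"].items()}
        if isinstance(entry["wmax_mu"], dict)
        else float(entry["wmax_mu"]),
        sigma2_g=float(s2.get("g", 0.0)),
        sigma2_block=float(s2.get("block", 0.0)),
        sigma2_row=float(s2.get("row", 0.0)),
        sigma2_col=float(s2.get("col", 0.0)),
        sigma2_e=float(s2.get("e", 0.0)),
    )
    te_mu = entry["te_mu"]
    if isinstance(te_mu, dict):
        te_mu = {int(k): float(v) for k, v in te_mu.items()}
    return CurveConfig(
        wmax=wmax,
        te_mu=te_mu,
        te_sigma_g=float(entry.get("te_sigma_g", 0.0)),
        tm_frac=float(entry.get("tm_frac", 0.45)),
        wmax_mult_weight=float(entry.get("wmax_mult_weight", 1.0)),
        shift_weight=float(entry.get("shift_weight", 1.0)),
    )


def _treatment_effect(entry: dict) -> TreatmentEffect:
    return TreatmentEffect(
        wmax_mult=float(entry.get("wmax_mult", 1.0)),
        tm_shift=float(entry.get("tm_shift", 0.0)),
        te_shift=float(entry.get("te_shift", 0.0)),
        senescence_accel=float(entry.get("senescence_accel", 1.0)),
        senescence_onset_shift=float(entry.get("senescence_onset_shift", 0.0)),
        stress=float(entry.get("stress", 0.1)),
        trait_mult={k: float(v) for k, v in entry.get("trait_mult", {}).items()},
    )


@dataclass
class SimulationOutput:
    """All frames produced by one simulated multi-year trial."""

    design: pd.DataFrame
    weather: pd.DataFrame
    env: pd.DataFrame
    series: pd.DataFrame
    thermal: pd.DataFrame
    manual: pd.DataFrame
    truth_varcomps: pd.DataFrame
    truth_effects: pd.DataFrame
    flights_gdd: dict = field(default_factory=dict)

    FILES = {
        "design": "design.csv",
        "weather": "weather.csv",
        "env": "env.csv",
        "series": "series.csv",
        "thermal": "thermal.csv",
        "manual": "manual_traits.csv",
        "truth_varcomps": "truth_varcomps.csv",
        "truth_effects": "truth.csv",
    }

    def write(self, outdir) -> list[str]:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for attr, fname in self.FILES.items():
            frame = getattr(self, attr)
            frame.to_csv(outdir / fname, index=False, float_format="%.6g")
            written.append(fname)
        return written


class TrialSimulator:
    """Seeded end-to-end generator for the synthetic drought trial.

    Child seeds for every stochastic component are spawned from the master
    seed through :class:`numpy.random.SeedSequence`, so one integer
    reproduces the complete dataset byte for byte.
    """

    def __init__(self, config: dict | None = None, seed: int | None = None):
        self.config = merge_config(config)
        validate_config(self.config)
        if seed is not None:
            self.config["seed"] = int(seed)
        self.seed = int(self.config["seed"])

    # deterministic per-purpose child seeds
    def _child_seed(self, *tags) -> int:
        h = 2166136261
        for tag in (self.seed,) + tags:
            for ch in str(tag).encode():
                h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
        return h % (2**31 - 1)

    def sowing_dates(self, year: str) -> dict[int, _dt.date]:
        start = _dt.date(int(year), 4, 1)
        return {
            int(gp): start + _dt.timedelta(days=int(d))
            for gp, d in self.config["sowing_days"].items()
        }

    def _flight_gdd(self, env: pd.DataFrame, year: str) -> dict[int, np.ndarray]:
        start = _dt.date(int(year), 4, 1)
        days = [start + _dt.timedelta(days=int(d)) for d in self.config["flight_days"]]
        env_idx = env.set_index("date")
        out = {}
        for gp in (1, 2, 3, 4):
            g = env_idx.loc[env_idx.index.isin(days), f"gdd_cum_gp{gp}"].to_numpy(float)
            g = g[g > 1.0]
            out[gp] = np.unique(g)
        return out

    def simulate_year(self, year: str) -> SimulationOutput:
        cfg = self.config
        ycfg = cfg["years"][year]
        start = _dt.date(int(year), 4, 1)
        sowing = self.sowing_dates(year)
        wx = _weather.simulate_weather(
            ycfg["archetype"], start, int(cfg["weather"]["n_days"]), self._child_seed(year, "wx")
        )
        env = envmet.build_env_table(
            wx,
            sowing,
            latitude=cfg["weather"]["latitude"],
            elevation=cfg["weather"]["elevation"],
            tbase=cfg["thermal_time"]["tbase"],
            tcap=cfg["thermal_time"]["tcap"],
        )
        flights = self._flight_gdd(env, year)

        dsg = cfg["design"]
        designs = {
            trt: build_design(
                n_unreplicated=int(dsg["n_unreplicated"]),
                check_classes=tuple((int(n), int(r)) for n, r in dsg["check_classes"]),
                grid=tuple(int(v) for v in dsg["grid"]),
                n_blocks=int(dsg["n_blocks"]),
                seed=self._child_seed(year, trt, "design"),
                year_label=year,
                treatment=trt,
                sowing_dates=sowing,
            )
            for trt in ("control", "drought")
        }

        curve_cfg = {k: _curve_config(v) for k, v in cfg["curves"].items()}
        manual_cfg = {k: _effect_config(v) for k, v in cfg["manual_traits"].items()}
        effects = {
            "control": _treatment_effect(cfg["treatment_effects"]["control"]),
            "drought": _treatment_effect(cfg["treatment_effects"][ycfg["treatment_effect"]]),
        }
        noise = NoiseConfig(**{k: float(v) for k, v in cfg["noise"].items()})
        sen = cfg["senescence"]

        series_parts, manual_parts, thermal_parts, design_parts = [], [], [], []
        vc_rows, eff_rows = [], []
        curve_truth = None
        manual_truth_effects = None
        for trt in ("control", "drought"):
            design = designs[trt]
            params, ctruth = simulate_curve_params(
                design,
                curve_cfg,
                self._child_seed(year, trt, "curves"),
                genotype_effects=curve_truth,
                treatment=effects[trt],
            )
            if curve_truth is None:
                curve_truth = ctruth  # reuse genotype effects in the paired field
            manual, mtruth = simulate_effects(
                design,
                manual_cfg,
                self._child_seed(year, trt, "manual"),
                genotype_effects=manual_truth_effects,
                treatment=effects[trt],
            )
            if manual_truth_effects is None:
                manual_truth_effects = mtruth["genotype_effects"]
            if trt == "drought":
                score_cfgs = {}
                for trait, entry in cfg["score_traits"].items():
                    for day, mu in zip(entry["days"], entry["mu"]):
                        score_cfgs[f"{trait}_DAT{int(day):02d}"] = _effect_config(
                            {"mu": mu, "sigma2": entry["sigma2"]}
                        )
                scores, _ = simulate_effects(
                    design, score_cfgs, self._child_seed(year, trt, "scores")
                )
                manual = manual.join(scores)
            emergence = simulate_emergence(
                design,
                float(cfg["emergence"]["failure_rate"]),
                self._child_seed(year, trt, "emerge"),
            )
            design.frame["emergence_pct"] = design.frame["plot_id"].map(emergence).to_numpy()

            series = simulate_plot_series(
                design,
                params,
                flights,
                self._child_seed(year, trt, "series"),
                noise=noise,
                responses=("height", "cover", "r_stage"),
                senescence_onset=float(sen["onset_gdd"]),
                senescence_rate=float(sen["rate_per_gdd"]),
                treatment=effects[trt],
            )
            # thermal flights: air temperature = day's tmax (midday mean proxy)
            wx_idx = wx.set_index("date")
            air = {}
            for d in cfg["thermal_flight_days"]:
                day = start + _dt.timedelta(days=int(d))
                if day in wx_idx.index:
                    dat = int(d) - int(cfg["drought_start_day"])
                    air[f"DAT{dat:02d}"] = float(wx_idx.at[day, "tmax"]) - 2.0
            thermal = simulate_canopy_temperature(
                design,
                air,
                self._child_seed(year, trt, "thermal"),
                treatment=effects[trt],
                dt_ll=float(cfg["cwsi"]["dt_ll"]),
                dt_ul=float(cfg["cwsi"]["dt_ul"]),
                noise=noise,
            )

            for frame, store in ((series, series_parts), (thermal, thermal_parts)):
                frame.insert(0, "treatment", trt)
                frame.insert(0, "year", year)
                store.append(frame)
            manual = manual.reset_index()
            manual.insert(0, "treatment", trt)
            manual.insert(0, "year", year)
            manual_parts.append(manual)
            dframe = design.frame.copy()
            dframe.insert(0, "treatment", trt)
            dframe.insert(0, "year", year)
            design_parts.append(dframe)

            for trait, comps in mtruth["varcomps"].items():
                for term, v in comps.items():
                    vc_rows.append(
                        {"year": year, "treatment": trt, "trait": trait, "term": term, "sigma2": v}
                    )
        for resp, eff in curve_truth.items():
            for par, series_ in eff.items():
                for gid, val in series_.items():
                    eff_rows.append(
                        {"year": year, "kind": f"curve:{resp}:{par}", "genotype_id": gid, "value": val}
                    )
        for trait, series_ in manual_truth_effects.items():
            for gid, val in series_.items():
                eff_rows.append(
                    {"year": year, "kind": f"trait:{trait}", "genotype_id": gid, "value": val}
                )

        wx = wx.copy()
        wx.insert(0, "year", year)
        env = env.copy()
        env.insert(0, "year", year)
        return SimulationOutput(
            design=pd.concat(design_parts, ignore_index=True),
            weather=wx,
            env=env,
            series=pd.concat(series_parts, ignore_index=True),
            thermal=pd.concat(thermal_parts, ignore_index=True),
            manual=pd.concat(manual_parts, ignore_index=True),
            truth_varcomps=pd.DataFrame(vc_rows),
            truth_effects=pd.DataFrame(eff_rows),
            flights_gdd={year: flights},
        )

    def run(self) -> SimulationOutput:
        """Simulate every configured year and concatenate the outputs."""
        outs = [self.simulate_year(y) for y in self.config["years"]]
        flights = {}
        for o in outs:
            flights.update(o.flights_gdd)
        return SimulationOutput(
            design=pd.concat([o.design for o in outs], ignore_index=True),
            weather=pd.concat([o.weather for o in outs], ignore_index=True),
            env=pd.concat([o.env for o in outs], ignore_index=True),
            series=pd.concat([o.series for o in outs], ignore_index=True),
            thermal=pd.concat([o.thermal for o in outs], ignore_index=True),
            manual=pd.concat([o.manual for o in outs], ignore_index=True),
            truth_varcomps=pd.concat([o.truth_varcomps for o in outs], ignore_index=True),
            truth_effects=pd.concat([o.truth_effects for o in outs], ignore_index=True),
            flights_gdd=flights,
        )
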