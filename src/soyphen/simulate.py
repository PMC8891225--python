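"""Generative twins of the analysis models: plot effects, emergence, series.

Every simulated quantity mirrors the model that will later be fitted to it.
Plot-level trait values follow the additive random-effects decomposition
``value = GP mean + genotype + block + row + column + residual`` (the same
structure the REML engine assumes); plot time series are sampled from the
beta growth family the curve fitter uses; canopy temperature follows the
linear stress model the CWSI inverts.  Ground truth (genotype effects,
variance components, curve parameters, stress levels) is returned alongside
the data so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import TrialDesign
from .growth import beta_curve

__all__ = [
    "EffectConfig",
    "CurveConfig",
    "TreatmentEffect",
    "NoiseConfig",
    "simulate_effects",
    "simulate_emergence",
    "simulate_curve_params",
    "simulate_plot_series",
    "simulate_canopy_temperature",
]


@dataclass(frozen=True)
class EffectConfig:
    """Variance-component configuration for one plot-level trait.

    ``mu`` is either a scalar or a per-growth-group mapping; the sigma2
    fields are the variances of the centered Gaussian genotype, block, row,
    column and residual effects.
    """

    mu: float | dict[int, float]
    sigma2_g: float = 1.0
    sigma2_block: float = 0.0
    sigma2_row: float = 0.0
    sigma2_col: float = 0.0
    sigma2_e: float = 1.0

    def __post_init__(self):
        for name in ("sigma2_g", "sigma2_block", "sigma2_row", "sigma2_col", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def mean_for(self, growth_group) -> np.ndarray:
        gg = np.asarray(growth_group)
        if isinstance(self.mu, dict):
            return np.vectorize(lambda g: self.mu[int(g)])(gg).astype(float)
        return np.full(gg.shape, float(self.mu))

    @property
    def implied_h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else np.nan


@dataclass(frozen=True)
class CurveConfig:
    """Beta-curve parameter distribution for one plot response.

    ``wmax`` carries the full variance-component structure; ``te`` gets a
    per-GP mean plus a genotype effect (phenology differences between
    accessions) and ``tm`` is a fixed fraction of ``te``.
    """

    wmax: EffectConfig
    te_mu: dict[int, float] | float
    te_sigma_g: float = 0.0
    tm_frac: float = 0.45
    #: fraction of a drought treatment's wmax reduction this response feels
    #: (1 for height, partial for cover, 0 for the R-stage score whose
    #: asymptote is a developmental scale, not a growth amplitude)
    wmax_mult_weight: float = 1.0
    #: fraction of the treatment's tm/te shifts applied to this response
    shift_weight: float = 1.0

    def te_mean_for(self, growth_group) -> np.ndarray:
        gg = np.asarray(growth_group)
        if isinstance(self.te_mu, dict):
            return np.vectorize(lambda g: self.te_mu[int(g)])(gg).astype(float)
        return np.full(gg.shape, float(self.te_mu))


@dataclass(frozen=True)
class TreatmentEffect:
    """How a drought field modifies the generative parameters.

    ``wmax_mult`` scales the genotype-level asymptote (a 0.71 multiplier
    reproduces a 29% height reduction), ``tm_shift``/``te_shift`` move the
    curve timing (GDD), ``senescence_accel`` multiplies the post-peak cover
    decline rate, ``senescence_onset_shift`` advances its onset, ``stress``
    is the mean CWSI-scale stress of drought plots, and ``trait_mult`` holds
    per-trait multipliers for the plot-level manual traits.
    """

    wmax_mult: float = 1.0
    tm_shift: float = 0.0
    te_shift: float = 0.0
    senescence_accel: float = 1.0
    senescence_onset_shift: float = 0.0
    stress: float = 0.1
    trait_mult: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.wmax_mult <= 0:
            raise ValueError("wmax_mult must be positive")


CONTROL_EFFECT = TreatmentEffect(stress=0.06)


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement noise standard deviations for the simulated series."""

    height: float = 1.5  # cm
    cover: float = 0.015  # fraction
    rstage: float = 0.15  # stage units
    canopy_temp: float = 0.25  # degC
    stress_spread: float = 0.05  # plot-to-plot half-width of stress levels


def draw_genotype_effects(genotypes, sigma2: float, rng) -> pd.Series:
    """Centered Gaussian genotype effects keyed by genotype id."""
    if sigma2 < 0:
        raise ValueError("variance must be non-negative")
    g = rng.normal(0.0, np.sqrt(sigma2), len(genotypes)) if sigma2 > 0 else np.zeros(len(genotypes))
    return pd.Series(g, index=pd.Index(genotypes, name="genotype_id"))


def _level_effects(levels, sigma2, rng) -> pd.Series:
    vals = rng.normal(0.0, np.sqrt(sigma2), len(levels)) if sigma2 > 0 else np.zeros(len(levels))
    return pd.Series(vals, index=pd.Index(levels))


def simulate_effects(
    design: TrialDesign,
    trait_config: dict[str, EffectConfig],
    seed: int,
    genotype_effects: dict[str, pd.Series] | None = None,
    treatment: TreatmentEffect = CONTROL_EFFECT,
) -> tuple[pd.DataFrame, dict]:
    """Sample plot-level trait values under the additive random-effects model.

    The treatment multiplier acts on the genotype-level value (GP mean plus
    genotype effect) so that the relative reduction is uniform across
    accessions; spatial and residual effects are field-specific and additive.

    Returns the plot x trait value table and a truth dictionary holding the
    genotype effects, the variance components and the implied heritability
    per trait.
    """
    rng = np.random.default_rng(seed)
    df = design.frame
    genotypes = sorted(df["genotype_id"].unique())
    values = pd.DataFrame({"plot_id": df["plot_id"]})
    truth: dict = {"genotype_effects": {}, "varcomps": {}, "implied_h2": {}}

    for trait, cfg in trait_config.items():
        if genotype_effects is not None and trait in genotype_effects:
            g = genotype_effects[trait]
        else:
            g = draw_genotype_effects(genotypes, cfg.sigma2_g, rng)
        b = _level_effects(sorted(df["block"].unique()), cfg.sigma2_block, rng)
        r = _level_effects(sorted(df["row"].unique()), cfg.sigma2_row, rng)
        c = _level_effects(sorted(df["column"].unique()), cfg.sigma2_col, rng)
        e = rng.normal(0.0, np.sqrt(cfg.sigma2_e), len(df)) if cfg.sigma2_e > 0 else 0.0
        mult = treatment.trait_mult.get(trait, 1.0)
        genetic = cfg.mean_for(df["growth_group"]) + df["genotype_id"].map(g).to_numpy()
        values[trait] = (
            mult * genetic
            + df["block"].map(b).to_numpy()
            + df["row"].map(r).to_numpy()
            + df["column"].map(c).to_numpy()
            + e
        )
        truth["genotype_effects"][trait] = g
        truth["varcomps"][trait] = {
            "genotype": cfg.sigma2_g,
            "block": cfg.sigma2_block,
            "row": cfg.sigma2_row,
            "column": cfg.sigma2_col,
            "residual": cfg.sigma2_e,
        }
        truth["implied_h2"][trait] = cfg.implied_h2
    return values.set_index("plot_id"), truth


def simulate_emergence(design: TrialDesign, failure_rate: float, seed: int) -> pd.Series:
    """Per-plot emergence percentage with a configurable failure fraction.

    Failed plots draw E uniformly below the 30% analysis threshold; the rest
    draw uniformly in [60, 100].
    """
    if not 0.0 <= failure_rate <= 1.0:
        raise ValueError("failure_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = design.n_plots
    failed = rng.random(n) < failure_rate
    e = np.where(failed, rng.uniform(5.0, 29.99, n), rng.uniform(60.0, 100.0, n))
    return pd.Series(np.round(e, 1), index=design.frame["plot_id"], name="emergence_pct")


def simulate_curve_params(
    design: TrialDesign,
    curve_config: dict[str, CurveConfig],
    seed: int,
    genotype_effects: dict[str, dict[str, pd.Series]] | None = None,
    treatment: TreatmentEffect = CONTROL_EFFECT,
) -> tuple[pd.DataFrame, dict]:
    """Per-plot true beta-curve parameters for each configured response.

    Returns a frame with columns ``{response}_wmax/_tm/_te`` indexed by
    plot_id, plus a truth dictionary with the genotype effects used (so a
    paired field can reuse them).
    """
    rng = np.random.default_rng(seed)
    df = design.frame
    genotypes = sorted(df["genotype_id"].unique())
    out = pd.DataFrame(index=pd.Index(df["plot_id"], name="plot_id"))
    truth: dict = {}
    for resp, cfg in curve_config.items():
        eff = (genotype_effects or {}).get(resp, {})
        g_w = eff.get("wmax", draw_genotype_effects(genotypes, cfg.wmax.sigma2_g, rng))
        g_te = eff.get("te", draw_genotype_effects(genotypes, cfg.te_sigma_g**2, rng))
        b = _level_effects(sorted(df["block"].unique()), cfg.wmax.sigma2_block, rng)
        r = _level_effects(sorted(df["row"].unique()), cfg.wmax.sigma2_row, rng)
        c = _level_effects(sorted(df["column"].unique()), cfg.wmax.sigma2_col, rng)
        e = (
            rng.normal(0.0, np.sqrt(cfg.wmax.sigma2_e), len(df))
            if cfg.wmax.sigma2_e > 0
            else np.zeros(len(df))
        )
        genetic = cfg.wmax.mean_for(df["growth_group"]) + df["genotype_id"].map(g_w).to_numpy()
        mult = 1.0 - cfg.wmax_mult_weight * (1.0 - treatment.wmax_mult)
        wmax = (
            mult * genetic
            + df["block"].map(b).to_numpy()
            + df["row"].map(r).to_numpy()
            + df["column"].map(c).to_numpy()
            + e
        )
        te = (
            cfg.te_mean_for(df["growth_group"])
            + df["genotype_id"].map(g_te).to_numpy()
            + cfg.shift_weight * treatment.te_shift
        )
        tm = cfg.tm_frac * te + cfg.shift_weight * treatment.tm_shift
        if np.any(te <= tm):
            raise ValueError(f"degenerate curve truth for '{resp}': te <= tm")
        out[f"{resp}_wmax"] = np.maximum(wmax, 1e-6)
        out[f"{resp}_tm"] = tm
        out[f"{resp}_te"] = te
        truth[resp] = {"wmax": g_w, "te": g_te}
    return out, truth


def simulate_plot_series(
    design: TrialDesign,
    params: pd.DataFrame,
    flight_times,
    seed: int,
    noise: NoiseConfig = NoiseConfig(),
    responses: tuple[str, ...] = ("height", "cover"),
    senescence_onset: float | None = None,
    senescence_rate: float = 0.0,
    treatment: TreatmentEffect = CONTROL_EFFECT,
) -> pd.DataFrame:
    """Sample UAV-like plot series from the true curves at the flight times.

    ``flight_times`` is either one GDD vector for all plots or a mapping
    ``growth_group -> GDD vector`` (staggered sowing gives each cohort its
    own thermal-time axis).  Cover senescence declines linearly after its
    onset; a drought treatment accelerates the rate and advances the onset.

    Returns a long frame: plot_id, thermal_time, variable, value.
    """
    rng = np.random.default_rng(seed)
    df = design.frame
    noise_sd = {"height": noise.height, "cover": noise.cover, "r_stage": noise.rstage}
    rows = []
    for rec in df.itertuples():
        times = np.asarray(
            flight_times[rec.growth_group] if isinstance(flight_times, dict) else flight_times,
            dtype=float,
        )
        for resp in responses:
            wmax = params.at[rec.plot_id, f"{resp}_wmax"]
            tm = params.at[rec.plot_id, f"{resp}_tm"]
            te = params.at[rec.plot_id, f"{resp}_te"]
            y = beta_curve(times, wmax, tm, te)
            if resp == "cover" and senescence_onset is not None:
                onset = senescence_onset + treatment.senescence_onset_shift
                rate = senescence_rate * treatment.senescence_accel
                y = y - np.maximum(times - onset, 0.0) * rate
            sd = noise_sd.get(resp, 0.0)
            if sd > 0:
                y = y + rng.normal(0.0, sd, len(times))
            if resp == "cover":
                y = np.clip(y, 0.0, 1.0)
            rows.append(
                pd.DataFrame(
                    {
                        "plot_id": rec.plot_id,
                        "thermal_time": times,
                        "variable": resp,
                        "value": y,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_canopy_temperature(
    design: TrialDesign,
    air_temps: dict,
    seed: int,
    treatment: TreatmentEffect = CONTROL_EFFECT,
    dt_ll: float = -4.0,
    dt_ul: float = 6.0,
    noise: NoiseConfig = NoiseConfig(),
) -> pd.DataFrame:
    """Thermal-flight canopy temperatures under the linear stress model.

    Each plot receives a stress level uniform in ``treatment.stress`` +/-
    ``noise.stress_spread`` (clipped to [0, 1]); canopy temperature is
    ``Ta + dT_ll + stress * (dT_ul - dT_ll) + noise``.  ``air_temps`` maps a
    flight label (e.g. a days-after-treatment tag) to the 10:00-14:00 mean
    air temperature of that flight.

    Returns a long frame with the true stress level per row, enabling exact
    CWSI inversion tests.
    """
    rng = np.random.default_rng(seed)
    df = design.frame
    n = len(df)
    stress = np.clip(
        rng.uniform(treatment.stress - noise.stress_spread, treatment.stress + noise.stress_spread, n),
        0.0,
        1.0,
    )
    rows = []
    for label, ta in air_temps.items():
        eps = rng.normal(0.0, noise.canopy_temp, n) if noise.canopy_temp > 0 else 0.0
        tc = ta + dt_ll + stress * (dt_ul - dt_ll) + eps
        rows.append(
            pd.DataFrame(
                {
                    "plot_id": df["plot_id"],
                    "flight": label,
                    "canopy_temp": tc,
                    "air_temp": ta,
                    "true_stress": stress,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
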