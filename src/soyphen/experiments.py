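"""Desk-scale validation experiments on the synthetic generator.

These are the package's own calibration checks, run by the test suite and
the acceptance script: heritability recovery under the generative mixed
model, drought-index calibration of the canopy-height reduction, and CWSI
inversion accuracy.  Each experiment regenerates its data from scratch for
a given seed, so results are reproducible from a single integer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import build_design
from .envmet import cwsi, estimate_baselines
from .growth import fit_beta_curve
from .mixedmodel import AugmentedTrialModel, ModelSpec
from .response import yr_table
from .simulate import (
    CurveConfig,
    EffectConfig,
    NoiseConfig,
    TreatmentEffect,
    simulate_canopy_temperature,
    simulate_curve_params,
    simulate_effects,
    simulate_plot_series,
)

__all__ = [
    "h2_recovery_experiment",
    "yr_ch_experiment",
    "cwsi_inversion_experiment",
]

BASE_MODEL = ModelSpec(("genotype", "block", "row", "column"))

#: canopy-height curve used by the drought-index calibration; GP means and
#: genetic variance follow the default scenario
_HEIGHT_CURVE = CurveConfig(
    wmax=EffectConfig(
        mu={1: 95.0, 2: 90.0, 3: 85.0, 4: 80.0},
        sigma2_g=36.0,
        sigma2_block=4.0,
        sigma2_row=1.0,
        sigma2_col=1.0,
        sigma2_e=4.0,
    ),
    te_mu={1: 900.0, 2: 860.0, 3: 820.0, 4: 780.0},
    te_sigma_g=25.0,
    tm_frac=0.45,
)


def h2_recovery_experiment(
    true_h2: float,
    seed: int,
    sigma2_e: float = 1.0,
    spatial: tuple[float, float, float] = (0.3, 0.15, 0.15),
) -> float:
    """Estimated broad-sense heritability for one simulated 454-plot field.

    The genotypic variance is set so that sigma2_g / (sigma2_g + sigma2_e)
    equals ``true_h2``; data are generated under the additive base model and
    refitted with the same structure.
    """
    if not 0.0 < true_h2 < 1.0:
        raise ValueError("true_h2 must lie strictly between 0 and 1")
    sigma2_g = true_h2 * sigma2_e / (1.0 - true_h2)
    design = build_design(seed=seed)
    cfg = {
        "Y": EffectConfig(
            mu=50.0,
            sigma2_g=sigma2_g,
            sigma2_block=spatial[0],
            sigma2_row=spatial[1],
            sigma2_col=spatial[2],
            sigma2_e=sigma2_e,
        )
    }
    values, _ = simulate_effects(design, cfg, seed=seed + 1)
    df = design.frame.merge(values, left_on="plot_id", right_index=True)
    fit = AugmentedTrialModel(df["Y"], df).fit(BASE_MODEL)
    return fit.h2


def yr_ch_experiment(
    seed: int,
    wmax_mult: float = 0.71,
    height_noise_sd: float = 0.5,
    n_flights: int = 14,
) -> float:
    """Mean drought index for canopy height in one simulated season.

    Control and drought fields (454 plots each, shared genotype effects) are
    simulated with the drought field's height asymptote scaled by
    ``wmax_mult``; the height series of every plot is refitted with the beta
    curve, CH (the fitted asymptote) is analysed per field with the base
    mixed model, and Yr(CH) is averaged over the genotypes common to both
    treatments.
    """
    treatments = {
        "control": TreatmentEffect(),
        "drought": TreatmentEffect(wmax_mult=wmax_mult, te_shift=-40.0),
    }
    noise = NoiseConfig(height=height_noise_sd)
    blups = {}
    genotype_effects = None
    for i, (trt, eff) in enumerate(treatments.items()):
        design = build_design(seed=seed * 4 + i, treatment=trt)
        params, truth = simulate_curve_params(
            design,
            {"height": _HEIGHT_CURVE},
            seed=seed * 4 + 2,
            genotype_effects=genotype_effects,
            treatment=eff,
        )
        genotype_effects = truth
        flights = {
            gp: np.linspace(120.0, 1.15 * _HEIGHT_CURVE.te_mu[gp], n_flights)
            for gp in (1, 2, 3, 4)
        }
        series = simulate_plot_series(
            design,
            params,
            flights,
            seed=seed * 4 + 3 + i,
            noise=noise,
            responses=("height",),
            treatment=eff,
        )
        ch = {}
        for plot_id, grp in series.groupby("plot_id", sort=False):
            fit = fit_beta_curve(grp["thermal_time"], grp["value"])
            if fit.converged:
                ch[plot_id] = fit.wmax
        df = design.frame
        y = df["plot_id"].map(ch)
        fit = AugmentedTrialModel(y.to_numpy(float), df).fit(BASE_MODEL)
        blups[trt] = fit.genotype_blups.to_frame(name="CH")
    yr = yr_table(blups["control"], blups["drought"])
    return float(yr["yr"].mean())


def cwsi_inversion_experiment(
    seed: int,
    noise_free: bool = True,
    dt_ll: float = -4.0,
    dt_ul: float = 6.0,
) -> dict[str, float]:
    """Recovery of the generator's stress levels through the CWSI.

    A paired control (low stress) / drought (high stress) field is simulated
    under the linear canopy-temperature model.  With the true baselines the
    index equals the stress level exactly in the noise-free case; with
    baselines estimated from the data (low quantile of well-watered plots,
    high quantile overall) a small bias remains.

    Returns the maximum absolute error under true baselines and the mean
    absolute error under estimated baselines.
    """
    noise = NoiseConfig(canopy_temp=0.0 if noise_free else 0.25, stress_spread=0.05)
    frames = []
    for i, (trt, stress) in enumerate((("control", 0.05), ("drought", 0.8))):
        design = build_design(seed=seed * 2 + i, treatment=trt)
        frame = simulate_canopy_temperature(
            design,
            {"DAT10": 28.0},
            seed=seed * 2 + i + 1,
            treatment=TreatmentEffect(stress=stress),
            dt_ll=dt_ll,
            dt_ul=dt_ul,
            noise=NoiseConfig(
                canopy_temp=noise.canopy_temp,
                stress_spread=0.05 if trt == "control" else 0.2,
            ),
        )
        frame["treatment"] = trt
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)

    true_idx = cwsi(data["canopy_temp"], data["air_temp"], dt_ll, dt_ul)
    err_true = np.max(np.abs(true_idx - data["true_stress"].to_numpy()))

    dt = pd.Series(
        data["canopy_temp"].to_numpy() - data["air_temp"].to_numpy(), index=data["plot_id"]
    )
    ww = data.loc[data["treatment"] == "control", "plot_id"]
    ll_hat, ul_hat = estimate_baselines(dt, ww)
    est_idx = cwsi(data["canopy_temp"], data["air_temp"], ll_hat, ul_hat)
    err_est = float(np.mean(np.abs(est_idx - data["true_stress"].to_numpy())))
    return {"max_error_true_baselines": float(err_true), "mae_estimated_baselines": err_est}
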