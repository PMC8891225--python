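"""Batch trait extraction: from plot time series to the trait table.

For every plot the canopy-height series is fitted with the beta growth
curve (CH = asymptote, AGRmax = closed-form maximum rate, te feeds DET),
the canopy-cover series gives CC75 (crossing of 0.75, fitted on the
pre-senescence part of the series) and SNC (raw-series senescence drop),
and the reproductive-stage scores give R1/R2/R5 from the fitted monotone
sigmoid.  Phase durations combine the fitted stages with the field-observed
R8.  Plots whose fits do not converge yield missing traits and are reported
in the curve-fit table rather than raising.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .growth import BetaGrowthResults, cc75, det, fit_beta_curve, fit_rstage_curve, snc

__all__ = ["extract_plot", "extract_traits"]


def _presenescence(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Truncate a cover series just past its running maximum.

    The beta family is monotone, so late senescent observations would bias
    the asymptote; one point beyond the max is kept to anchor the plateau.
    """
    imax = int(np.argmax(y))
    stop = min(imax + 2, len(y))
    return t[:stop], y[:stop]


def extract_plot(series: pd.DataFrame, r8: float = np.nan, k_tail: int = 2) -> tuple[dict, list[dict]]:
    """Derive all curve traits for one plot.

    ``series`` is the long frame for a single plot (thermal_time, variable,
    value).  Returns the trait dict and per-response curve-fit records.
    """
    traits: dict = {}
    fits: list[dict] = []
    by_var = {v: g.sort_values("thermal_time") for v, g in series.groupby("variable")}

    def _record(resp: str, fit: BetaGrowthResults | None):
        if fit is None:
            return
        fits.append(
            {
                "response": resp,
                "wmax": fit.wmax,
                "tm": fit.tm,
                "te": fit.te,
                "rss": fit.rss,
                "n_points": fit.n_points,
                "converged": fit.converged,
            }
        )

    height_fit = None
    if "height" in by_var:
        g = by_var["height"]
        try:
            height_fit = fit_beta_curve(g["thermal_time"], g["value"])
        except ValueError:
            height_fit = None
        _record("height", height_fit)
        if height_fit is not None and height_fit.converged:
            traits["CH"] = height_fit.wmax
            traits["AGRmax"] = height_fit.agrmax

    if "cover" in by_var:
        g = by_var["cover"]
        t = g["thermal_time"].to_numpy(float)
        y = g["value"].to_numpy(float)
        traits["SNC"] = snc(y, k_tail=k_tail)
        tt, yy = _presenescence(t, y)
        cover_fit = None
        if len(tt) >= 4:
            try:
                cover_fit = fit_beta_curve(tt, yy, wmax_bound=1.2)
            except ValueError:
                cover_fit = None
        _record("cover", cover_fit)
        if cover_fit is not None and cover_fit.converged:
            traits["CC75"] = cc75(cover_fit)

    r1 = np.nan
    if "r_stage" in by_var:
        g = by_var["r_stage"]
        rfit, crossings = fit_rstage_curve(g["thermal_time"], g["value"])
        _record("r_stage", rfit)
        traits["R2"], traits["R5"] = crossings["R2"], crossings["R5"]
        r1 = crossings["R1"]

    traits["R8"] = r8
    traits["R2R5"] = traits.get("R5", np.nan) - traits.get("R2", np.nan)
    traits["R5R8"] = r8 - traits.get("R5", np.nan)
    traits["R2R8"] = r8 - traits.get("R2", np.nan)
    traits["DET"] = det(height_fit, r1)
    return traits, fits


def extract_traits(
    series: pd.DataFrame,
    manual: pd.DataFrame | None = None,
    k_tail: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract curve traits for every plot of a long series table.

    ``manual`` (optional, indexed or keyed by plot_id) contributes the
    field-observed traits; its R8 column is used for the phase durations.
    Returns (traits table, curve-fit table), one row per plot / per
    plot x response respectively.
    """
    meta_cols = [c for c in ("year", "treatment") if c in series.columns]
    manual_idx = None
    if manual is not None:
        manual_idx = manual.set_index("plot_id") if "plot_id" in manual.columns else manual
    trait_rows, fit_rows = [], []
    for plot_id, g in series.groupby("plot_id", sort=False):
        r8 = np.nan
        if manual_idx is not None and plot_id in manual_idx.index and "R8" in manual_idx.columns:
            r8 = float(manual_idx.at[plot_id, "R8"])
        traits, fits = extract_plot(g, r8=r8, k_tail=k_tail)
        meta = {c: g[c].iloc[0] for c in meta_cols}
        trait_rows.append({**meta, "plot_id": plot_id, **traits})
        for f in fits:
            fit_rows.append({**meta, "plot_id": plot_id, **f})
    traits_df = pd.DataFrame(trait_rows)
    fits_df = pd.DataFrame(fit_rows)
    if manual_idx is not None:
        extra = manual_idx.drop(columns=[c for c in ("year", "treatment", "R8") if c in manual_idx.columns])
        traits_df = traits_df.merge(extra, left_on="plot_id", right_index=True, how="left")
    return traits_df, fits_df
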