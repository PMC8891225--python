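"""Beta-sigmoid growth curves and the plot-level traits derived from them.

The determinate growth of a soybean canopy on a thermal-time axis is well
described by the beta growth function

    w(t) = wmax * (1 + (te - t) / (te - tm)) * (t / te) ** (te / (te - tm))

for 0 <= t <= te and w(t) = wmax beyond te, where ``wmax`` is the asymptote,
``tm`` the thermal time of maximum growth rate and ``te`` the thermal time at
which the asymptote is reached (0 < tm < te).  The maximum rate itself has
the closed form

    AGRmax = wmax * (2*te - tm) / (te * (te - tm)) * (tm / te) ** (tm / (te - tm))

The same single family is used for canopy height, canopy cover and the
reproductive-stage score (asymptote free), which keeps the trait definitions
uniform: CH is the height asymptote, CC75 the time the cover curve crosses
0.75, R1/R2/R5 the times the R-stage curve crosses 1/2/5, DET the lag from
start of flowering (R1) to the end of height growth (te), and SNC the drop
from maximum cover to the end-of-season low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "beta_curve",
    "beta_curve_derivative",
    "agrmax_closed_form",
    "BetaGrowthModel",
    "BetaGrowthResults",
    "fit_beta_curve",
    "cc75",
    "time_to_level",
    "fit_rstage_curve",
    "durations",
    "det",
    "snc",
]


def beta_curve(t, wmax: float, tm: float, te: float):
    """Evaluate the beta growth function; constant at ``wmax`` beyond ``te``."""
    t = np.asarray(t, dtype=float)
    if not 0 < tm < te:
        raise ValueError(f"require 0 < tm < te, got tm={tm}, te={te}")
    tt = np.clip(t, 0.0, te)
    with np.errstate(invalid="ignore"):
        w = wmax * (1.0 + (te - tt) / (te - tm)) * (tt / te) ** (te / (te - tm))
    w = np.where(t >= te, wmax, w)
    w = np.where(t <= 0.0, 0.0, w)
    return float(w) if w.ndim == 0 else w


def beta_curve_derivative(t, wmax: float, tm: float, te: float):
    """dw/dt of the beta growth function (0 outside (0, te))."""
    t = np.asarray(t, dtype=float)
    if not 0 < tm < te:
        raise ValueError(f"require 0 < tm < te, got tm={tm}, te={te}")
    p = te / (te - tm)
    inside = (t > 0) & (t < te)
    tt = np.where(inside, t, tm)  # dummy value avoids 0**neg warnings
    d = wmax * p * (tt / te) ** (p - 1.0) / te * (1.0 + (te - tt) / (te - tm)) - wmax * (
        tt / te
    ) ** p / (te - tm)
    d = np.where(inside, d, 0.0)
    return float(d) if d.ndim == 0 else d


def agrmax_closed_form(wmax: float, tm: float, te: float) -> float:
    """Maximum growth rate, attained at t = tm (per unit thermal time)."""
    if not te > tm > 0:
        raise ValueError(f"require te > tm > 0, got tm={tm}, te={te}")
    return wmax * (2.0 * te - tm) / (te * (te - tm)) * (tm / te) ** (tm / (te - tm))


@dataclass
class BetaGrowthResults:
    """Fitted beta growth curve for one plot response.

    ``agrmax`` is reported per 100 GDD (the conventional unit for canopy
    height growth rate, cm GDD^-100).
    """

    wmax: float
    tm: float
    te: float
    rss: float
    n_points: int
    converged: bool
    model: "BetaGrowthModel | None" = field(default=None, repr=False)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.wmax, self.tm, self.te])

    @property
    def agrmax(self) -> float:
        """Maximum absolute growth rate scaled to per-100-GDD units."""
        return 100.0 * agrmax_closed_form(self.wmax, self.tm, self.te)

    def predict(self, t):
        return beta_curve(t, self.wmax, self.tm, self.te)

    def time_to(self, level: float) -> float:
        """Smallest t with w(t) == level, NaN when the asymptote stays below it."""
        return time_to_level(self, level)

    def summary(self) -> str:
        lines = [
            "Beta growth curve fit",
            "---------------------",
            f"converged : {self.converged}",
            f"n points  : {self.n_points}",
            f"wmax      : {self.wmax:.4f}",
            f"tm (GDD)  : {self.tm:.2f}",
            f"te (GDD)  : {self.te:.2f}",
            f"AGRmax    : {self.agrmax:.4f} per 100 GDD" if self.converged else "AGRmax    : --",
            f"RSS       : {self.rss:.6g}",
        ]
        return "\n".join(lines)


class BetaGrowthModel:
    """Least-squares beta growth curve for one (thermal_time, response) series.

    ``fit`` runs a bounded trust-region least-squares from at least three
    starting points (tm at 0.3/0.5/0.7 of the observed time range, te at 1.2x
    the last observation, wmax at the observed maximum) and keeps the lowest
    residual sum of squares.  A fit that fails on every start, or a response
    with no signal, is returned with ``converged=False``; downstream trait
    extraction treats it as a missing trait rather than an error.
    """

    def __init__(self, thermal_time, response, wmax_bound: float | None = None):
        t = np.asarray(thermal_time, dtype=float)
        y = np.asarray(response, dtype=float)
        ok = np.isfinite(t) & np.isfinite(y)
        self.t, self.y = t[ok], y[ok]
        if len(self.t) < 4:
            raise ValueError("need at least 4 observations to fit a growth curve")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("thermal_time must be strictly increasing")
        self.wmax_bound = wmax_bound

    def _residuals(self, params):
        wmax, tm, dte = params
        return beta_curve(self.t, wmax, tm, tm + dte) - self.y

    def _jacobian(self, params):
        """Analytic d(residual)/d(wmax, tm, dte); piecewise-zero off (0, te)."""
        wmax, tm, dte = params
        te = tm + dte
        t = self.t
        inside = (t > 0) & (t < te)
        tt = np.where(inside, t, tm)
        u = dte
        x = tt / te
        a = 1.0 + (te - tt) / u
        w = wmax * a * x ** (te / u)
        lx = np.log(x)
        dw_dte = w * ((tt - tm) / (u * u * a) - tm * lx / (u * u) - 1.0 / u)
        dw_dtm = w * ((te - tt) / (u * u * a) + te * lx / (u * u))
        jac = np.zeros((len(t), 3))
        jac[:, 0] = np.where(inside, w / wmax, np.where(t >= te, 1.0, 0.0))
        jac[:, 1] = np.where(inside, dw_dtm + dw_dte, 0.0)
        jac[:, 2] = np.where(inside, dw_dte, 0.0)
        return jac

    def fit(self, n_starts: int = 3) -> BetaGrowthResults:
        ymax = float(np.max(self.y))
        span = float(self.t[-1] - self.t[0])
        if ymax <= 0 or float(np.std(self.y)) == 0.0 or span <= 0:
            return BetaGrowthResults(np.nan, np.nan, np.nan, np.nan, len(self.t), False, self)

        ub_w = self.wmax_bound if self.wmax_bound is not None else 5.0 * ymax
        lo = np.array([1e-8, 1.0, 1.0])
        hi = np.array([ub_w, 3.0 * self.t[-1], 3.0 * self.t[-1]])
        te0 = 1.2 * self.t[-1]
        fracs = np.linspace(0.3, 0.7, max(n_starts, 3))
        best = None
        for f in fracs:
            tm0 = self.t[0] + f * span
            x0 = np.clip(np.array([ymax, tm0, max(te0 - tm0, 10.0)]), lo, hi)
            try:
                sol = optimize.least_squares(
                    self._residuals,
                    x0,
                    jac=self._jacobian,
                    bounds=(lo, hi),
                    method="trf",
                    xtol=1e-10,
                    ftol=1e-10,
                )
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            if np.isfinite(rss) and (best is None or rss < best[0]):
                best = (rss, sol.x)
        if best is None:
            return BetaGrowthResults(np.nan, np.nan, np.nan, np.nan, len(self.t), False, self)
        rss, (wmax, tm, dte) = best
        return BetaGrowthResults(
            float(wmax), float(tm), float(tm + dte), rss, len(self.t), True, self
        )


def fit_beta_curve(thermal_time, response, wmax_bound: float | None = None) -> BetaGrowthResults:
    """Functional wrapper around :class:`BetaGrowthModel`."""
    return BetaGrowthModel(thermal_time, response, wmax_bound=wmax_bound).fit()


def time_to_level(fit: BetaGrowthResults, level: float) -> float:
    """Smallest thermal time at which the fitted curve reaches ``level``.

    Found by bracketed root solving on [0, te]; the beta curve is strictly
    increasing there so the crossing is unique.  Returns NaN when the
    asymptote never reaches the level (flagged-missing semantics).
    """
    if not fit.converged or not np.isfinite(fit.wmax):
        return np.nan
    if fit.wmax < level:
        return np.nan
    if level <= 0:
        return 0.0
    f = lambda t: beta_curve(t, fit.wmax, fit.tm, fit.te) - level
    hi = fit.te
    if f(hi) < 0:  # level == wmax within rounding
        return hi
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-8))


def cc75(cover_fit: BetaGrowthResults, level: float = 0.75) -> float:
    """Thermal time to 75% canopy cover; NaN if cover never reaches it."""
    return time_to_level(cover_fit, level)


def fit_rstage_curve(thermal_time, r_scores):
    """Fit the reproductive-stage progression and extract R1/R2/R5.

    Scores are restricted to the observable window [1, 6] (the early part of
    the double-sigmoid development pattern) before fitting the same beta
    family with a free asymptote.  Crossings of 1, 2 and 5 give the thermal
    times to start of flowering (R1), full flowering (R2) and beginning of
    seed fill (R5); a crossing whose level exceeds the fitted asymptote is
    missing.

    Returns
    -------
    (BetaGrowthResults, dict with keys 'R1', 'R2', 'R5')
    """
    t = np.asarray(thermal_time, dtype=float)
    y = np.asarray(r_scores, dtype=float)
    ok = np.isfinite(y) & (y >= 1.0) & (y <= 6.0)
    crossings = {"R1": np.nan, "R2": np.nan, "R5": np.nan}
    if ok.sum() < 4 or float(np.std(y[ok])) == 0.0:
        res = BetaGrowthResults(np.nan, np.nan, np.nan, np.nan, int(ok.sum()), False)
        return res, crossings
    res = BetaGrowthModel(t[ok], y[ok], wmax_bound=10.0).fit()
    if res.converged:
        for name, level in (("R1", 1.0), ("R2", 2.0), ("R5", 5.0)):
            crossings[name] = time_to_level(res, level)
    return res, crossings


def durations(r2: float, r5: float, r8: float) -> tuple[float, float, float]:
    """(R2R5, R5R8, R2R8) phase durations in GDD; missing inputs propagate."""
    r2r5 = r5 - r2
    r5r8 = r8 - r5
    r2r8 = r8 - r2
    return r2r5, r5r8, r2r8


def det(height_fit: BetaGrowthResults, r1: float) -> float:
    """Degree of indeterminacy: thermal time of continued height growth
    after start of flowering, ``te(height) - R1``.

    Left unclamped: strongly determinate plots can go (slightly) negative.
    """
    if height_fit is None or not height_fit.converged or not np.isfinite(r1):
        return np.nan
    return float(height_fit.te - r1)


def snc(cover, k_tail: int = 2) -> float:
    """Rate of senescence from a canopy-cover series, on [0, 1].

    A 3-point running median smooths the series; SNC is the smoothed maximum
    minus the mean of the ``k_tail`` lowest smoothed values observed after
    the maximum, clamped to [0, 1].  Missing when fewer than ``k_tail``
    observations follow the maximum.
    """
    y = np.asarray(cover, dtype=float)
    y = y[np.isfinite(y)]
    if len(y) < 3:
        return np.nan
    sm = np.copy(y)
    sm[1:-1] = np.median(np.column_stack([y[:-2], y[1:-1], y[2:]]), axis=1)
    imax = int(np.argmax(sm))
    tail = sm[imax + 1 :]
    if len(tail) < k_tail:
        return np.nan
    low = np.sort(tail)[:k_tail]
    return float(np.clip(sm[imax] - low.mean(), 0.0, 1.0))
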