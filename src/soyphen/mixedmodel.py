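"""REML variance components, BLUPs and heritability for augmented trials.

The analysis model is an intercept-only linear mixed model

    y = mu + genotype + (spatial terms) + e

in which every term is a random intercept: the genotype effect of the
accession and a subset of block, row, column effects describing spatial
field trends.  Because columns (and rows) are physically nested in blocks,
six candidate random structures spanning the plausible nesting lattice are
fitted per trait and the one with the lowest AIC is retained.

Variance components are estimated by restricted maximum likelihood with a
log parameterization (hence non-negative by construction; a component can
converge to the zero boundary), using the analytic REML gradient.  Genotype
BLUPs are the mixed-model-equation predictions, reported as intercept +
predicted effect.  Broad-sense heritability is

    H2 = Var(genotype) / (Var(genotype) + Var(residual))

classed as low (< 0.30), medium (0.30-0.60) or high (> 0.60).

AIC is computed as ``-2 * loglik_REML + 2 * k`` with ``k`` = number of
variance components (including the residual) + 1 for the intercept; the
fixed part is identical across candidates so REML likelihoods are
comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "ModelSpec",
    "candidate_models",
    "AugmentedTrialModel",
    "TrialFitResults",
    "select_model",
    "heritability",
    "h2_class",
    "summarize_blups",
    "filter_emergence",
    "tukey_clean",
    "maybe_transform",
]

SPATIAL_FACTORS = ("block", "row", "column", "row_in_block", "column_in_block")
_NESTED_OF = {"row_in_block": "row", "column_in_block": "column"}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate random-effects structure.

    ``random_terms`` always contains 'genotype'; crossed and nested versions
    of the same factor (e.g. 'column' and 'column_in_block') cannot co-occur.
    """

    random_terms: tuple[str, ...]
    transform: str = "none"
    label: str = ""

    def __post_init__(self):
        terms = self.random_terms
        if "genotype" not in terms:
            raise ValueError("the genotype term is always included")
        if len(set(terms)) != len(terms):
            raise ValueError("duplicated random term")
        for nested, crossed in _NESTED_OF.items():
            if nested in terms and crossed in terms:
                raise ValueError(f"'{crossed}' and '{nested}' cannot co-occur")
        if not self.label:
            object.__setattr__(self, "label", "+".join(terms))


def candidate_models(transform: str = "none") -> list[ModelSpec]:
    """The six random structures evaluated per trait (all include genotype)."""
    structures = [
        ("genotype", "block"),
        ("genotype", "block", "row"),
        ("genotype", "block", "column_in_block"),
        ("genotype", "block", "row", "column_in_block"),
        ("genotype", "row", "column"),
        ("genotype", "block", "row_in_block", "column_in_block"),
    ]
    return [ModelSpec(s, transform=transform) for s in structures]


def _factor_codes(design: pd.DataFrame) -> dict[str, pd.Series]:
    f = {
        "genotype": design["genotype_id"].astype(str),
        "block": design["block"].astype(str),
        "row": design["row"].astype(str),
        "column": design["column"].astype(str),
        "row_in_block": design["block"].astype(str) + ":" + design["row"].astype(str),
        "column_in_block": design["block"].astype(str) + ":" + design["column"].astype(str),
    }
    return f


@dataclass
class TrialFitResults:
    """REML fit of one trait: variance components, BLUPs, H2, AIC."""

    spec: ModelSpec
    varcomps: dict[str, float]
    loglik_reml: float
    aic: float
    n_params: int
    intercept: float
    genotype_blups: pd.Series  # intercept + predicted genotype effect
    converged: bool
    n_obs: int

    @property
    def h2(self) -> float:
        return heritability(self.varcomps)

    @property
    def h2_class(self) -> str:
        return h2_class(self.h2)

    @property
    def blup_deviations(self) -> pd.Series:
        return self.genotype_blups - self.intercept

    def summary(self) -> str:
        lines = [
            "Augmented trial mixed model (REML)",
            "==================================",
            f"model      : {self.spec.label}",
            f"transform  : {self.spec.transform}",
            f"n obs      : {self.n_obs}   genotypes: {len(self.genotype_blups)}",
            f"converged  : {self.converged}",
            f"loglik     : {self.loglik_reml:.4f}   AIC: {self.aic:.2f} (k={self.n_params})",
            f"intercept  : {self.intercept:.4f}",
            "variance components:",
        ]
        for term, v in self.varcomps.items():
            lines.append(f"  {term:<16s} {v:.6g}")
        h2 = self.h2
        lines.append(f"H2         : {h2:.3f} ({self.h2_class})" if np.isfinite(h2) else "H2         : --")
        return "\n".join(lines)


class AugmentedTrialModel:
    """Intercept-only mixed model for one trait of one field trial.

    Parameters
    ----------
    y : array-like
        Trait values, one per retained plot (no missing values).
    design : DataFrame
        Plot table with genotype_id, block, row, column columns aligned to y.
    """

    def __init__(self, y, design: pd.DataFrame):
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(y)
        self.y = y[ok]
        self.design = design.loc[ok].reset_index(drop=True)
        self.n = len(self.y)
        if self.n < 3:
            raise ValueError("too few observations")
        self._codes = _factor_codes(self.design)
        self._gram: dict[str, np.ndarray] = {}
        self._z: dict[str, tuple[np.ndarray, pd.Index]] = {}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str) -> "AugmentedTrialModel":
        sub = df[np.isfinite(df[response].to_numpy(float))]
        return cls(sub[response].to_numpy(float), sub)

    # -- design matrices --------------------------------------------------
    def _factor(self, term: str) -> tuple[np.ndarray, pd.Index]:
        if term not in self._z:
            codes, levels = pd.factorize(self._codes[term], sort=True)
            if len(levels) < 2:
                raise ValueError(f"factor '{term}' has fewer than 2 levels")
            z = np.zeros((self.n, len(levels)))
            z[np.arange(self.n), codes] = 1.0
            self._z[term] = (z, pd.Index(levels, name=term))
        return self._z[term]

    def _gram_matrix(self, term: str) -> np.ndarray:
        if term not in self._gram:
            z, _ = self._factor(term)
            self._gram[term] = z @ z.T
        return self._gram[term]

    # -- REML -------------------------------------------------------------
    def _loglik_and_grad(self, log_s2, grams, y):
        s2 = np.exp(log_s2)
        v = s2[-1] * np.eye(self.n)
        for k, g in enumerate(grams):
            v += s2[k] * g
        try:
            cf = linalg.cho_factor(v, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return np.inf, np.zeros_like(s2)
        logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
        vi = linalg.cho_solve(cf, np.eye(self.n), check_finite=False)
        vi1 = vi.sum(axis=1)
        s = vi1.sum()  # X'V^-1X with X = 1
        p = vi - np.outer(vi1, vi1) / s
        py = p @ y
        quad = float(y @ py)
        ll = -0.5 * ((self.n - 1) * np.log(2 * np.pi) + logdet_v + np.log(s) + quad)
        grad = np.empty_like(s2)
        for k, g in enumerate(grams):
            gpy = g @ py
            grad[k] = -0.5 * (np.sum(p * g) - py @ gpy) * s2[k]
        grad[-1] = -0.5 * (np.trace(p) - py @ py) * s2[-1]
        return -ll, -grad

    def fit(self, spec: ModelSpec) -> TrialFitResults:
        """Estimate variance components by REML and predict genotype BLUPs."""
        terms = list(spec.random_terms)
        grams = [self._gram_matrix(t) for t in terms]
        vy = float(np.var(self.y))
        if vy <= 0:
            raise ValueError("response has zero variance")
        ymean = float(np.mean(self.y))
        yc = self.y - ymean  # centering leaves REML invariant, improves precision
        k = len(terms) + 1  # + residual
        x0 = np.log(np.full(k, vy / k))
        bounds = [(np.log(vy * 1e-10), np.log(vy * 1e4))] * k
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                self._loglik_and_grad,
                x0,
                args=(grams, yc),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 1000, "ftol": 1e-16, "gtol": 1e-12},
            )
        s2 = np.exp(res.x)
        # accept a near-stationary point even when the line search gives up
        grad_ok = np.isfinite(res.fun) and np.max(np.abs(res.jac)) < 1e-3 * max(1.0, abs(res.fun))
        converged = np.isfinite(res.fun) and (bool(res.success) or grad_ok)
        loglik = -float(res.fun)

        # snap boundary components to exactly zero for reporting
        floor = vy * 1e-8
        varcomps = {t: (0.0 if v < floor else float(v)) for t, v in zip(terms, s2[:-1])}
        varcomps["residual"] = float(max(s2[-1], 0.0))

        # mixed-model equations at the estimate
        v = s2[-1] * np.eye(self.n)
        for kk, g in enumerate(grams):
            v += s2[kk] * g
        cf = linalg.cho_factor(v, lower=True, check_finite=False)
        vi1 = linalg.cho_solve(cf, np.ones(self.n), check_finite=False)
        intercept = ymean + float(vi1 @ yc / vi1.sum())
        resid_v = linalg.cho_solve(cf, self.y - intercept, check_finite=False)
        zg, glevels = self._factor("genotype")
        u_g = s2[terms.index("genotype")] * (zg.T @ resid_v)
        blups = pd.Series(intercept + u_g, index=glevels, name="blup")

        n_params = k + 1  # variance components (incl residual) + intercept
        aic = -2.0 * loglik + 2.0 * n_params
        return TrialFitResults(
            spec=spec,
            varcomps=varcomps,
            loglik_reml=loglik,
            aic=aic,
            n_params=n_params,
            intercept=intercept,
            genotype_blups=blups,
            converged=converged,
            n_obs=self.n,
        )

    def fit_best(self, specs: list[ModelSpec] | None = None) -> TrialFitResults:
        """Fit all candidate structures and return the AIC-selected one."""
        if specs is None:
            specs = candidate_models()
        fits = []
        for spec in specs:
            try:
                fits.append(self.fit(spec))
            except ValueError:
                continue
        return select_model(fits)


def select_model(fits: list[TrialFitResults]) -> TrialFitResults:
    """Lowest-AIC converged fit; ties break to fewest parameters, then order."""
    usable = [(f.aic, f.n_params, i, f) for i, f in enumerate(fits) if f.converged]
    if not usable:
        raise ValueError("no candidate model converged")
    usable.sort(key=lambda t: (t[0], t[1], t[2]))
    return usable[0][3]


def heritability(varcomps: dict[str, float]) -> float:
    """Broad-sense H2 = Var(genotype) / (Var(genotype) + Var(residual))."""
    vg = varcomps.get("genotype", np.nan)
    ve = varcomps.get("residual", np.nan)
    tot = vg + ve
    if not np.isfinite(tot) or tot <= 0:
        return np.nan
    return float(vg / tot)


def h2_class(h2: float) -> str:
    """low < 0.30 <= medium <= 0.60 < high (missing for NaN)."""
    if not np.isfinite(h2):
        return "missing"
    if h2 < 0.30:
        return "low"
    if h2 <= 0.60:
        return "medium"
    return "high"


def summarize_blups(fit: TrialFitResults, accessions: pd.DataFrame) -> pd.DataFrame:
    """Summary rows (all accessions + one per growth group) of BLUP values.

    ``accessions`` maps genotype_id to growth_group.  cv_pct is
    ``100 * sd / |mean|``.
    """
    meta = accessions.drop_duplicates("genotype_id").set_index("genotype_id")["growth_group"]
    blups = fit.genotype_blups
    groups = [("all", blups)]
    for gp in sorted(meta.unique()):
        ids = meta.index[meta == gp]
        sub = blups.loc[blups.index.intersection(ids)]
        if len(sub):
            groups.append((f"GP{gp}", sub))
    rows = []
    for name, vals in groups:
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            {
                "group": name,
                "n_obs": len(vals),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "mean": mean,
                "sd": sd,
                "cv_pct": 100.0 * sd / abs(mean) if mean != 0 else np.nan,
                "h2": fit.h2,
                "h2_class": fit.h2_class,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# data cleaning
# ---------------------------------------------------------------------------

def filter_emergence(
    plots: pd.DataFrame, threshold_pct: float = 30.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop plots whose emergence is below the threshold (E == threshold kept).

    Returns the retained table and a removal report with per-field counts.
    """
    e = plots["emergence_pct"].to_numpy(float)
    keep = ~(e < threshold_pct)  # NaN emergence is retained
    removed = plots[~keep]
    group_cols = [c for c in ("year", "treatment") if c in plots.columns]
    if group_cols:
        report = (
            removed.groupby(group_cols, dropna=False).size().rename("n_removed").reset_index()
        )
    else:
        report = pd.DataFrame({"n_removed": [len(removed)]})
    return plots[keep].reset_index(drop=True), report


def tukey_clean(values) -> np.ndarray:
    """Boolean outlier mask by Tukey's fences (1.5 IQR beyond the quartiles).

    Quartiles use linear interpolation between order statistics.  Applied per
    trait x treatment x year by the pipeline; with fewer than 4 non-missing
    values nothing is flagged.
    """
    x = np.asarray(values, dtype=float)
    mask = np.zeros(x.shape, dtype=bool)
    ok = np.isfinite(x)
    if ok.sum() < 4:
        return mask
    q1, q3 = np.quantile(x[ok], [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask[ok] = (x[ok] < lo) | (x[ok] > hi)
    return mask


def maybe_transform(values) -> tuple[np.ndarray, str]:
    """Automatic skewness-guarded transform: |skew| > 1 -> log1p, else none.

    log1p requires all values > -1; otherwise the data are left untouched
    with a warning.  The returned flag ('none' or 'log1p') is recorded per
    trait; BLUPs are reported on the analysis scale.
    """
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 3:
        return x, "none"
    skew = stats.skew(x[ok])
    if abs(skew) > 1.0:
        if np.min(x[ok]) > -1.0:
            out = np.where(ok, np.log1p(x), np.nan)
            return out, "log1p"
        warnings.warn("skewed response contains values <= -1; transform skipped")
    return x, "none"
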