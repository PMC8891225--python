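"""Drought-index, correlation and PCA analysis of genotype BLUPs.

The drought index of a genotype for one trait is

    Yr = (Control - Drought) / Control

computed on BLUPs, so Yr = 0 means identical performance, Yr > 0 a lower
value under drought (the trait is reduced by stress) and Yr < 0 a higher
value under drought.  Yr is only defined for genotypes observed in both
treatments and is skipped for traits determined before the drought started
(PLV, CC75) and for DET (a growth-habit trait rather than a response).

Multi-trait patterns are summarised by a PCA on the standardized Yr matrix
(correlation scaling, complete-case genotypes), optionally after a greedy
within-subset reduction of highly correlated variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "NO_YR_TRAITS",
    "drought_index",
    "yr_table",
    "cv_of_yr",
    "correlation_suite",
    "reduce_variables",
    "PCAResult",
    "pca_biplot",
    "plot_biplot",
]

#: traits for which a drought index is not computed: PLV and CC75 describe
#: moments before drought initiation; DET reflects growth habit.
NO_YR_TRAITS = ("PLV", "CC75", "DET")

#: |control| below this multiple of the trait sd makes Yr undefined.
YR_CONTROL_FLOOR = 1e-6


def drought_index(control, drought, floor: float = 0.0):
    """(control - drought) / control on BLUPs; NaN when |control| <= floor."""
    c = np.asarray(control, dtype=float)
    d = np.asarray(drought, dtype=float)
    small = np.abs(c) <= floor
    if np.any(small):
        warnings.warn("control BLUP at or below the floor; Yr set to missing")
    with np.errstate(divide="ignore", invalid="ignore"):
        yr = np.where(small, np.nan, (c - d) / c)
    return float(yr) if yr.ndim == 0 else yr


def yr_table(
    blups_control: pd.DataFrame,
    blups_drought: pd.DataFrame,
    skip_traits: tuple[str, ...] = NO_YR_TRAITS,
) -> pd.DataFrame:
    """Per-genotype drought indices from two BLUP tables.

    Both tables are wide (index genotype, one column per trait).  Only the
    genotypes present in both treatments enter (inner join); the common count
    is recorded per trait as ``n_common``.

    Returns a long frame: genotype, trait, control, drought, yr.
    """
    common = blups_control.index.intersection(blups_drought.index)
    if len(common) == 0:
        raise ValueError("no genotype is present in both treatments")
    rows = []
    for trait in blups_control.columns:
        if trait in skip_traits or trait not in blups_drought.columns:
            continue
        c = blups_control.loc[common, trait].astype(float)
        d = blups_drought.loc[common, trait].astype(float)
        ok = c.notna() & d.notna()
        floor = YR_CONTROL_FLOOR * float(np.nanstd(c))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            yr = drought_index(c[ok].to_numpy(), d[ok].to_numpy(), floor=floor)
        rows.append(
            pd.DataFrame(
                {
                    "genotype_id": common[ok],
                    "trait": trait,
                    "control": c[ok].to_numpy(),
                    "drought": d[ok].to_numpy(),
                    "yr": yr,
                    "n_common": int(ok.sum()),
                }
            )
        )
    if not rows:
        raise ValueError("no trait is shared between the two BLUP tables")
    return pd.concat(rows, ignore_index=True)


def cv_of_yr(yr, floor: float = 1e-12) -> float:
    """Coefficient of variation (%) of drought-index values: 100*sd/|mean|."""
    x = np.asarray(yr, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        return np.nan
    mean = x.mean()
    if abs(mean) < floor:
        return np.nan
    return float(100.0 * x.std(ddof=1) / abs(mean))


def correlation_suite(tables: dict[str, pd.DataFrame], min_pairs: int = 3) -> pd.DataFrame:
    """Pearson correlations between all table pairs that share an index.

    ``tables`` maps a label (e.g. 'control_2018', 'yr_2018') to a wide frame
    (index genotype, columns traits).  For every ordered pair of distinct
    labels and every trait present in both, the pairwise-complete Pearson r
    is computed; within-table trait x trait correlations are included under
    the family '<label>:within'.  Entries with fewer than ``min_pairs``
    complete pairs are reported as NaN.

    Returns a long frame: family, x, y, r, n.
    """
    rows = []

    def _corr(a: pd.Series, b: pd.Series):
        ok = a.notna() & b.notna()
        n = int(ok.sum())
        if n < min_pairs:
            return np.nan, n
        av, bv = a[ok].to_numpy(float), b[ok].to_numpy(float)
        if av.std() == 0 or bv.std() == 0:
            return np.nan, n
        return float(np.corrcoef(av, bv)[0, 1]), n

    labels = list(tables)
    for label in labels:
        df = tables[label]
        cols = list(df.columns)
        for i, x in enumerate(cols):
            for y in cols[i + 1 :]:
                r, n = _corr(df[x], df[y])
                rows.append({"family": f"{label}:within", "x": x, "y": y, "r": r, "n": n})
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            a, b = tables[la], tables[lb]
            shared = a.index.intersection(b.index)
            for trait in [c for c in a.columns if c in b.columns]:
                r, n = _corr(a.loc[shared, trait], b.loc[shared, trait])
                rows.append({"family": f"{la}~{lb}", "x": trait, "y": trait, "r": r, "n": n})
    return pd.DataFrame(rows)


def reduce_variables(
    data: pd.DataFrame,
    subsets: dict[str, list[str]] | None = None,
    r_threshold: float = 0.8,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy within-subset removal of highly correlated variables.

    Variables are visited in their declared order within each subset; a
    variable whose |r| with an already-retained variable of the same subset
    reaches the threshold is dropped (recorded with the variable it
    duplicates).  With no subsets, all columns form one subset.

    Returns (retained variables in original order, dropped records).
    """
    if subsets is None:
        subsets = {"all": list(data.columns)}
    retained: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for _, variables in subsets.items():
        kept_here: list[str] = []
        for var in variables:
            if var not in data.columns:
                continue
            reason = None
            for prev in kept_here:
                ok = data[var].notna() & data[prev].notna()
                if ok.sum() < 3:
                    continue
                r = np.corrcoef(data.loc[ok, var], data.loc[ok, prev])[0, 1]
                if np.isfinite(r) and abs(r) >= r_threshold:
                    reason = (var, prev, float(r))
                    break
            if reason is None:
                kept_here.append(var)
            else:
                dropped.append(reason)
        retained.extend(kept_here)
    return [c for c in data.columns if c in retained], dropped


@dataclass
class PCAResult:
    """Standardized PCA of a genotype x variable response matrix."""

    variables: list[str]
    loadings: pd.DataFrame  # variables x PCs, orthonormal columns
    scores: pd.DataFrame  # genotypes x PCs
    explained_variance_ratio: np.ndarray
    n_complete: int
    dropped_variables: list[tuple[str, str, float]]

    def summary(self) -> str:
        lines = [
            "Principal component analysis (correlation scaling)",
            f"variables : {', '.join(self.variables)}",
            f"complete-case genotypes : {self.n_complete}",
        ]
        for i, v in enumerate(self.explained_variance_ratio):
            lines.append(f"PC{i + 1}: {100 * v:.1f}% of variance")
        if self.dropped_variables:
            for var, dup, r in self.dropped_variables:
                lines.append(f"dropped {var} (|r|={abs(r):.2f} with {dup})")
        return "\n".join(lines)


def pca_biplot(
    data: pd.DataFrame,
    subsets: dict[str, list[str]] | None = None,
    r_threshold: float | None = None,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of centered, unit-variance columns on complete-case rows.

    ``data`` is a wide genotype x variable frame (drought indices plus any
    max-over-dates scores).  When ``r_threshold`` is given, redundant
    variables are first removed per subset via :func:`reduce_variables`.
    A constant column is an error (it cannot be standardized).
    """
    dropped: list[tuple[str, str, float]] = []
    if r_threshold is not None:
        keep, dropped = reduce_variables(data, subsets, r_threshold)
        data = data[keep]
    complete = data.dropna()
    if len(complete) < len(data.columns) + 1:
        raise ValueError(
            f"only {len(complete)} complete-case rows for {len(data.columns)} variables"
        )
    sd = complete.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant column(s) cannot enter a standardized PCA: {constant}")
    z = (complete - complete.mean()) / sd
    k = n_components or len(data.columns)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    pcs = [f"PC{i + 1}" for i in range(pca.n_components_)]
    return PCAResult(
        variables=list(data.columns),
        loadings=pd.DataFrame(pca.components_.T, index=data.columns, columns=pcs),
        scores=pd.DataFrame(scores, index=complete.index, columns=pcs),
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_complete=len(complete),
        dropped_variables=dropped,
    )


def plot_biplot(result: PCAResult, ax=None, score_color=None):
    """Simple static score + loading biplot of the first two components."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    xs, ys = result.scores["PC1"], result.scores["PC2"]
    ax.scatter(xs, ys, s=12, alpha=0.6, c=score_color)
    scale = 0.9 * max(xs.abs().max(), ys.abs().max())
    for var in result.variables:
        lx, ly = result.loadings.loc[var, ["PC1", "PC2"]]
        ax.annotate(
            var,
            xy=(lx * scale, ly * scale),
            xytext=(0, 0),
            textcoords="data",
            arrowprops={"arrowstyle": "<-", "color": "firebrick"},
            color="firebrick",
            fontsize=9,
        )
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    return ax
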