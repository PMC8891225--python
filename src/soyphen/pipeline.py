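"""Reproducible generate -> extract -> fit -> respond -> report workflow.

Each stage reads the CSV outputs of the previous one from a working
directory and writes its own, so any stage can be re-run from cached
inputs.  A run manifest (JSON) records the configuration hash, the master
seed, file checksums and the bookkeeping counts (plots retained, outliers
removed, fits converged, genotypes in the PCA); identical configuration and
seed give identical checksums.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .envmet import cwsi as _cwsi, estimate_baselines
from .extract import extract_traits
from .mixedmodel import (
    AugmentedTrialModel,
    candidate_models,
    filter_emergence,
    maybe_transform,
    summarize_blups,
    tukey_clean,
)
from .response import NO_YR_TRAITS, correlation_suite, cv_of_yr, pca_biplot, yr_table
from .scenario import TrialSimulator, merge_config, validate_config

__all__ = ["load_config", "run", "STAGES", "PipelineError"]

STAGES = ("simulate", "extract", "fit", "respond", "report")

#: which upstream files each stage needs, and the stage that makes them
_REQUIRES = {
    "extract": (["series.csv", "manual_traits.csv", "design.csv", "thermal.csv"], "simulate"),
    "fit": (["traits.csv", "design.csv"], "extract"),
    "respond": (["blups.csv"], "fit"),
    "report": (["summary.csv", "fits.csv"], "fit"),
}

#: plot-level traits that get their own mixed model (durations are derived
#: from the R2/R5/R8 BLUPs instead, so no variance components exist for them)
DURATION_TRAITS = ("R2R5", "R5R8", "R2R8")

PCA_YR_TRAITS = ("R2", "R5", "R8", "R2R5", "R5R8", "R2R8", "AGRmax", "CH", "SNC", "PPS", "SN", "SW")
PCA_SUBSETS = {
    "developmental": ["R2-Yr", "R5-Yr", "R8-Yr", "R2R5-Yr", "R5R8-Yr", "R2R8-Yr"],
    "growth": ["AGRmax-Yr", "CH-Yr", "SNC-Yr"],
    "resistance": ["CW", "LSEN", "CWSI-Yr"],
    "yield": ["PPS-Yr", "SN-Yr", "SW-Yr"],
}


class PipelineError(RuntimeError):
    pass


def load_config(path=None) -> dict:
    """Load, merge with defaults and validate a YAML configuration file."""
    overrides = None
    if path is not None:
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
    cfg = merge_config(overrides)
    validate_config(cfg)
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write(df: pd.DataFrame, outdir: Path, name: str) -> None:
    df.to_csv(outdir / name, index=False, float_format="%.6g")


def _need(outdir: Path, stage: str) -> None:
    if stage not in _REQUIRES:
        return
    files, upstream = _REQUIRES[stage]
    missing = [f for f in files if not (outdir / f).exists()]
    if missing:
        raise PipelineError(
            f"stage '{stage}' is missing input {missing}; run stage '{upstream}' first"
        )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path, log) -> dict:
    sim = TrialSimulator(cfg)
    out = sim.run()
    out.write(outdir)
    counts = (
        out.design.groupby(["year", "treatment"]).size().rename("n_plots").reset_index()
    )
    for rec in counts.itertuples():
        log(f"simulate: {rec.year} {rec.treatment}: {rec.n_plots} plots")
    return {"plots_per_field": counts.to_dict("records")}


def stage_extract(cfg: dict, outdir: Path, log) -> dict:
    _need(outdir, "extract")
    series = pd.read_csv(outdir / "series.csv")
    manual = pd.read_csv(outdir / "manual_traits.csv")
    design = pd.read_csv(outdir / "design.csv")
    thermal = pd.read_csv(outdir / "thermal.csv")

    traits, fits = extract_traits(series, manual)
    n_bad = int((~fits["converged"]).sum()) if len(fits) else 0
    log(f"extract: {len(fits)} curve fits, {n_bad} non-convergent")
    for rec in fits[~fits["converged"]].itertuples():
        log(f"extract: non-convergent {rec.response} fit for plot {rec.plot_id}")

    # CWSI per year x flight with empirically estimated baselines
    cw_cfg = cfg["cwsi"]
    cwsi_rows = []
    for (year, flight), grp in thermal.groupby(["year", "flight"]):
        dt = pd.Series(
            grp["canopy_temp"].to_numpy(float) - grp["air_temp"].to_numpy(float),
            index=grp["plot_id"],
        )
        ww = grp.loc[grp["treatment"] == "control", "plot_id"]
        try:
            dt_ll, dt_ul = estimate_baselines(
                dt, ww, q_low=cw_cfg["q_low"], q_high=cw_cfg["q_high"], margin=cw_cfg["margin"]
            )
        except ValueError as exc:
            log(f"extract: CWSI baselines failed for {year} {flight}: {exc}")
            continue
        vals = _cwsi(grp["canopy_temp"].to_numpy(float), grp["air_temp"].to_numpy(float), dt_ll, dt_ul)
        cwsi_rows.append(
            pd.DataFrame(
                {
                    "year": year,
                    "flight": flight,
                    "plot_id": grp["plot_id"].to_numpy(),
                    "treatment": grp["treatment"].to_numpy(),
                    "tc": grp["canopy_temp"].to_numpy(float),
                    "ta": grp["air_temp"].to_numpy(float),
                    "dt": dt.to_numpy(),
                    "dt_ll": dt_ll,
                    "dt_ul": dt_ul,
                    "cwsi": vals,
                }
            )
        )
    cwsi_df = (
        pd.concat(cwsi_rows, ignore_index=True)
        if cwsi_rows
        else pd.DataFrame(columns=["year", "flight", "plot_id", "treatment", "cwsi"])
    )
    _write(cwsi_df, outdir, "cwsi.csv")
    if len(cwsi_df):
        wide = cwsi_df.pivot_table(index="plot_id", columns="flight", values="cwsi")
        wide.columns = [f"CWSI_{c}" for c in wide.columns]
        traits = traits.merge(wide, left_on="plot_id", right_index=True, how="left")

    # field-observed emergence travels with the trait table
    traits = traits.merge(
        design[["plot_id", "emergence_pct"]].rename(columns={"emergence_pct": "E"}),
        on="plot_id",
        how="left",
    )
    _write(traits, outdir, "traits.csv")
    _write(fits, outdir, "curvefits.csv")
    return {"curve_fits": len(fits), "curve_fits_failed": n_bad}


def stage_fit(cfg: dict, outdir: Path, log) -> dict:
    _need(outdir, "fit")
    traits = pd.read_csv(outdir / "traits.csv")
    design = pd.read_csv(outdir / "design.csv")

    retained, removal = filter_emergence(
        traits.rename(columns={"E": "emergence_pct"}), threshold_pct=30.0
    )
    retained = retained.rename(columns={"emergence_pct": "E"})
    for rec in removal.itertuples(index=False):
        log(f"fit: emergence filter removed {rec.n_removed} plots in {rec.year} {rec.treatment}")
    removed_ids = set(traits["plot_id"]) - set(retained["plot_id"])
    for pid in sorted(removed_ids):
        log(f"fit: plot {pid} removed (emergence < 30%)")

    id_cols = {"year", "treatment", "plot_id", "E"}
    trait_cols = [
        c for c in retained.columns if c not in id_cols and pd.api.types.is_numeric_dtype(retained[c])
    ]
    dmeta = design[["plot_id", "genotype_id", "growth_group", "block", "row", "column"]]
    data = retained.merge(dmeta, on="plot_id", how="left")

    blup_rows, fit_rows, summary_rows = [], [], []
    n_outliers = n_converged = 0
    for (year, trt), sub in data.groupby(["year", "treatment"]):
        for trait in trait_cols:
            if trait in DURATION_TRAITS:
                continue
            y = sub[trait].to_numpy(float)
            if np.isfinite(y).sum() < 20:
                continue
            mask = tukey_clean(y)
            if mask.any():
                n_outliers += int(mask.sum())
                for pid in sub.loc[mask, "plot_id"]:
                    log(f"fit: outlier removed {year} {trt} {trait} plot {pid}")
                y = np.where(mask, np.nan, y)
            y, transform = maybe_transform(y)
            try:
                model = AugmentedTrialModel(y, sub)
                fit = model.fit_best(candidate_models(transform))
            except ValueError as exc:
                log(f"fit: skipped {year} {trt} {trait}: {exc}")
                continue
            n_converged += 1
            rec = {
                "year": year,
                "treatment": trt,
                "trait": trait,
                "model": fit.spec.label,
                "transform": transform,
                "n_obs": fit.n_obs,
                "loglik_reml": fit.loglik_reml,
                "aic": fit.aic,
                "h2": fit.h2,
                "h2_class": fit.h2_class,
            }
            for term, v in fit.varcomps.items():
                rec[f"var_{term}"] = v
            fit_rows.append(rec)
            for gid, b in fit.genotype_blups.items():
                blup_rows.append(
                    {"year": year, "treatment": trt, "trait": trait, "genotype_id": gid, "blup": b}
                )
            summ = summarize_blups(fit, dmeta)
            summ.insert(0, "trait", trait)
            summ.insert(0, "treatment", trt)
            summ.insert(0, "year", year)
            summary_rows.append(summ)

    blups = pd.DataFrame(blup_rows)
    # durations from the spatially adjusted (BLUP) stage values
    gp_of = design.drop_duplicates("genotype_id").set_index("genotype_id")["growth_group"]
    for (year, trt), sub in blups.groupby(["year", "treatment"]):
        wide = sub.pivot_table(index="genotype_id", columns="trait", values="blup")
        if not {"R2", "R5", "R8"} <= set(wide.columns):
            continue
        derived = {
            "R2R5": wide["R5"] - wide["R2"],
            "R5R8": wide["R8"] - wide["R5"],
            "R2R8": wide["R8"] - wide["R2"],
        }
        for name, vals in derived.items():
            vals = vals.dropna()
            blups = pd.concat(
                [
                    blups,
                    pd.DataFrame(
                        {
                            "year": year,
                            "treatment": trt,
                            "trait": name,
                            "genotype_id": vals.index,
                            "blup": vals.to_numpy(),
                        }
                    ),
                ],
                ignore_index=True,
            )
            groups = [("all", vals)] + [
                (f"GP{gp}", vals[vals.index.map(gp_of) == gp]) for gp in sorted(gp_of.unique())
            ]
            for gname, gv in groups:
                if not len(gv):
                    continue
                mean = float(gv.mean())
                sd = float(gv.std(ddof=1)) if len(gv) > 1 else 0.0
                summary_rows.append(
                    pd.DataFrame(
                        [
                            {
                                "year": year,
                                "treatment": trt,
                                "trait": name,
                                "group": gname,
                                "n_obs": len(gv),
                                "min": float(gv.min()),
                                "max": float(gv.max()),
                                "mean": mean,
                                "sd": sd,
                                "cv_pct": 100.0 * sd / abs(mean) if mean != 0 else np.nan,
                                "h2": np.nan,
                                "h2_class": "missing",
                            }
                        ]
                    )
                )

    _write(blups, outdir, "blups.csv")
    _write(pd.DataFrame(fit_rows), outdir, "fits.csv")
    _write(pd.concat(summary_rows, ignore_index=True), outdir, "summary.csv")
    log(f"fit: {n_converged} trait models fitted, {n_outliers} outliers removed")
    return {
        "plots_retained": len(retained),
        "plots_removed_emergence": len(removed_ids),
        "outliers_removed": n_outliers,
        "fits_converged": n_converged,
    }


def stage_respond(cfg: dict, outdir: Path, log) -> dict:
    _need(outdir, "respond")
    blups = pd.read_csv(outdir / "blups.csv")
    years = sorted(blups["year"].astype(str).unique())

    tables: dict[str, pd.DataFrame] = {}
    for (year, trt), sub in blups.groupby(["year", "treatment"]):
        tables[f"{trt}_{year}"] = sub.pivot_table(index="genotype_id", columns="trait", values="blup")

    yr_parts = []
    for year in years:
        c, d = tables.get(f"control_{year}"), tables.get(f"drought_{year}")
        if c is None or d is None:
            continue
        yr = yr_table(c, d)
        yr.insert(0, "year", year)
        yr_parts.append(yr)
    yr_long = pd.concat(yr_parts, ignore_index=True) if yr_parts else pd.DataFrame()
    _write(yr_long, outdir, "yr.csv")

    corr_tables = dict(tables)
    for year in years:
        if len(yr_long):
            sub = yr_long[yr_long["year"] == year]
            corr_tables[f"yr_{year}"] = sub.pivot_table(
                index="genotype_id", columns="trait", values="yr"
            )
    _write(correlation_suite(corr_tables), outdir, "correlations.csv")

    scores_parts, load_parts, summ_parts = [], [], []
    n_pca_genotypes = {}
    for year in years:
        yr_wide = corr_tables.get(f"yr_{year}")
        drought = tables.get(f"drought_{year}")
        if yr_wide is None or drought is None:
            continue
        mat = pd.DataFrame(index=yr_wide.index)
        for trait in PCA_YR_TRAITS:
            if trait in yr_wide.columns:
                mat[f"{trait}-Yr"] = yr_wide[trait]
        cwsi_cols = sorted(c for c in yr_wide.columns if c.startswith("CWSI_"))
        if cwsi_cols:
            mat["CWSI-Yr"] = yr_wide[cwsi_cols[-1]]  # last measurement date
        for score in ("CW", "LSEN"):
            cols = sorted(c for c in drought.columns if c.startswith(f"{score}_"))
            if cols:  # highest value observed at any date
                mat[score] = drought.loc[mat.index.intersection(drought.index), cols].max(axis=1)
        # a constant column cannot be standardized; constancy is judged on the
        # complete-case rows the PCA will actually see, so iterate to a fixpoint
        while True:
            sparse = [c for c in mat.columns if mat[c].notna().sum() < max(5, 0.3 * len(mat))]
            cc = mat.drop(columns=sparse).dropna()
            flat = sparse + [c for c in cc.columns if len(cc) and cc[c].nunique() <= 1]
            if not flat:
                break
            for c in flat:
                log(f"respond: PCA {year}: dropped constant/empty variable {c}")
            mat = mat.drop(columns=flat)
        try:
            pca = pca_biplot(mat, subsets=PCA_SUBSETS, r_threshold=0.8)
        except ValueError as exc:
            log(f"respond: PCA skipped for {year}: {exc}")
            continue
        n_pca_genotypes[year] = pca.n_complete
        sc = pca.scores.reset_index().rename(columns={"index": "genotype_id"})
        sc.insert(0, "year", year)
        scores_parts.append(sc)
        ld = pca.loadings.reset_index().rename(columns={"index": "variable"})
        ld.insert(0, "year", year)
        load_parts.append(ld)
        rows = [
            {"year": year, "entry": f"PC{i + 1}", "value": 100.0 * v, "note": "explained_variance_pct"}
            for i, v in enumerate(pca.explained_variance_ratio)
        ]
        rows.append({"year": year, "entry": "n_complete", "value": pca.n_complete, "note": ""})
        for var, dup, r in pca.dropped_variables:
            rows.append({"year": year, "entry": f"dropped:{var}", "value": r, "note": f"|r|>=0.8 with {dup}"})
        summ_parts.append(pd.DataFrame(rows))
        log(f"respond: PCA {year}: {pca.n_complete} genotypes, vars: {', '.join(pca.variables)}")

    for parts, name in (
        (scores_parts, "pca_scores.csv"),
        (load_parts, "pca_loadings.csv"),
        (summ_parts, "pca_summary.csv"),
    ):
        _write(pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(), outdir, name)
    return {"genotypes_in_pca": n_pca_genotypes, "n_yr_rows": len(yr_long)}


def _is_per_date(trait: str) -> bool:
    return trait.startswith(("CW_", "LSEN_", "CWSI_"))


def stage_report(cfg: dict, outdir: Path, log) -> dict:
    _need(outdir, "report")
    summary = pd.read_csv(outdir / "summary.csv")
    yr_path = outdir / "yr.csv"
    yr = pd.read_csv(yr_path) if yr_path.exists() and yr_path.stat().st_size > 1 else pd.DataFrame()

    def _yr_cell(year, trait):
        if trait in NO_YR_TRAITS or not len(yr):
            return "", ""
        sub = yr[(yr["year"].astype(str) == str(year)) & (yr["trait"] == trait)]
        if not len(sub):
            return "", ""
        vals = sub["yr"].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if not len(vals):
            return "", ""
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        return f"{vals.mean():.2f} ± {sd:.2f}", str(int(sub["n_common"].iloc[0]))

    lines = ["Synthetic trial analysis report", "=" * 60, ""]
    overall = summary[summary["group"] == "all"].copy()
    for per_date, title in ((False, "Season traits"), (True, "Per-date traits (CW / LSEN / CWSI)")):
        sel = overall[overall["trait"].map(_is_per_date) == per_date]
        if not len(sel):
            continue
        lines += [title, "-" * len(title)]
        rows = []
        for rec in sel.itertuples():
            yr_mean, n_common = _yr_cell(rec.year, rec.trait)
            rows.append(
                {
                    "trait": rec.trait,
                    "year": rec.year,
                    "treat": rec.treatment[0].upper(),
                    "n": rec.n_obs,
                    "mean±sd": f"{rec.mean:.2f} ± {rec.sd:.2f}",
                    "CV%": f"{rec.cv_pct:.1f}" if np.isfinite(rec.cv_pct) else "",
                    "H2": f"{rec.h2:.2f}" if np.isfinite(rec.h2) else "",
                    "Yr (mean±sd)": yr_mean,
                    "n_common": n_common,
                }
            )
        tbl = pd.DataFrame(rows).sort_values(["trait", "year", "treat"])
        lines += [tbl.to_string(index=False), ""]

    if len(yr):
        lines += ["Drought-index dispersion (CV% of Yr)", "-" * 36]
        for (year, trait), sub in yr.groupby(["year", "trait"]):
            cv = cv_of_yr(sub["yr"])
            if np.isfinite(cv):
                lines.append(f"  {year} {trait:<12s} {cv:8.1f}")
        lines.append("")

    pca_path = outdir / "pca_summary.csv"
    if pca_path.exists() and pca_path.stat().st_size > 1:
        pca = pd.read_csv(pca_path)
        if len(pca):
            lines += ["PCA of multi-trait drought responses", "-" * 36, pca.to_string(index=False), ""]

    report = "\n".join(lines)
    (outdir / "report.txt").write_text(report)
    log("report: written report.txt")
    return {"report_lines": len(lines)}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "fit": stage_fit,
    "respond": stage_respond,
    "report": stage_report,
}


def run(
    config: dict | str | Path | None = None,
    stages=STAGES,
    seed: int | None = None,
    outdir="soyphen_run",
) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = merge_config(config)
        validate_config(cfg)
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise PipelineError(f"unknown stage(s) {bad}; valid stages: {list(STAGES)}")
    ordered = [s for s in STAGES if s in stages]

    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    counts: dict = {}
    for stage in ordered:
        counts[stage] = _STAGE_FUNCS[stage](cfg, outdir, log)

    (outdir / "cleaning_log.txt").write_text("\n".join(log_lines) + "\n")
    manifest = {
        "package": "soyphen",
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "stages": ordered,
        "counts": counts,
        "files": {
            p.name: {"sha256": _checksum(p), "n_rows": max(sum(1 for _ in p.open()) - 1, 0)}
            for p in sorted(outdir.glob("*.csv"))
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
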