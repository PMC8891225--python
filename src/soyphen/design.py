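"""Augmented row-column trial designs for soybean germplasm screening.

An augmented design evaluates a large number of unreplicated accessions
alongside a small set of replicated check varieties.  The checks, present in
several blocks, carry the information needed to estimate spatial (block, row,
column) effects so that the unreplicated entries can be adjusted for field
trends.  The reference trial evaluated 359 accessions in 454 plots per field:
three checks replicated nine times, nine replicated six times, thirteen
replicated three times, and 334 entries sown once.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Accession",
    "TrialDesign",
    "DesignCapacityError",
    "PAPER_CHECK_CLASSES",
    "PAPER_N_UNREPLICATED",
    "DEFAULT_SOWING_DATES",
    "build_design",
    "plot_geometry",
]

#: replication classes of the reference trial: (number of checks, replicates).
PAPER_CHECK_CLASSES: tuple[tuple[int, int], ...] = ((3, 9), (9, 6), (13, 3))
PAPER_N_UNREPLICATED: int = 334

#: staggered sowing dates per growth group (late GP1 sown first) used as
#: defaults; the four groups are sown on different dates to synchronise the
#: developmental stage at which drought is imposed.
DEFAULT_SOWING_DATES: dict[int, _dt.date] = {
    1: _dt.date(2018, 4, 20),
    2: _dt.date(2018, 5, 2),
    3: _dt.date(2018, 5, 8),
    4: _dt.date(2018, 5, 11),
}

# sowing density (seeds m^-2) per growth group; GP1 = latest maturity class.
_SOWING_DENSITY = {1: 45.0, 2: 55.0, 3: 65.0, 4: 75.0}
# GP1/GP2 plots are thinned to 60% of the seeding density after emergence;
# GP3/GP4 are not thinned.
_THINNED_GROUPS = {1, 2}


class DesignCapacityError(ValueError):
    """Raised when the block grid cannot hold the requested number of plots."""


@dataclass(frozen=True)
class Accession:
    """One entry of the germplasm collection.

    ``rep_class`` is the number of plots the accession occupies in one field;
    checks (replicated entries) have ``rep_class`` > 1.
    """

    id: str
    growth_group: int
    is_check: bool
    rep_class: int

    def __post_init__(self) -> None:
        if self.rep_class not in (9, 6, 3, 1):
            raise ValueError(f"rep_class must be one of 9/6/3/1, got {self.rep_class}")
        if self.is_check != (self.rep_class > 1):
            raise ValueError("is_check must hold exactly when rep_class > 1")
        if self.growth_group not in (1, 2, 3, 4):
            raise ValueError(f"growth_group must be in 1..4, got {self.growth_group}")


@dataclass
class TrialDesign:
    """A single-field layout: one row per plot, with spatial coordinates.

    ``frame`` columns: plot_id, genotype_id, growth_group, is_check,
    rep_class, block, row, column, sowing_date, row_spacing, plot_area,
    seeds_sown, emergence_pct (NaN until emergence is simulated or observed).
    """

    frame: pd.DataFrame
    year_label: str = "2018"
    treatment: str = "control"

    def __post_init__(self) -> None:
        if self.treatment not in ("control", "drought"):
            raise ValueError(f"treatment must be control/drought, got {self.treatment}")
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        df = self.frame
        occupied = df[["block", "row", "column"]]
        if occupied.duplicated().any():
            raise ValueError("each (block,row,column) cell may hold at most one plot")
        counts = df.groupby("genotype_id").size()
        declared = df.drop_duplicates("genotype_id").set_index("genotype_id")["rep_class"]
        bad = counts[counts != declared.loc[counts.index]]
        if len(bad):
            raise ValueError(f"replication counts disagree with rep_class for {list(bad.index)}")

    @property
    def n_plots(self) -> int:
        return len(self.frame)

    @property
    def n_genotypes(self) -> int:
        return self.frame["genotype_id"].nunique()

    def accessions(self) -> list[Accession]:
        rows = self.frame.drop_duplicates("genotype_id")
        return [
            Accession(r.genotype_id, int(r.growth_group), bool(r.is_check), int(r.rep_class))
            for r in rows.itertuples()
        ]

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "treatment", self.treatment)
        out.insert(0, "year", self.year_label)
        out.to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialDesign":
        year = str(frame["year"].iloc[0]) if "year" in frame else "2018"
        treat = str(frame["treatment"].iloc[0]) if "treatment" in frame else "control"
        cols = [c for c in frame.columns if c not in ("year", "treatment")]
        return cls(frame[cols].reset_index(drop=True), year_label=year, treatment=treat)


def plot_geometry(growth_group: int) -> tuple[float, float, float, float]:
    """Row spacing, plot area, sowing density and post-thinning density.

    GP1/GP2 (late types) use a 0.40 m row distance on 1.20 x 0.75 m plots and
    are thinned to 60% of the seeding density; GP3/GP4 (early types) use
    0.25 m rows on 0.75 x 1.20 m plots and are not thinned.

    Returns
    -------
    (row_spacing_m, plot_area_m2, sowing_density_seeds_m2, thinned_density_plants_m2)
    """
    if growth_group not in (1, 2, 3, 4):
        raise ValueError(f"growth_group must be in 1..4, got {growth_group}")
    density = _SOWING_DENSITY[growth_group]
    if growth_group in _THINNED_GROUPS:
        spacing, area = 0.40, 1.20 * 0.75
        thinned = 0.60 * density
    else:
        spacing, area = 0.25, 0.75 * 1.20
        thinned = density
    return spacing, area, density, thinned


def _assign_growth_groups(n: int, offset: int = 0) -> list[int]:
    """Cycle entries over the four growth groups (near-equal class sizes)."""
    return [(i + offset) % 4 + 1 for i in range(n)]


def build_design(
    n_unreplicated: int = PAPER_N_UNREPLICATED,
    check_classes: tuple[tuple[int, int], ...] = PAPER_CHECK_CLASSES,
    grid: tuple[int, int] = (6, 9),
    n_blocks: int = 9,
    seed: int = 0,
    year_label: str = "2018",
    treatment: str = "control",
    sowing_dates: dict[int, _dt.date] | None = None,
) -> TrialDesign:
    """Build a randomized augmented row-column design.

    Checks are spread over distinct blocks (round-robin over a seeded block
    permutation) so that replicated entries connect the spatial strata;
    unreplicated entries fill the remaining cells.  Placement within a block
    is a seeded shuffle of the free (row, column) cells.

    Raises
    ------
    DesignCapacityError
        If ``n_blocks * rows * cols`` is smaller than the total plot count.
    """
    if n_unreplicated < 0 or any(n < 0 or r < 1 for n, r in check_classes):
        raise ValueError("check counts and replicate numbers must be non-negative")
    rows, cols = grid
    n_check_plots = sum(n * r for n, r in check_classes)
    total = n_unreplicated + n_check_plots
    capacity = n_blocks * rows * cols
    if capacity < total:
        raise DesignCapacityError(
            f"grid capacity {capacity} ({n_blocks} blocks of {rows}x{cols}) "
            f"cannot hold {total} plots"
        )
    if sowing_dates is None:
        sowing_dates = DEFAULT_SOWING_DATES

    rng = np.random.default_rng(seed)

    # genotype roster
    accessions: list[Accession] = []
    idx = 0
    for class_i, (n_checks, reps) in enumerate(check_classes):
        groups = _assign_growth_groups(n_checks, offset=class_i)
        for j in range(n_checks):
            accessions.append(Accession(f"CHK{reps}_{j + 1:02d}", groups[j], True, reps))
        idx += n_checks
    for j, gp in enumerate(_assign_growth_groups(n_unreplicated)):
        accessions.append(Accession(f"ACC{j + 1:03d}", gp, False, 1))

    # block assignment: each check's replicates round-robin over a seeded
    # block permutation (distinct blocks while reps <= n_blocks)
    block_of: list[list[str]] = [[] for _ in range(n_blocks)]
    for acc in accessions:
        if acc.is_check:
            order = rng.permutation(n_blocks)
            for k in range(acc.rep_class):
                block_of[order[k % n_blocks]].append(acc.id)
    free = [rows * cols - len(b) for b in block_of]
    unrep = [a.id for a in accessions if not a.is_check]
    rng.shuffle(unrep)
    b = 0
    for gid in unrep:
        # next block with free capacity, round-robin for balance
        for _ in range(n_blocks):
            if free[b] > 0:
                break
            b = (b + 1) % n_blocks
        block_of[b].append(gid)
        free[b] -= 1
        b = (b + 1) % n_blocks

    meta = {a.id: a for a in accessions}
    records = []
    plot_no = 0
    for bi in range(n_blocks):
        cells = [(r + 1, c + 1) for r in range(rows) for c in range(cols)]
        rng.shuffle(cells)
        for gid in block_of[bi]:
            r, c = cells.pop()
            acc = meta[gid]
            spacing, area, density, _ = plot_geometry(acc.growth_group)
            plot_no += 1
            records.append(
                {
                    "plot_id": f"{treatment[0].upper()}{year_label}_{plot_no:04d}",
                    "genotype_id": gid,
                    "growth_group": acc.growth_group,
                    "is_check": acc.is_check,
                    "rep_class": acc.rep_class,
                    "block": bi + 1,
                    "row": r,
                    "column": c,
                    "sowing_date": sowing_dates[acc.growth_group].isoformat(),
                    "row_spacing": spacing,
                    "plot_area": area,
                    "seeds_sown": int(round(density * area)),
                    "emergence_pct": np.nan,
                }
            )
    frame = pd.DataFrame.from_records(records)
    frame = frame.sort_values(["block", "row", "column"], kind="mergesort").reset_index(drop=True)
    return TrialDesign(frame, year_label=year_label, treatment=treatment)
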