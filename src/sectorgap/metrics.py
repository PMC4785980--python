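"""Stand-level summary statistics per year and at equilibrium."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stand import StandState, Tree
from .light import ClaimMap

__all__ = [
    "shade_tolerance_index",
    "basal_area",
    "canopy_cover",
    "crown_symmetry",
    "stand_crown_symmetry",
    "annual_record",
    "records_to_frame",
    "equilibrium_summary",
]


def _weights(trees: list[Tree], metric: str) -> np.ndarray:
    if metric == "basal_area":
        return np.array([t.basal_area for t in trees])
    if metric == "count":
        return np.ones(len(trees))
    if metric == "biomass_proxy":
        return np.array([t.dbh ** 2.5 for t in trees])
    raise ValueError(f"unknown weight metric {metric!r}")


def shade_tolerance_index(trees: list[Tree], weight_metric: str = "basal_area") -> float:
    """Abundance-weighted mean shade-tolerance rank of the stand.

    sti = sum(rho_t * w_t) / sum(w_t) with w the chosen abundance weight
    (basal area by default). Undefined (NaN) for an empty stand.
    """
    if not trees:
        return float("nan")
    w = _weights(trees, weight_metric)
    ranks = np.array([t.species.tol_rank for t in trees])
    return float(np.sum(ranks * w) / np.sum(w))


def basal_area(trees: list[Tree], area_ha: float, stratum: str = "all") -> float:
    """Stand basal area (m^2/ha) of a canopy stratum.

    The canopy/understory split uses each tree's canopy flag (won at
    least one pixel of direct light this year).
    """
    if stratum == "all":
        sel = trees
    elif stratum == "canopy":
        sel = [t for t in trees if t.canopy_flag]
    elif stratum == "understory":
        sel = [t for t in trees if not t.canopy_flag]
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    return float(sum(t.basal_area for t in sel) / area_ha)


def canopy_cover(claims: ClaimMap) -> float:
    """Fraction of the forest floor under >= 1 potential crown projection.

    Uses the maximal (allometric) crown discs: realized crowns tile the
    canopy without overlap, so their union is bounded away from 1 by the
    interstitial pores of any disc packing; the potential projections
    overlap and close over them, which is what a closed canopy means.
    """
    return float(claims.max_covered_any.mean())


def crown_symmetry(tree: Tree) -> float:
    """min/max sector radius: 1 for a perfectly symmetric crown."""
    r = tree.sector_radii
    mx = float(r.max())
    if mx <= 0:
        raise ValueError("all-zero sector radii have no symmetry ratio")
    return float(r.min() / mx)


def stand_crown_symmetry(trees: list[Tree]) -> float:
    """Basal-area-weighted mean crown symmetry over canopy trees (NaN if none)."""
    sel = [t for t in trees if t.canopy_flag and t.sector_radii.max() > 0]
    if not sel:
        return float("nan")
    w = np.array([t.basal_area for t in sel])
    sym = np.array([crown_symmetry(t) for t in sel])
    return float(np.sum(sym * w) / np.sum(w))


def annual_record(stand: StandState, claims: ClaimMap, tolerant_cut: float = 0.5) -> dict:
    """One tidy row of stand summaries for the current year.

    Species with tolerance rank >= ``tolerant_cut`` count as shade
    tolerant in the tolerant/intolerant basal-area split (the split is
    exhaustive, so the two add up to the total).
    """
    trees = stand.trees
    area = stand.area_ha
    tol = [t for t in trees if t.species.tol_rank >= tolerant_cut]
    intol = [t for t in trees if t.species.tol_rank < tolerant_cut]
    rec = {
        "year": stand.year,
        "n_trees_per_ha": len(trees) / area,
        "sti": shade_tolerance_index(trees),
        "basal_area_total": basal_area(trees, area, "all"),
        "basal_area_canopy": basal_area(trees, area, "canopy"),
        "basal_area_understory": basal_area(trees, area, "understory"),
        "ba_shade_tolerant": basal_area(tol, area, "all"),
        "ba_shade_intolerant": basal_area(intol, area, "all"),
        "canopy_cover": canopy_cover(claims),
        "mean_age": float(np.mean([t.age for t in trees])) if trees else float("nan"),
        "crown_symmetry": stand_crown_symmetry(trees),
    }
    for name in sorted({t.species.name for t in trees}):
        sub = [t for t in trees if t.species.name == name]
        rec[f"ba_{name}"] = basal_area(sub, area, "all")
    return rec


def records_to_frame(records: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(records)


def equilibrium_summary(records: pd.DataFrame, T: int | None = None) -> pd.DataFrame:
    """Mean and sd of every metric over the second half of the run.

    Uses years in (T/2, T]; ``T`` defaults to the last recorded year.
    Raises when the series is shorter than ``T``.
    """
    if "year" not in records.columns:
        raise ValueError("records must carry a 'year' column")
    if T is None:
        T = int(records["year"].max())
    if records["year"].max() < T:
        raise ValueError(f"series ends before year {T}")
    half = records[(records["year"] > T / 2) & (records["year"] <= T)]
    num = half.drop(columns=["year"]).select_dtypes("number")
    return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})
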