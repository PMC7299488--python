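"""Disclosure-controlled release of household aggregates and validation.

Household-level data are disclosive: grouping individuals for whom much
is known raises re-identification risk, so only aggregated counts with
small cells suppressed leave the safe setting.  Aggregates are
point-prevalence tables — households counted at one date, banded by size
(1/2/3/4/5+ mirroring census tables) per area at a chosen geography
level — and are validated against a census-style reference: each cell's
observed count is compared with a continuity-corrected normal
approximation to the binomial confidence interval implied by the
reference's band proportion, at the 95% level by default.  Per-cell,
per-area and global verdicts are all reported; the choice of roll-up is
left to the reader.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .household import snapshot
from .spine.geography import area_parents

__all__ = ["aggregate_households", "suppress", "validate_aggregates", "ValidationSummary"]

SIZE_BANDS = ["1", "2", "3", "4", "5+"]
LEVELS = ("LSOA", "MSOA", "LA")


def size_band(n: int | np.ndarray) -> np.ndarray:
    n = np.asarray(n)
    return np.where(n >= 5, "5+", n.astype(str))


def aggregate_households(
    episodes: pd.DataFrame,
    dwellings: pd.DataFrame,
    geography: pd.DataFrame,
    at,
    level: str = "LSOA",
    exclude_dwellings=None,
) -> pd.DataFrame:
    """Point-prevalence household counts per area and size band.

    Households present at ``at`` are counted once at their dwelling's
    area of the requested level; every area of that level appears with
    all five bands (zero counts are structural).  ``exclude_dwellings``
    optionally removes communal dwellings from the statistics.

    The per-band counts of an MSOA equal the sum over its LSOAs: the
    aggregation is additive up the hierarchy.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    snap = snapshot(episodes, at)
    if exclude_dwellings is not None:
        snap = snap.loc[~snap["dwelling_id"].isin(set(exclude_dwellings))]

    lut = dwellings.set_index("dwelling_id")["lsoa_code"]
    lsoa = lut.reindex(snap["dwelling_id"]).to_numpy()
    parents = area_parents(geography).set_index("lsoa_code")
    if level == "LSOA":
        area = lsoa
        all_areas = parents.index.to_numpy()
    elif level == "MSOA":
        area = parents["msoa_code"].reindex(lsoa).to_numpy()
        all_areas = parents["msoa_code"].unique()
    else:
        area = parents["la_code"].reindex(lsoa).to_numpy()
        all_areas = parents["la_code"].unique()

    cells = (
        pd.DataFrame({"area_code": area, "size_band": size_band(snap["n_occupants"])})
        .value_counts()
        .rename("count")
    )
    full = pd.MultiIndex.from_product(
        [np.sort(all_areas), SIZE_BANDS], names=["area_code", "size_band"]
    )
    out = cells.reindex(full, fill_value=0).reset_index()
    out["level"] = level
    out["suppressed"] = False
    return out[["area_code", "level", "size_band", "count", "suppressed"]]


def suppress(agg: pd.DataFrame, threshold: int = 5) -> pd.DataFrame:
    """Mark small cells for suppression (0 < count < threshold).

    Zero cells are structural and stay visible; suppressed counts must be
    withheld from any written output (the CSV writer blanks them).
    Unsuppressed values are never altered.  Complementary (secondary)
    suppression is not applied.
    """
    if threshold < 2:
        raise ValueError("suppression threshold must be >= 2")
    out = agg.copy()
    out["suppressed"] = (out["count"] > 0) & (out["count"] < threshold)
    return out


@dataclass
class ValidationSummary:
    n_cells: int
    n_within: int
    proportion_within: float
    n_unmatched: int
    per_area: pd.DataFrame  # area_code, n_cells, n_within, all_within


def validate_aggregates(
    agg: pd.DataFrame,
    reference: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, ValidationSummary]:
    """Compare aggregates against a census-style reference at the 1-alpha level.

    For each (area, band) cell the reference's band proportion
    p = expected / area-total is treated as a binomial probability over
    the area's reference total N; the observed count is judged against
    the continuity-corrected normal interval
    ``N p ± (z sqrt(N p (1-p)) + 0.5)``.  A cell with no reference
    counterpart is reported as unmatchable and excluded from the summary
    denominator.  The summary gives the global proportion of cells
    within their interval and a per-area roll-up; "within the 95%
    confidence level" can then be read per cell, per area or globally.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2)
    ref = reference.rename(columns={"count": "expected"})
    ref_tot = ref.groupby("area_code")["expected"].sum().rename("area_total")
    merged = agg.rename(columns={"count": "observed"}).merge(
        ref[["area_code", "size_band", "expected"]],
        on=["area_code", "size_band"],
        how="left",
    )
    merged = merged.merge(ref_tot, on="area_code", how="left")
    matched = merged["expected"].notna() & (merged["area_total"] > 0)

    p = (merged["expected"] / merged["area_total"]).to_numpy()
    n = merged["area_total"].to_numpy()
    center = n * p
    half = z * np.sqrt(n * p * (1 - p)) + 0.5
    merged["ci_low"] = np.maximum(center - half, 0.0)
    merged["ci_high"] = center + half
    merged["within_ci"] = (
        (merged["observed"] >= merged["ci_low"])
        & (merged["observed"] <= merged["ci_high"])
        & matched
    )
    merged.loc[~matched, ["ci_low", "ci_high"]] = np.nan
    merged["matched"] = matched

    verdicts = merged[
        ["area_code", "level", "size_band", "observed", "expected",
         "ci_low", "ci_high", "within_ci", "matched"]
    ]
    m = verdicts.loc[verdicts["matched"]]
    per_area = (
        m.groupby("area_code")
        .agg(n_cells=("within_ci", "size"), n_within=("within_ci", "sum"))
        .reset_index()
    )
    per_area["all_within"] = per_area["n_within"] == per_area["n_cells"]
    summary = ValidationSummary(
        n_cells=len(m),
        n_within=int(m["within_ci"].sum()),
        proportion_within=float(m["within_ci"].mean()) if len(m) else float("nan"),
        n_unmatched=int((~verdicts["matched"]).sum()),
        per_area=per_area,
    )
    return verdicts, summary
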