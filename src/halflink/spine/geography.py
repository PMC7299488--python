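"""Synthetic four-level census geography (OA < LSOA < MSOA < LA).

Generates an area hierarchy honouring the structural rules a preset
encodes: every OA has an LSOA parent, every LSOA an MSOA parent, every
MSOA an LA parent; LSOAs contain 4-6 OAs and MSOAs 4-5 LSOAs under the
definitional presets.  Planar centroids (km, synthetic) support
family-distance computations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .presets import SpinePreset

__all__ = ["generate_geography"]

GEOGRAPHY_COLUMNS = ["area_code", "level", "parent_code", "centroid_x", "centroid_y"]


def _partition(n: int, lo: int, hi: int, rng: np.random.Generator) -> np.ndarray:
    """Split n into parts each within [lo, hi], sizes as even as possible.

    Used to decide how many child areas each parent gets when the total
    child count is fixed (e.g. 1,909 LSOAs over 22 LAs, then LSOAs into
    MSOAs of 4-5).
    """
    if n < lo:
        # a single undersized part is unavoidable for tiny totals
        return np.array([n])
    m_min = int(np.ceil(n / hi))
    m_max = n // lo
    if m_min > m_max:
        m = m_min
    else:
        m = int(rng.integers(m_min, m_max + 1))
    base, rem = divmod(n, m)
    sizes = np.full(m, base)
    sizes[:rem] += 1
    return sizes


def generate_geography(
    preset: SpinePreset, seed: int, n_lsoa: int | None = None
) -> pd.DataFrame:
    """Generate the four-level area table for a preset.

    Parameters
    ----------
    preset
        Spine preset; ``preset.n_lsoa_total`` (or the ``n_lsoa`` override)
        fixes the exact LSOA count, otherwise counts are drawn from the
        preset's per-level ranges.
    seed
        Seed for the dedicated geography random stream; the same
        (preset, seed) always yields an identical table.
    n_lsoa
        Optional exact LSOA total overriding the preset (used to scale a
        definitional preset up or down without touching its size rules).

    Returns
    -------
    DataFrame with columns area_code, level, parent_code, centroid_x,
    centroid_y; one row per area at every level.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    n_lsoa_total = n_lsoa if n_lsoa is not None else preset.n_lsoa_total

    rows: list[tuple] = []
    la_codes = [f"LA{i + 1:03d}" for i in range(preset.n_la)]
    # LAs on a coarse grid, ~60 km apart
    grid = int(np.ceil(np.sqrt(preset.n_la)))
    for i, la in enumerate(la_codes):
        rows.append((la, "LA", None, 60.0 * (i % grid), 60.0 * (i // grid)))

    if n_lsoa_total is not None:
        base, rem = divmod(n_lsoa_total, preset.n_la)
        lsoa_per_la = np.full(preset.n_la, base)
        lsoa_per_la[:rem] += 1
        msoa_sizes_per_la = [
            _partition(int(n), *preset.lsoa_per_msoa, rng) for n in lsoa_per_la
        ]
    else:
        lo, hi = preset.n_msoa_per_la
        n_msoa_la = rng.integers(lo, hi + 1, size=preset.n_la)
        msoa_sizes_per_la = [
            rng.integers(preset.lsoa_per_msoa[0], preset.lsoa_per_msoa[1] + 1, size=int(m))
            for m in n_msoa_la
        ]

    msoa_i = lsoa_i = oa_i = 0
    for la_idx, la in enumerate(la_codes):
        la_x, la_y = rows[la_idx][3], rows[la_idx][4]
        for m_size in msoa_sizes_per_la[la_idx]:
            msoa_i += 1
            msoa = f"M{msoa_i:05d}"
            mx, my = la_x + rng.uniform(-20, 20), la_y + rng.uniform(-20, 20)
            rows.append((msoa, "MSOA", la, mx, my))
            for _ in range(int(m_size)):
                lsoa_i += 1
                lsoa = f"L{lsoa_i:05d}"
                lx, ly = mx + rng.uniform(-5, 5), my + rng.uniform(-5, 5)
                rows.append((lsoa, "LSOA", msoa, lx, ly))
                n_oa = int(rng.integers(preset.oa_per_lsoa[0], preset.oa_per_lsoa[1] + 1))
                for _ in range(n_oa):
                    oa_i += 1
                    rows.append(
                        (f"O{oa_i:06d}", "OA", lsoa,
                         lx + rng.uniform(-1.5, 1.5), ly + rng.uniform(-1.5, 1.5))
                    )

    df = pd.DataFrame(rows, columns=GEOGRAPHY_COLUMNS)
    df["centroid_x"] = df["centroid_x"].round(4)
    df["centroid_y"] = df["centroid_y"].round(4)
    return df


def area_parents(geography: pd.DataFrame) -> pd.DataFrame:
    """Map every LSOA to its MSOA and LA (wide lookup table)."""
    lsoa = geography.loc[geography["level"] == "LSOA", ["area_code", "parent_code"]]
    lsoa = lsoa.rename(columns={"area_code": "lsoa_code", "parent_code": "msoa_code"})
    msoa = geography.loc[geography["level"] == "MSOA", ["area_code", "parent_code"]]
    msoa = msoa.rename(columns={"area_code": "msoa_code", "parent_code": "la_code"})
    return lsoa.merge(msoa, on="msoa_code", how="left")
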