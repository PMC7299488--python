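"""Tabular I/O: CSV schemas shared by all pipeline stages.

All tables are RFC 4180 CSV, UTF-8, ISO-8601 dates, empty field =
missing.  The one non-scalar column is the episode occupant list, which
is serialised pipe-delimited inside its CSV cell.  Write-then-read is
lossless for every table (dates, missing values, flag strings).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_persons", "read_dwellings", "read_spells", "read_geography",
    "read_episodes", "read_reference", "write_table", "write_episodes",
    "write_aggregates", "file_sha256", "write_manifest",
]

_DATE_COLS = {
    "persons": ["birth_date", "death_date"],
    "spells": ["start", "end"],
    "episodes": ["start", "end"],
}


class SchemaError(ValueError):
    """An input file does not conform to its documented schema."""


def _require(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def _parse_dates(df: pd.DataFrame, cols: list[str], name: str) -> pd.DataFrame:
    for c in cols:
        try:
            df[c] = pd.to_datetime(df[c], format="ISO8601")
        except (ValueError, TypeError) as exc:
            bad = df[c][pd.to_datetime(df[c], format="ISO8601", errors="coerce").isna()
                        & df[c].notna()]
            row = int(bad.index[0]) if len(bad) else "?"
            raise SchemaError(
                f"{name}: invalid ISO date in column {c!r} at row {row}"
            ) from exc
    return df


def read_persons(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str, "maternal_id": str})
    _require(df, ["person_id", "sex", "birth_date"], "persons")
    if "death_date" not in df.columns:
        df["death_date"] = pd.NaT
    if "maternal_id" not in df.columns:
        df["maternal_id"] = None
    return _parse_dates(df, _DATE_COLS["persons"], "persons")


def read_dwellings(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require(df, ["dwelling_id", "lsoa_code"], "dwellings")
    for c in ("parent_id", "oa_code"):
        if c not in df.columns:
            df[c] = None
    if "status" not in df.columns:
        df["status"] = "active"
    return df


def read_spells(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str, "dwelling_id": str})
    _require(df, ["person_id", "dwelling_id", "start"], "spells")
    if "end" not in df.columns:
        df["end"] = pd.NaT
    return _parse_dates(df, _DATE_COLS["spells"], "spells")


def read_geography(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"area_code": str, "parent_code": str})
    _require(df, ["area_code", "level", "parent_code"], "geography")
    return df


def read_reference(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"area_code": str, "size_band": str})
    _require(df, ["area_code", "level", "size_band", "count"], "reference")
    return df


def read_episodes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"dwelling_id": str, "half_base": str})
    _require(df, ["dwelling_id", "start", "end", "occupants"], "episodes")
    df = _parse_dates(df, _DATE_COLS["episodes"], "episodes")
    df["occupants"] = df["occupants"].map(
        lambda s: tuple(s.split("|")) if isinstance(s, str) and s else ()
    )
    df["n_occupants"] = df["occupants"].map(len)
    if "flags" in df.columns:
        df["flags"] = df["flags"].fillna("")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[c]):
            out[c] = out[c].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, lineterminator="\n")


def write_episodes(episodes: pd.DataFrame, path) -> None:
    out = episodes.copy()
    out["occupants"] = out["occupants"].map("|".join)
    write_table(out, path)


def write_aggregates(agg: pd.DataFrame, path) -> None:
    """Suppressed cell counts are withheld (blank) on disk."""
    out = agg.copy()
    out["count"] = out["count"].astype(object)
    out.loc[out["suppressed"], "count"] = None
    write_table(out, path)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, inputs: dict, config: dict, row_counts: dict) -> None:
    from . import __version__

    payload = {
        "tool": {"name": "halflink", "version": __version__},
        "inputs": {k: file_sha256(v) for k, v in inputs.items()},
        "config": config,
        "row_counts": row_counts,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as f:
        json.dump(payload, f, indent=2, sort_keys=True)
        f.write("\n")
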