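"""Construction of versioned household units (HALFs) from residence spells.

A household is "one person living alone or a group of people (not
necessarily related) living at the same address", the address being a
de-identified dwelling identifier.  Because individual residents arrive
and leave at different times, each dwelling's timeline is partitioned
into *episodes* — maximal intervals with a constant, non-empty occupant
set — and consecutive episodes that share at least one occupant with no
vacancy in between carry the same household identifier with an
incremented version (1.1, 1.2, ... 1.n).  The version count doubles as a
stability measure.

All intervals are half-open ``[start, end)`` at day resolution, so a
move-out day equals the next move-in day without double counting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "clean_spells",
    "build_episodes",
    "assign_half_ids",
    "snapshot",
    "stability",
    "episode_membership",
]

logger = logging.getLogger(__name__)

_DAYS_PER_YEAR = 365.25

FLAG_TRUNCATED = "truncated_overlap"
FLAG_IMPUTED_END = "imputed_end"
FLAG_CHILD_FIRST = "child_first"
FLAG_SINGLE = "single_person"
FLAG_MINORS_ONLY = "minors_only"


def _join_flags(*masks_and_names: tuple[np.ndarray, str]) -> np.ndarray:
    """Combine boolean flag masks into a ';'-joined string column."""
    n = len(masks_and_names[0][0])
    parts = np.full(n, "", dtype=object)
    for mask, name in masks_and_names:
        add = np.where(mask, name, "")
        sep = np.where((parts != "") & (add != ""), ";", "")
        parts = np.char.add(np.char.add(parts.astype(str), sep), add)
    return parts


def clean_spells(
    raw: pd.DataFrame,
    censor_date,
    persons: pd.DataFrame | None = None,
    adult_age: int = 18,
) -> pd.DataFrame:
    """Resolve registration defects so each person occupies one dwelling per day.

    Rules, applied per person on spells sorted by start date:

    - a spell overlapping a later-starting spell is truncated to end at
      that later start (the most recent registration is presumed
      current); ties on identical starts keep the spell at the
      lexicographically larger dwelling id — a deterministic but
      arbitrary choice;
    - an open end (never deregistered, or simply ongoing) becomes
      ``censor_date`` and is flagged ``imputed_end``; recorded ends past
      the censor date are capped to it;
    - zero-length spells are dropped; spells starting after the censor
      date are dropped with a logged warning (not an error);
    - when a ``persons`` table is supplied, a minor's spell that starts
      before any adult has arrived at the dwelling is flagged
      ``child_first`` (children registered before their parents).

    Returns a table with columns person_id, dwelling_id, start, end,
    flags; per person the intervals are pairwise disjoint.  The function
    is idempotent: cleaning an already-clean table changes nothing.
    """
    censor = pd.Timestamp(censor_date)
    df = raw.loc[:, ["person_id", "dwelling_id", "start", "end"]].copy()
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])

    late = df["start"] > censor
    if late.any():
        logger.warning(
            "dropping %d spell(s) starting after the censor date %s",
            int(late.sum()), censor.date(),
        )
        df = df.loc[~late]

    df = df.sort_values(
        ["person_id", "start", "dwelling_id"], kind="stable", ignore_index=True
    )

    imputed = df["end"].isna()
    df.loc[imputed, "end"] = censor
    df.loc[df["end"] > censor, "end"] = censor

    nxt_start = df["start"].shift(-1)
    same_person = df["person_id"].shift(-1) == df["person_id"]
    cap = df["end"].copy()
    capped = same_person & (nxt_start < df["end"])
    cap[capped] = nxt_start[capped]
    truncated = capped & (cap < df["end"])
    df["end"] = cap

    df["flags"] = _join_flags(
        (truncated.to_numpy(), FLAG_TRUNCATED),
        (imputed.to_numpy(), FLAG_IMPUTED_END),
    )
    df = df.loc[df["start"] < df["end"]].reset_index(drop=True)

    if persons is not None and len(df):
        birth = persons.set_index("person_id")["birth_date"]
        b = pd.to_datetime(birth.reindex(df["person_id"]).to_numpy())
        age_days = (df["start"] - b).dt.days
        minor = age_days < adult_age * _DAYS_PER_YEAR
        adult_starts = (
            df.loc[~minor].groupby("dwelling_id")["start"].min()
        )
        first_adult = adult_starts.reindex(df["dwelling_id"]).to_numpy()
        child_first = (
            minor.to_numpy()
            & ~pd.isna(first_adult)
            & (df["start"].to_numpy() < first_adult)
        )
        if child_first.any():
            flags = df["flags"].to_numpy(dtype=object)
            sep = np.where(flags[child_first] != "", ";", "")
            flags[child_first] = np.char.add(
                np.char.add(flags[child_first].astype(str), sep), FLAG_CHILD_FIRST
            )
            df["flags"] = flags
    return df


def build_episodes(
    spells: pd.DataFrame,
    persons: pd.DataFrame | None = None,
    adult_age: int = 18,
) -> pd.DataFrame:
    """Partition each dwelling's timeline into constant-occupancy episodes.

    Event points are all spell starts and ends at the dwelling; between
    consecutive event points the occupant set is constant.  One episode
    is emitted per maximal interval with a constant non-empty occupant
    set (no episode covers a vacancy).  Episodes with one occupant are
    flagged ``single_person``; with a ``persons`` table, episodes whose
    occupants are all younger than ``adult_age`` at the episode start are
    flagged ``minors_only`` — the child-registered-first signature.

    Returns episodes ordered per dwelling with columns dwelling_id,
    start, end, occupants (sorted tuple of person ids), n_occupants,
    flags.  Half ids are assigned separately by :func:`assign_half_ids`.
    """
    cols = ["dwelling_id", "start", "end", "occupants", "n_occupants", "flags"]
    if len(spells) == 0:
        return pd.DataFrame(columns=cols)

    df = spells.reset_index(drop=True)
    ev = pd.concat(
        [
            df[["dwelling_id", "start"]].rename(columns={"start": "date"}),
            df[["dwelling_id", "end"]].rename(columns={"end": "date"}),
        ],
        ignore_index=True,
    ).drop_duplicates()
    ev = ev.sort_values(["dwelling_id", "date"], kind="stable", ignore_index=True)
    ev["k"] = ev.groupby("dwelling_id", sort=False).cumcount()

    lut = pd.Series(
        ev["k"].to_numpy(), index=pd.MultiIndex.from_frame(ev[["dwelling_id", "date"]])
    )
    s_k = lut.reindex(
        pd.MultiIndex.from_frame(df[["dwelling_id", "start"]])
    ).to_numpy()
    e_k = lut.reindex(
        pd.MultiIndex.from_frame(df[["dwelling_id", "end"]])
    ).to_numpy()

    reps = (e_k - s_k).astype(np.int64)
    rows = np.repeat(np.arange(len(df)), reps)
    offs = np.arange(reps.sum()) - np.repeat(
        np.concatenate([[0], np.cumsum(reps)[:-1]]), reps
    )
    membership = pd.DataFrame(
        {
            "dwelling_id": df["dwelling_id"].to_numpy()[rows],
            "k": np.repeat(s_k, reps) + offs,
            "person_id": df["person_id"].to_numpy()[rows],
        }
    ).sort_values(["dwelling_id", "k", "person_id"], kind="stable", ignore_index=True)

    grouped = (
        membership.groupby(["dwelling_id", "k"], sort=False)["person_id"]
        .agg(tuple)
        .reset_index(name="occupants")
    )
    date_lut = pd.Series(
        ev["date"].to_numpy(), index=pd.MultiIndex.from_frame(ev[["dwelling_id", "k"]])
    )
    key = pd.MultiIndex.from_frame(grouped[["dwelling_id", "k"]])
    grouped["start"] = pd.to_datetime(date_lut.reindex(key).to_numpy())
    key_next = pd.MultiIndex.from_arrays(
        [grouped["dwelling_id"], grouped["k"] + 1]
    )
    grouped["end"] = pd.to_datetime(date_lut.reindex(key_next).to_numpy())

    # merge contiguous intervals whose occupant set did not change
    same = (
        (grouped["dwelling_id"] == grouped["dwelling_id"].shift())
        & (grouped["k"] == grouped["k"].shift() + 1)
        & (grouped["occupants"] == grouped["occupants"].shift())
    )
    epi_id = (~same).cumsum()
    episodes = (
        grouped.groupby(epi_id, sort=False)
        .agg(
            dwelling_id=("dwelling_id", "first"),
            start=("start", "first"),
            end=("end", "last"),
            occupants=("occupants", "first"),
        )
        .reset_index(drop=True)
    )
    episodes["n_occupants"] = episodes["occupants"].map(len)

    single = (episodes["n_occupants"] == 1).to_numpy()
    if persons is not None:
        birth = persons.set_index("person_id")["birth_date"]
        exploded = episodes["occupants"].explode()
        oldest_birth = (
            pd.to_datetime(birth.reindex(exploded).to_numpy())
            .to_series(index=exploded.index)
            .groupby(level=0)
            .min()
        )
        cutoff = episodes["start"] - pd.to_timedelta(
            int(adult_age * _DAYS_PER_YEAR), unit="D"
        )
        minors_only = (oldest_birth > cutoff).to_numpy()
    else:
        minors_only = np.zeros(len(episodes), dtype=bool)
    episodes["flags"] = _join_flags((single, FLAG_SINGLE), (minors_only, FLAG_MINORS_ONLY))
    return episodes[cols]


def assign_half_ids(
    episodes: pd.DataFrame, allow_gap_days: int = 0
) -> pd.DataFrame:
    """Assign versioned household identifiers to episodes.

    A consecutive pair of episodes at one dwelling continues the same
    household — same ``half_base``, version incremented — when the gap
    between them is at most ``allow_gap_days`` (default 0: temporally
    adjacent) *and* at least one occupant is shared.  A vacated dwelling
    therefore starts a fresh household even if the same people return,
    unless ``allow_gap_days`` is raised.  ``half_base`` values are
    globally unique across dwellings.
    """
    df = episodes.sort_values(
        ["dwelling_id", "start"], kind="stable", ignore_index=True
    ).copy()
    if len(df) == 0:
        df["half_base"] = pd.Series(dtype=object)
        df["half_version"] = pd.Series(dtype=np.int64)
        return df

    same_dw = (df["dwelling_id"] == df["dwelling_id"].shift()).to_numpy()
    gap = (df["start"] - df["end"].shift()).dt.days.to_numpy()
    gap_ok = same_dw & (gap <= allow_gap_days) & (gap >= 0)
    occ = df["occupants"].to_numpy()
    shared = np.zeros(len(df), dtype=bool)
    idx = np.flatnonzero(gap_ok)
    for i in idx:
        shared[i] = not set(occ[i]).isdisjoint(occ[i - 1])
    continues = gap_ok & shared
    base_num = np.cumsum(~continues)
    df["half_base"] = np.char.add("H", np.char.zfill(base_num.astype(str), 8))
    df["half_version"] = (
        df.groupby("half_base", sort=False).cumcount().to_numpy() + 1
    )
    return df


def snapshot(episodes: pd.DataFrame, at) -> pd.DataFrame:
    """Cross-sectional view: the episodes whose interval contains ``at``.

    Each person appears in at most one returned household (episodes at a
    dwelling are disjoint and cleaned spells put a person in one dwelling
    per day).
    """
    at = pd.Timestamp(at)
    sel = episodes.loc[(episodes["start"] <= at) & (at < episodes["end"])]
    cols = [c for c in ("half_base", "half_version") if c in sel.columns]
    return sel[cols + ["dwelling_id", "occupants", "n_occupants"]].reset_index(drop=True)


def stability(episodes: pd.DataFrame) -> pd.DataFrame:
    """Per-household stability metrics from its version sequence.

    ``composition_changes_per_year`` is (n_versions - 1) over the
    household's total duration in years; ``founder_retention`` is the
    fraction of version-1 occupants still present in the final version.
    Durations are censored at the observation end, so rates for ongoing
    households are computed over the observed span.
    """
    if "half_base" not in episodes.columns:
        raise ValueError("assign_half_ids must run before stability")
    df = episodes.sort_values(["half_base", "half_version"], kind="stable")
    g = df.groupby("half_base", sort=True)
    first_occ = g["occupants"].first()
    last_occ = g["occupants"].last()
    retention = np.array(
        [len(set(a) & set(b)) / len(a) for a, b in zip(first_occ, last_occ)]
    )
    out = pd.DataFrame(
        {
            "half_base": first_occ.index,
            "n_versions": g.size().to_numpy(),
            "total_duration": (g["end"].last() - g["start"].first()).dt.days.to_numpy(),
            "mean_episode_duration": g.apply(
                lambda d: float((d["end"] - d["start"]).dt.days.mean()),
                include_groups=False,
            ).to_numpy(),
            "founder_retention": retention,
        }
    )
    out["composition_changes_per_year"] = (out["n_versions"] - 1) / (
        out["total_duration"] / _DAYS_PER_YEAR
    )
    return out.reset_index(drop=True)


def episode_membership(episodes: pd.DataFrame) -> pd.DataFrame:
    """Long (episode_row, person_id) membership table for joined analyses."""
    out = episodes.reset_index()[["index", "dwelling_id", "start", "end", "occupants"]]
    out = out.rename(columns={"index": "episode_row"})
    out = out.explode("occupants").rename(columns={"occupants": "person_id"})
    return out.reset_index(drop=True)
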