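"""Household lineage and familial-relationship inference.

Households that relocate together can be followed across dwellings:
every group of people who end spells at one dwelling and begin spells at
another within a short window is a *co-move*, and chaining household
identifiers through co-moves yields a lineage.  A lineage whose members
have moved together repeatedly (two or more co-moves by default) is
flagged as a probable family.

Recorded maternal identifiers (the mother's id on a child's birth
record) give biological mother-child links; an adult male resident in
the child's household from or before the child's birth is emitted as a
*candidate* father — a significant relationship, never an assertion of
paternity.  Sibling and maternal-grandmother links follow from chaining
maternal identifiers.  For non-coresident pairs the planar distance
between LSOA centroids is attached as a family-support indicator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .household import episode_membership

__all__ = [
    "detect_comoves",
    "link_lineages",
    "link_mother_child",
    "infer_candidate_father",
    "link_extended_family",
    "family_distance",
    "residence_at",
]

logger = logging.getLogger(__name__)

_DAYS_PER_YEAR = 365.25


def detect_comoves(
    spells: pd.DataFrame,
    persons: pd.DataFrame | None = None,
    window_days: int = 28,
    min_movers: int = 2,
) -> pd.DataFrame:
    """Group individual moves into co-move events.

    A move is an adjacent pair of one person's cleaned spells from one
    dwelling to another with at most ``window_days`` between the old
    spell's end and the new spell's start.  Moves over the same
    (from, to) dwelling pair whose departure dates fall within
    ``window_days`` of the event's first departure form one event; events
    with fewer than ``min_movers`` members are discarded.  Each person
    belongs to at most one event per departure.

    Returns columns from_dwelling, to_dwelling, movers (sorted tuple),
    n_movers, depart_date, arrive_date.
    """
    if window_days < 0:
        raise ValueError("window_days must be non-negative")
    df = spells.sort_values(["person_id", "start"], kind="stable", ignore_index=True)
    nxt = df.shift(-1)
    is_move = (
        (nxt["person_id"] == df["person_id"])
        & (nxt["dwelling_id"] != df["dwelling_id"])
        & ((nxt["start"] - df["end"]).dt.days.between(0, window_days))
    )
    moves = pd.DataFrame(
        {
            "person_id": df["person_id"][is_move].to_numpy(),
            "from_dwelling": df["dwelling_id"][is_move].to_numpy(),
            "to_dwelling": nxt["dwelling_id"][is_move].to_numpy(),
            "depart": df["end"][is_move].to_numpy(),
            "arrive": nxt["start"][is_move].to_numpy(),
        }
    ).sort_values(["from_dwelling", "to_dwelling", "depart"], kind="stable",
                  ignore_index=True)
    if len(moves) == 0:
        return pd.DataFrame(
            columns=["from_dwelling", "to_dwelling", "movers", "n_movers",
                     "depart_date", "arrive_date"]
        )

    # greedy windowed clustering of departures per (from, to) pair
    new_pair = (
        (moves["from_dwelling"] != moves["from_dwelling"].shift())
        | (moves["to_dwelling"] != moves["to_dwelling"].shift())
    ).to_numpy()
    depart = moves["depart"].to_numpy()
    arrive = moves["arrive"].to_numpy()
    win = np.timedelta64(window_days, "D").astype("timedelta64[ns]")
    cluster = np.empty(len(moves), dtype=np.int64)
    cid = -1
    anchor = depart[0]
    for i in range(len(moves)):
        if (
            new_pair[i]
            or depart[i] - anchor > win
            or arrive[i] - anchor > win
        ):
            cid += 1
            anchor = depart[i]
        cluster[i] = cid
    moves["cluster"] = cluster

    events = (
        moves.groupby("cluster", sort=True)
        .agg(
            from_dwelling=("from_dwelling", "first"),
            to_dwelling=("to_dwelling", "first"),
            movers=("person_id", lambda s: tuple(sorted(s))),
            depart_date=("depart", "min"),
            arrive_date=("arrive", "max"),
        )
        .reset_index(drop=True)
    )
    events["n_movers"] = events["movers"].map(len)
    events = events.loc[events["n_movers"] >= min_movers].reset_index(drop=True)
    return events[["from_dwelling", "to_dwelling", "movers", "n_movers",
                   "depart_date", "arrive_date"]]


def link_lineages(
    episodes: pd.DataFrame,
    comoves: pd.DataFrame,
    family_min_comoves: int = 2,
) -> pd.DataFrame:
    """Chain household identifiers through co-move events into lineages.

    A co-move links the household whose *final* episode at the origin
    dwelling contains all the movers (the household dissolved or left) to
    the household whose *first* episode at the destination contains them.
    Chains form lineages; every half_base belongs to exactly one lineage
    (never-moving households are singleton lineages).  ``family_flag`` is
    true when a lineage accumulated at least ``family_min_comoves``
    co-moves — "moving repeatedly together".

    Returns columns lineage_id, half_bases (time-ordered tuple),
    n_comoves, family_flag.
    """
    if "half_base" not in episodes.columns:
        raise ValueError("assign_half_ids must run before link_lineages")
    epi = episodes.reset_index(drop=True)
    is_last = ~epi.duplicated("half_base", keep="last")
    is_first = ~epi.duplicated("half_base", keep="first")

    edges: list[tuple[str, str]] = []
    last_by_dw = epi.loc[is_last].groupby("dwelling_id")
    first_by_dw = epi.loc[is_first].groupby("dwelling_id")
    last_map = {dw: g for dw, g in last_by_dw}
    first_map = {dw: g for dw, g in first_by_dw}
    for ev in comoves.itertuples(index=False):
        movers = set(ev.movers)
        src = None
        g = last_map.get(ev.from_dwelling)
        if g is not None:
            for row in g.itertuples(index=False):
                if (
                    ev.depart_date <= row.end <= ev.arrive_date
                    and movers.issubset(row.occupants)
                ):
                    src = row.half_base
                    break
        dst = None
        g = first_map.get(ev.to_dwelling)
        if g is not None:
            for row in g.itertuples(index=False):
                if (
                    abs((row.start - ev.arrive_date).days) <= 1
                    or row.start <= ev.arrive_date < row.end
                ) and movers.issubset(row.occupants):
                    dst = row.half_base
                    break
        if src is not None and dst is not None and src != dst:
            edges.append((src, dst))

    # union-find over half_bases
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    bases = epi["half_base"].drop_duplicates().tolist()
    for b in bases:
        parent.setdefault(b, b)
    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    comp: dict[str, list[str]] = {}
    for b in bases:
        comp.setdefault(find(b), []).append(b)
    n_edges: dict[str, int] = {}
    for a, b in edges:
        r = find(a)
        n_edges[r] = n_edges.get(r, 0) + 1

    first_start = epi.loc[is_first].set_index("half_base")["start"]
    rows = []
    for i, (root, members) in enumerate(
        sorted(comp.items(), key=lambda kv: min(kv[1]))
    ):
        ordered = tuple(sorted(members, key=lambda b: (first_start[b], b)))
        k = n_edges.get(root, 0)
        rows.append(
            {
                "lineage_id": f"F{i + 1:06d}",
                "half_bases": ordered,
                "n_comoves": k,
                "family_flag": k >= family_min_comoves,
            }
        )
    return pd.DataFrame(rows, columns=["lineage_id", "half_bases", "n_comoves",
                                       "family_flag"])


def _shared_episodes(episodes: pd.DataFrame, pairs: pd.DataFrame) -> pd.Series:
    """First shared-episode start for (person_a, person_b) pairs, NaT if never."""
    mem = episode_membership(episodes)
    a = mem.merge(pairs, left_on="person_id", right_on="person_a")
    b = a.merge(
        mem[["episode_row", "person_id"]],
        left_on=["episode_row", "person_b"],
        right_on=["episode_row", "person_id"],
        suffixes=("", "_b"),
    )
    if len(b) == 0:
        return pd.Series(pd.NaT, index=pd.MultiIndex.from_frame(
            pairs[["person_a", "person_b"]]))
    firsts = b.groupby(["person_a", "person_b"])["start"].min()
    return firsts.reindex(pd.MultiIndex.from_frame(pairs[["person_a", "person_b"]]))


def link_mother_child(
    persons: pd.DataFrame,
    episodes: pd.DataFrame,
    dwellings: pd.DataFrame | None = None,
    geography: pd.DataFrame | None = None,
    at=None,
) -> pd.DataFrame:
    """One mother-child link per person carrying a maternal identifier.

    ``coresident`` is true when mother and child ever share an episode;
    ``evidence_start`` is the first shared episode's start, or the
    child's birth date when they never coreside.  Links whose maternal id
    points at a missing or ineligible person (not female, or not at least
    12 years older) are skipped with a log message.  When dwelling and
    geography tables are supplied, non-coresident pairs get the planar
    LSOA-centroid distance at ``at`` (see :func:`family_distance`).
    """
    p = persons.set_index("person_id")
    kids = persons.loc[persons["maternal_id"].notna(),
                       ["person_id", "maternal_id", "birth_date"]].copy()
    mother = p.reindex(kids["maternal_id"])
    missing = mother["sex"].isna().to_numpy()
    not_female = (mother["sex"] != "F").to_numpy() & ~missing
    too_young = (
        (kids["birth_date"].to_numpy() - mother["birth_date"].to_numpy())
        < np.timedelta64(12 * 365, "D")
    ) & ~missing
    bad = missing | not_female | too_young
    if bad.any():
        logger.warning(
            "skipping %d maternal link(s): %d missing, %d not female, %d age gap < 12y",
            int(bad.sum()), int(missing.sum()), int(not_female.sum()),
            int(too_young.sum()),
        )
    kids = kids.loc[~bad]

    pairs = pd.DataFrame(
        {"person_a": kids["maternal_id"].to_numpy(),
         "person_b": kids["person_id"].to_numpy()}
    )
    shared = _shared_episodes(episodes, pairs).to_numpy()
    out = pd.DataFrame(
        {
            "link_type": "mother_child",
            "person_a": pairs["person_a"],
            "person_b": pairs["person_b"],
            "coresident": ~pd.isna(shared),
            "evidence_start": np.where(
                ~pd.isna(shared), shared, kids["birth_date"].to_numpy()
            ),
        }
    )
    out["evidence_start"] = pd.to_datetime(out["evidence_start"])
    out["distance_km"] = np.nan
    if dwellings is not None and geography is not None and (~out["coresident"]).any():
        when = pd.Timestamp(at) if at is not None else episodes["end"].max()
        non = out.loc[~out["coresident"]]
        out.loc[~out["coresident"], "distance_km"] = family_distance(
            non, episodes, dwellings, geography, at=when
        )
    return out


def infer_candidate_father(
    persons: pd.DataFrame,
    episodes: pd.DataFrame,
    mother_links: pd.DataFrame,
    adult_age: int = 18,
) -> pd.DataFrame:
    """Candidate-father links: adult males present from/before the birth.

    For each child with a maternal link, the household holding the child
    at birth is located; every male occupant aged at least ``adult_age``
    at the birth whose membership of that household began at or before
    the child's birth date is emitted as a ``candidate_father``.  All
    qualifying males are emitted (the relationship is significant, not
    necessarily biological); households with no adult male yield no
    links.
    """
    if "half_base" not in episodes.columns:
        raise ValueError("assign_half_ids must run before infer_candidate_father")
    p = persons.set_index("person_id")
    mem = episode_membership(episodes)
    mem = mem.merge(
        episodes.reset_index()[["index", "half_base"]],
        left_on="episode_row", right_on="index",
    )
    # first appearance of each person within each household chain
    first_seen = (
        mem.groupby(["half_base", "person_id"])["start"].min().rename("member_since")
    )

    kids = mother_links[["person_b"]].drop_duplicates().rename(
        columns={"person_b": "child_id"}
    )
    kids["birth_date"] = p["birth_date"].reindex(kids["child_id"]).to_numpy()

    child_mem = mem.merge(kids, left_on="person_id", right_on="child_id")
    at_birth = child_mem.loc[
        (child_mem["start"] <= child_mem["birth_date"])
        & (child_mem["birth_date"] < child_mem["end"])
    ]
    if len(at_birth) == 0:
        return pd.DataFrame(
            columns=["link_type", "person_a", "person_b", "coresident",
                     "evidence_start", "distance_km"]
        )

    cands = at_birth[["episode_row", "half_base", "child_id", "birth_date"]].merge(
        mem[["episode_row", "person_id"]], on="episode_row"
    )
    cands = cands.loc[cands["person_id"] != cands["child_id"]]
    cands["sex"] = p["sex"].reindex(cands["person_id"]).to_numpy()
    cands["cand_birth"] = p["birth_date"].reindex(cands["person_id"]).to_numpy()
    adult = (
        (cands["birth_date"] - cands["cand_birth"]).dt.days
        >= adult_age * _DAYS_PER_YEAR
    )
    cands = cands.loc[(cands["sex"] == "M") & adult]
    cands = cands.merge(
        first_seen.reset_index(),
        on=["half_base", "person_id"], how="left",
    )
    cands = cands.loc[cands["member_since"] <= cands["birth_date"]]
    out = pd.DataFrame(
        {
            "link_type": "candidate_father",
            "person_a": cands["person_id"].to_numpy(),
            "person_b": cands["child_id"].to_numpy(),
            "coresident": True,
            "evidence_start": cands["member_since"].to_numpy(),
            "distance_km": np.nan,
        }
    ).drop_duplicates(["person_a", "person_b"]).reset_index(drop=True)
    return out


def link_extended_family(persons: pd.DataFrame, episodes: pd.DataFrame) -> pd.DataFrame:
    """Sibling and maternal-grandmother links from chained maternal ids."""
    kids = persons.loc[persons["maternal_id"].notna(), ["person_id", "maternal_id"]]
    sib = kids.merge(kids, on="maternal_id", suffixes=("_a", "_b"))
    sib = sib.loc[sib["person_id_a"] < sib["person_id_b"]]
    p = persons.set_index("person_id")
    grand = kids.copy()
    grand["grandmother_id"] = p["maternal_id"].reindex(grand["maternal_id"]).to_numpy()
    grand = grand.loc[grand["grandmother_id"].notna()]

    pairs = pd.DataFrame(
        {
            "person_a": np.concatenate(
                [sib["person_id_a"].to_numpy(), grand["grandmother_id"].to_numpy()]
            ),
            "person_b": np.concatenate(
                [sib["person_id_b"].to_numpy(), grand["person_id"].to_numpy()]
            ),
        }
    ).drop_duplicates()
    if len(pairs) == 0:
        return pd.DataFrame(
            columns=["link_type", "person_a", "person_b", "coresident",
                     "evidence_start", "distance_km"]
        )
    shared = _shared_episodes(episodes, pairs).to_numpy()
    return pd.DataFrame(
        {
            "link_type": "extended_family",
            "person_a": pairs["person_a"].to_numpy(),
            "person_b": pairs["person_b"].to_numpy(),
            "coresident": ~pd.isna(shared),
            "evidence_start": pd.to_datetime(shared),
            "distance_km": np.nan,
        }
    )


def residence_at(episodes: pd.DataFrame, person_ids, at) -> pd.Series:
    """Dwelling of each person at date ``at`` (NaN when not resident)."""
    at = pd.Timestamp(at)
    snap = episodes.loc[(episodes["start"] <= at) & (at < episodes["end"])]
    mem = snap[["dwelling_id", "occupants"]].explode("occupants")
    lut = mem.set_index("occupants")["dwelling_id"]
    lut = lut[~lut.index.duplicated()]
    return lut.reindex(pd.Index(person_ids))


def family_distance(
    links: pd.DataFrame,
    episodes: pd.DataFrame,
    dwellings: pd.DataFrame,
    geography: pd.DataFrame,
    at,
) -> np.ndarray:
    """Planar distance (km) between two persons' LSOA centroids at ``at``.

    0 when both live in the same LSOA; missing when either person is not
    resident anywhere at ``at``.  Synthetic planar centroids stand in for
    real population-weighted centroids.
    """
    dw_lut = dwellings.set_index("dwelling_id")["lsoa_code"]
    geo = geography.loc[geography["level"] == "LSOA"].set_index("area_code")
    res_a = residence_at(episodes, links["person_a"], at)
    res_b = residence_at(episodes, links["person_b"], at)
    lsoa_a = dw_lut.reindex(res_a.to_numpy()).to_numpy()
    lsoa_b = dw_lut.reindex(res_b.to_numpy()).to_numpy()
    xa = geo["centroid_x"].reindex(lsoa_a).to_numpy()
    ya = geo["centroid_y"].reindex(lsoa_a).to_numpy()
    xb = geo["centroid_x"].reindex(lsoa_b).to_numpy()
    yb = geo["centroid_y"].reindex(lsoa_b).to_numpy()
    dist = np.hypot(xa - xb, ya - yb)
    same = pd.Series(lsoa_a) == pd.Series(lsoa_b)
    dist[same.to_numpy()] = 0.0
    return dist
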