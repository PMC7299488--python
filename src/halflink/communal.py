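"""Classification of dwellings into private and communal residence types.

Communal establishments — student halls of residence, residential care
homes, blocks of flats — leave distinctive occupancy signatures in
residence-spell data: halls hold large young cohorts that churn every
September; care homes hold small elderly populations whose exits
coincide with death; blocks of flats are parent dwellings with child
sub-dwellings.  A transparent rule cascade over per-dwelling occupancy
features assigns every dwelling exactly one type.  The thresholds are
declared heuristics held in configuration and evaluated against
generator ground truth; they are a starting point, not a validated
instrument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .household import episode_membership

__all__ = ["RuleConfig", "occupancy_features", "classify"]

_DAYS_PER_YEAR = 365.25


class RuleConfig(BaseModel):
    """Thresholds of the residence-type rule cascade (order: flats,
    student hall, care home, else private)."""

    flats_min_children: int = 2
    hall_min_occupants: int = 20
    hall_min_frac_18_25: float = 0.8
    hall_min_september_share: float = 0.5
    care_min_occupants: int = 10
    care_min_median_age: float = 70.0
    care_min_death_exit_share: float = 0.3


def occupancy_features(
    episodes: pd.DataFrame,
    persons: pd.DataFrame,
    dwellings: pd.DataFrame,
) -> pd.DataFrame:
    """Per-dwelling occupancy features over the full observation window.

    One row per dwelling ever occupied, with: peak simultaneous
    occupancy; annual turnover (departures per year over mean
    occupancy); median occupant age at the window midpoint; fraction of
    occupants aged 18-25 at first arrival; share of arrivals falling in
    September; share of exits coinciding with the occupant's death; and
    the count of child dwellings naming this dwelling as parent.
    """
    mem = episode_membership(episodes)
    # contiguous residence runs per (dwelling, person): a re-arrival after
    # a genuine absence counts as a new arrival
    mem = mem.sort_values(["dwelling_id", "person_id", "start"], kind="stable")
    new_run = (
        (mem["dwelling_id"] != mem["dwelling_id"].shift())
        | (mem["person_id"] != mem["person_id"].shift())
        | (mem["start"] != mem["end"].shift())
    )
    run_id = new_run.cumsum()
    runs = mem.groupby(run_id).agg(
        dwelling_id=("dwelling_id", "first"),
        person_id=("person_id", "first"),
        arrive=("start", "first"),
        depart=("end", "last"),
    )

    window_end = episodes["end"].max()
    mid = episodes["start"].min() + (window_end - episodes["start"].min()) / 2

    p = persons.set_index("person_id")
    runs["birth"] = p["birth_date"].reindex(runs["person_id"]).to_numpy()
    runs["death"] = p["death_date"].reindex(runs["person_id"]).to_numpy()
    runs["age_at_arrival"] = (runs["arrive"] - runs["birth"]).dt.days / _DAYS_PER_YEAR
    runs["age_mid"] = (mid - runs["birth"]).dt.days / _DAYS_PER_YEAR
    runs["is_18_25"] = runs["age_at_arrival"].between(18, 25)
    runs["sept"] = runs["arrive"].dt.month == 9
    ended = runs["depart"] < window_end
    runs["death_exit"] = (
        ended & ((runs["depart"] - runs["death"]).abs().dt.days <= 3)
    )
    runs["departed"] = ended
    runs["days"] = (runs["depart"] - runs["arrive"]).dt.days

    g = runs.groupby("dwelling_id")
    span_start = g["arrive"].min()
    span_end = g["depart"].max()
    span_years = ((span_end - span_start).dt.days / _DAYS_PER_YEAR).clip(lower=1 / 12)
    person_years = g["days"].sum() / _DAYS_PER_YEAR
    mean_occ = (person_years / span_years).clip(lower=1e-9)

    feats = pd.DataFrame(
        {
            "dwelling_id": span_start.index,
            "max_simultaneous": episodes.groupby("dwelling_id")["n_occupants"].max()
            .reindex(span_start.index).to_numpy(),
            "annual_turnover": (g["departed"].sum() / span_years / mean_occ).to_numpy(),
            "median_age": g["age_mid"].median().to_numpy(),
            "fraction_18_25": g["is_18_25"].mean().to_numpy(),
            "september_arrival_share": g["sept"].mean().to_numpy(),
            "death_exit_share": np.where(
                g["departed"].sum() > 0,
                g["death_exit"].sum() / g["departed"].sum().clip(lower=1),
                0.0,
            ),
        }
    ).reset_index(drop=True)

    n_children = dwellings["parent_id"].dropna().value_counts()
    feats["n_child_dwellings"] = (
        n_children.reindex(feats["dwelling_id"]).fillna(0).astype(int).to_numpy()
    )

    # parent dwellings may never host spells themselves; include them so
    # every dwelling with structure gets classified
    parents_only = n_children.index.difference(feats["dwelling_id"])
    if len(parents_only):
        pad = pd.DataFrame(
            {
                "dwelling_id": parents_only,
                "max_simultaneous": 0,
                "annual_turnover": 0.0,
                "median_age": np.nan,
                "fraction_18_25": 0.0,
                "september_arrival_share": 0.0,
                "death_exit_share": 0.0,
                "n_child_dwellings": n_children.reindex(parents_only).to_numpy(),
            }
        )
        feats = pd.concat([feats, pad], ignore_index=True)
    return feats


def classify(features: pd.DataFrame, rules: RuleConfig | None = None) -> pd.DataFrame:
    """Apply the rule cascade; every dwelling receives exactly one type.

    Order matters: structural evidence (child dwellings) wins, then the
    student-hall signature, then the care-home signature, else private.
    """
    r = rules or RuleConfig()
    if not isinstance(r, RuleConfig):
        raise TypeError("rules must be a RuleConfig")
    f = features
    is_flats = f["n_child_dwellings"] >= r.flats_min_children
    is_hall = (
        (f["max_simultaneous"] >= r.hall_min_occupants)
        & (f["fraction_18_25"] >= r.hall_min_frac_18_25)
        & (f["september_arrival_share"] >= r.hall_min_september_share)
    )
    is_care = (
        (f["max_simultaneous"] >= r.care_min_occupants)
        & (f["median_age"] >= r.care_min_median_age)
        & (f["death_exit_share"] >= r.care_min_death_exit_share)
    )
    predicted = np.select(
        [is_flats, is_hall, is_care],
        ["flats_block", "student_hall", "care_home"],
        default="private",
    )
    return pd.DataFrame(
        {"dwelling_id": f["dwelling_id"], "predicted_type": predicted}
    )
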