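"""GP-registration data-quality defects injected into a clean spell table.

Administrative residence data inherit the quirks of GP registration:
people who never deregister from an old practice (the old spell is left
open, which is why registered counts can exceed the true population),
people simultaneously registered at two practices (an overlapping
duplicate spell), and parents who register their children at a new
address before themselves (the child appears at a dwelling before any
adult).  Each defect has its own rate; with all rates zero the output is
the input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

__all__ = ["NoiseParams", "inject_noise"]

_DAYS_PER_YEAR = 365.25


class NoiseParams(BaseModel):
    """Rates and magnitudes of the simulated registration defects.

    Defaults reflect the scale of the Welsh registration excess
    (registered count exceeding the mid-year population by ~2.7%).
    """

    stale_rate: float = Field(0.03, ge=0.0, le=1.0)
    duplicate_rate: float = Field(0.01, ge=0.0, le=1.0)
    child_first_rate: float = Field(0.10, ge=0.0, le=1.0)
    child_first_lag: tuple[int, int] = (1, 60)  # uniform, days
    adult_age: int = 18


def inject_noise(
    spells: pd.DataFrame,
    persons: pd.DataFrame,
    params: NoiseParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Return a noisy copy of a clean spell table.

    A "move" is an adjacent pair of spells for one person (the first ends
    on the day the second starts).  Per move, independently:

    - with ``stale_rate`` the old spell's end is erased (never
      deregistered);
    - with ``duplicate_rate`` an overlapping second registration at the
      old dwelling is appended;
    - whole-household moves (all occupants departing one dwelling for one
      destination on one day) are, with ``child_first_rate``, shifted so
      every child in the move appears at the destination ``lag`` days
      before the adults.

    The output has at least as many rows as the input and is
    deterministic given ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    df = spells.sort_values(["person_id", "start"], kind="stable", ignore_index=True)

    nxt_person = df["person_id"].shift(-1)
    nxt_start = df["start"].shift(-1)
    is_move = (nxt_person == df["person_id"]) & (df["end"] == nxt_start)
    move_idx = np.flatnonzero(is_move.to_numpy())  # index of the *old* spell

    if len(move_idx) == 0:
        return df

    moves = pd.DataFrame(
        {
            "old_row": move_idx,
            "new_row": move_idx + 1,
            "person_id": df["person_id"].to_numpy()[move_idx],
            "from_dw": df["dwelling_id"].to_numpy()[move_idx],
            "to_dw": df["dwelling_id"].to_numpy()[move_idx + 1],
            "date": df["end"].to_numpy()[move_idx],
        }
    )

    # --- child-registered-first: shift children of whole-household moves
    if params.child_first_rate > 0:
        birth = persons.set_index("person_id")["birth_date"]
        mv_birth = birth.reindex(moves["person_id"]).to_numpy()
        age_days = (moves["date"].to_numpy() - mv_birth).astype("timedelta64[D]").astype(float)
        is_child = age_days < params.adult_age * _DAYS_PER_YEAR
        grp = moves.groupby(["from_dw", "to_dw", "date"], sort=True)
        gid = grp.ngroup().to_numpy()
        n_groups = gid.max() + 1
        has_child = np.zeros(n_groups, dtype=bool)
        has_adult = np.zeros(n_groups, dtype=bool)
        np.logical_or.at(has_child, gid, is_child)
        np.logical_or.at(has_adult, gid, ~is_child)
        hit = (rng.random(n_groups) < params.child_first_rate) & has_child & has_adult
        lag = rng.integers(params.child_first_lag[0], params.child_first_lag[1] + 1,
                           size=n_groups)
        shift_rows = hit[gid] & is_child
        if shift_rows.any():
            shift_days = pd.to_timedelta(lag[gid[shift_rows]], unit="D")
            old_rows = moves["old_row"].to_numpy()[shift_rows]
            new_rows = moves["new_row"].to_numpy()[shift_rows]
            shifted = moves["date"].to_numpy()[shift_rows] - shift_days.to_numpy()
            # never shift past the start of the child's old spell
            floor = df["start"].to_numpy()[old_rows] + np.timedelta64(1, "D")
            shifted = np.maximum(shifted, floor)
            df.iloc[old_rows, df.columns.get_loc("end")] = shifted
            df.iloc[new_rows, df.columns.get_loc("start")] = shifted

    # --- stale ends and duplicate registrations (per move, independent)
    u_stale = rng.random(len(moves)) < params.stale_rate
    u_dup = rng.random(len(moves)) < params.duplicate_rate
    dup_len = rng.integers(30, 366, size=len(moves))

    if u_stale.any():
        df.iloc[moves["old_row"].to_numpy()[u_stale], df.columns.get_loc("end")] = pd.NaT

    extras = []
    if u_dup.any():
        sel = moves[u_dup]
        dup_start = df["start"].to_numpy()[sel["new_row"].to_numpy()]
        extras.append(
            pd.DataFrame(
                {
                    "person_id": sel["person_id"].to_numpy(),
                    "dwelling_id": sel["from_dw"].to_numpy(),
                    "start": dup_start,
                    "end": dup_start + pd.to_timedelta(dup_len[u_dup], unit="D").to_numpy(),
                }
            )
        )

    if extras:
        df = pd.concat([df, *extras], ignore_index=True)
    return df.sort_values(["person_id", "start"], kind="stable", ignore_index=True)
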