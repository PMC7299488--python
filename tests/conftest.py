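"""Shared fixtures and independent oracles for the test suite.

The day-scan oracle answers "who lives at dwelling d on day t?" directly
from the cleaned spell table, one day at a time, with no interval
segmentation — deliberately naive so it cannot share a bug with the
episode builder it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from halflink import household
from halflink.spine import generate_geography, generate_population, get_preset


def day_scan_occupants(spells: pd.DataFrame, dwelling, date) -> set:
    """Occupant set at (dwelling, date) straight from the spells."""
    date = pd.Timestamp(date)
    sel = spells[
        (spells["dwelling_id"] == dwelling)
        & (spells["start"] <= date)
        & (date < spells["end"])
    ]
    return set(sel["person_id"])


def episode_occupants_at(episodes: pd.DataFrame, dwelling, date) -> set:
    """Occupant set of the (unique) episode containing a date, or empty."""
    date = pd.Timestamp(date)
    sel = episodes[
        (episodes["dwelling_id"] == dwelling)
        & (episodes["start"] <= date)
        & (date < episodes["end"])
    ]
    assert len(sel) <= 1, "episodes at one dwelling must not overlap"
    return set(sel.iloc[0]["occupants"]) if len(sel) else set()


def make_spells(rows) -> pd.DataFrame:
    """Spell frame from (person, dwelling, start, end-or-None) tuples."""
    return pd.DataFrame(
        {
            "person_id": [r[0] for r in rows],
            "dwelling_id": [r[1] for r in rows],
            "start": pd.to_datetime([r[2] for r in rows]),
            "end": pd.to_datetime([r[3] for r in rows]),
        }
    )


def make_persons(rows) -> pd.DataFrame:
    """Person frame from (id, sex, birth, maternal-or-None) tuples."""
    return pd.DataFrame(
        {
            "person_id": [r[0] for r in rows],
            "sex": [r[1] for r in rows],
            "birth_date": pd.to_datetime([r[2] for r in rows]),
            "death_date": pd.NaT,
            "maternal_id": [r[3] if len(r) > 3 else None for r in rows],
        }
    )


def toy_spine(seed: int):
    preset = get_preset("toy")
    geography = generate_geography(preset, seed)
    return generate_population(geography, preset, seed=seed)


@pytest.fixture(scope="session")
def toy():
    return toy_spine(1)


@pytest.fixture(scope="session")
def ons30():
    """A 30-LSOA definitional spine: large enough to contain communal
    dwellings, blocks of flats and plenty of moves."""
    preset = get_preset("ons-definitional")
    geography = generate_geography(preset, 3, n_lsoa=30)
    return generate_population(geography, preset, seed=3)


@pytest.fixture(scope="session")
def ons30_built(ons30):
    """Cleaned spells and half-id-assigned episodes for the ons30 spine."""
    spells = household.clean_spells(
        ons30.spells, "2016-12-31", persons=ons30.persons
    )
    episodes = household.build_episodes(spells, persons=ons30.persons)
    episodes = household.assign_half_ids(episodes)
    return spells, episodes


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160101)
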