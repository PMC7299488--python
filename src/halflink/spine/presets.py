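"""Spine presets: the study conditions a synthetic spine is generated under.

A preset bundles the geography shape (how many areas at each level and the
ONS size rules they must honour), the demographic targets (residents per
LSOA, household-size mix) and the longitudinal dynamics (move hazards,
fertility, communal occupancy).  Three presets ship:

``toy``
    A deliberately tiny spine (a few hundred people) for unit tests and
    worked examples; its size rules are scaled down accordingly.
``ons-definitional``
    Encodes the ONS definitional bounds for census geography: OAs of at
    least 100 residents, LSOAs of 4-6 OAs holding 1,000-3,000 residents
    (averaging 1,500 residents in roughly 650 households), MSOAs of 4-5
    LSOAs.
``wales-2016``
    The 2016 Welsh spine: 1,909 LSOAs across 22 local authorities,
    3,113,150 residents, LSOA sizes averaging 1,631 (observed range
    900-4,512).
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field, model_validator

__all__ = ["SpinePreset", "SpineDynamics", "PRESETS", "get_preset"]


class SpineDynamics(BaseModel):
    """Longitudinal behaviour of the spine over the observation window.

    None of these rates is dictated by census geography; they are set near
    UK residential-mobility and fertility magnitudes and are exposed as
    configuration.
    """

    window_start: str = "2000-01-01"
    window_end: str = "2016-12-31"
    household_move_hazard: float = 0.10   # whole-household moves / household-year
    individual_move_hazard: float = 0.03  # solo departures / adult-year
    annual_birth_rate: float = 0.055      # births / resident woman aged 15-44 / year
    maternal_coverage: float = 0.95       # probability a birth records the mother's id
    same_la_move_prob: float = 0.80       # household moves staying in the same LA


class SpinePreset(BaseModel):
    """Parameters of one synthetic-spine scenario."""

    name: str
    n_la: int = 1
    n_msoa_per_la: tuple[int, int] = (1, 1)
    lsoa_per_msoa: tuple[int, int] = (4, 5)
    oa_per_lsoa: tuple[int, int] = (4, 6)
    n_lsoa_total: Optional[int] = None
    total_population: Optional[int] = None
    lsoa_size_bounds: tuple[int, int] = (1000, 3000)
    lsoa_size_mean: float = 1500.0
    lsoa_size_sd: float = 300.0
    oa_min_residents: int = 100
    msoa_min_residents: int = 5000
    # P(household size = k), k = 1..8; sizes 8 mean "8 or more" but are
    # generated as exactly 8.  Calibrated so the mean size is ~2.32, i.e.
    # ~1,500 residents in ~650 households per average LSOA.
    household_size_distribution: dict[int, float] = Field(
        default_factory=lambda: {
            1: 0.310, 2: 0.350, 3: 0.155, 4: 0.120,
            5: 0.042, 6: 0.013, 7: 0.006, 8: 0.004,
        }
    )
    communal_fraction: float = 0.010      # share of window-start residents in communal dwellings
    flats_fraction: float = 0.10          # share of private dwellings sitting inside a parent block
    historic_fraction: float = 0.005      # never-occupied demolished dwellings, per private dwelling
    dynamics: SpineDynamics = Field(default_factory=SpineDynamics)

    @model_validator(mode="after")
    def _check(self) -> "SpinePreset":
        lo, hi = self.lsoa_size_bounds
        if not 0 < lo <= hi:
            raise ValueError("lsoa_size_bounds must satisfy 0 < min <= max")
        probs = self.household_size_distribution
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("household_size_distribution must sum to 1")
        if any(k < 1 for k in probs):
            raise ValueError("household sizes start at 1")
        for pair in (self.n_msoa_per_la, self.lsoa_per_msoa, self.oa_per_lsoa):
            if not 1 <= pair[0] <= pair[1]:
                raise ValueError(f"invalid range {pair}")
        return self

    def mean_household_size(self) -> float:
        return sum(k * p for k, p in self.household_size_distribution.items())


def _toy() -> SpinePreset:
    return SpinePreset(
        name="toy",
        n_la=1,
        n_msoa_per_la=(1, 1),
        lsoa_per_msoa=(2, 2),
        oa_per_lsoa=(4, 4),
        lsoa_size_bounds=(40, 120),
        lsoa_size_mean=80.0,
        lsoa_size_sd=20.0,
        oa_min_residents=5,
        msoa_min_residents=0,
        communal_fraction=0.0,
        flats_fraction=0.0,
        historic_fraction=0.0,
    )


def _ons_definitional() -> SpinePreset:
    return SpinePreset(
        name="ons-definitional",
        n_la=2,
        n_msoa_per_la=(5, 6),
        lsoa_per_msoa=(4, 5),
        oa_per_lsoa=(4, 6),
        lsoa_size_bounds=(1000, 3000),
        lsoa_size_mean=1500.0,
        lsoa_size_sd=300.0,
    )


def _wales_2016() -> SpinePreset:
    return SpinePreset(
        name="wales-2016",
        n_la=22,
        n_lsoa_total=1909,
        lsoa_per_msoa=(4, 5),
        oa_per_lsoa=(4, 6),
        total_population=3_113_150,
        lsoa_size_bounds=(900, 4512),
        lsoa_size_mean=1631.0,
        lsoa_size_sd=300.0,
    )


PRESETS = {
    "toy": _toy,
    "ons-definitional": _ons_definitional,
    "wales-2016": _wales_2016,
}


def get_preset(name: str, **overrides) -> SpinePreset:
    """Return a fresh preset by name, optionally overriding fields.

    Raises ``KeyError`` for an unknown preset name.
    """
    try:
        preset = PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; known presets: {sorted(PRESETS)}"
        ) from None
    if overrides:
        preset = preset.model_copy(update=overrides, deep=True)
        preset = SpinePreset.model_validate(preset.model_dump())
    return preset
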