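"""Co-moves, lineages, maternal and candidate-father inference, distances."""

import numpy as np
import pandas as pd
import pytest

from halflink import family, household

from conftest import make_persons, make_spells

CENSOR = "2016-12-31"

ADULTS = make_persons(
    [("A1", "F", "1975-01-01"), ("A2", "M", "1974-01-01"),
     ("B1", "M", "1980-01-01")]
)


def _build(spells, persons=None):
    cl = household.clean_spells(spells, CENSOR, persons=persons)
    return cl, household.assign_half_ids(household.build_episodes(cl, persons=persons))


class TestDetectComoves:
    def test_two_adults_moving_same_day_form_one_event(self):
        spells = make_spells(
            [("A1", "R1", "2000-01-01", "2005-03-01"),
             ("A1", "R2", "2005-03-01", None),
             ("A2", "R1", "2000-01-01", "2005-03-01"),
             ("A2", "R2", "2005-03-01", None)]
        )
        cl, _ = _build(spells, ADULTS)
        ev = family.detect_comoves(cl, ADULTS)
        assert len(ev) == 1
        assert ev["movers"].iloc[0] == ("A1", "A2")
        assert ev["depart_date"].iloc[0] == pd.Timestamp("2005-03-01")

    def test_solo_mover_yields_no_event(self):
        spells = make_spells(
            [("A1", "R1", "2000-01-01", "2005-03-01"),
             ("A1", "R2", "2005-03-01", None)]
        )
        cl, _ = _build(spells, ADULTS)
        assert len(family.detect_comoves(cl, ADULTS)) == 0

    def test_repeat_moves_are_separate_events(self):
        spells = make_spells(
            [("A1", "R1", "2000-01-01", "2011-05-01"),
             ("A1", "R2", "2011-05-01", "2014-08-01"),
             ("A1", "R3", "2014-08-01", None),
             ("A2", "R1", "2000-01-01", "2011-05-01"),
             ("A2", "R2", "2011-05-01", "2014-08-01"),
             ("A2", "R3", "2014-08-01", None)]
        )
        cl, _ = _build(spells, ADULTS)
        ev = family.detect_comoves(cl, ADULTS)
        assert len(ev) == 2
        assert set(zip(ev["from_dwelling"], ev["to_dwelling"])) == {
            ("R1", "R2"), ("R2", "R3")
        }

    def test_event_span_respects_window(self, toy):
        cl = household.clean_spells(toy.spells, CENSOR)
        ev = family.detect_comoves(cl, toy.persons, window_days=28)
        span = (ev["arrive_date"] - ev["depart_date"]).dt.days
        assert (span.between(0, 28)).all()

    def test_negative_window_rejected(self, toy):
        with pytest.raises(ValueError):
            family.detect_comoves(toy.spells, toy.persons, window_days=-1)

    def test_events_rederivable_from_spells(self, toy):
        """Every event member really ends at `from` and starts at `to`."""
        cl = household.clean_spells(toy.spells, CENSOR)
        ev = family.detect_comoves(cl, toy.persons)
        by_person = {p: g for p, g in cl.groupby("person_id")}
        for e in ev.itertuples(index=False):
            for m in e.movers:
                g = by_person[m]
                left = g[(g["dwelling_id"] == e.from_dwelling)
                         & (g["end"] >= e.depart_date)
                         & (g["end"] <= e.arrive_date)]
                arrived = g[(g["dwelling_id"] == e.to_dwelling)
                            & (g["start"] >= e.depart_date)
                            & (g["start"] <= e.arrive_date)]
                assert len(left) and len(arrived)


class TestLinkLineages:
    def _household_path(self, path):
        """Two adults living together, moving along a dwelling path."""
        dates = ["2000-01-01", "2005-01-01", "2010-01-01", "2015-01-01"]
        rows = []
        for p in ("A1", "A2"):
            for i, dw in enumerate(path):
                end = dates[i + 1] if i + 1 < len(path) else None
                rows.append((p, dw, dates[i], end))
        return make_spells(rows)

    def test_single_move_links_two_households(self):
        cl, epi = _build(self._household_path(["R1", "R2"]), ADULTS)
        ev = family.detect_comoves(cl, ADULTS)
        lin = family.link_lineages(epi, ev)
        assert len(lin) == 1
        assert len(lin["half_bases"].iloc[0]) == 2
        assert lin["n_comoves"].iloc[0] == 1
        assert not lin["family_flag"].iloc[0]

    def test_repeated_comoves_flag_a_family(self):
        cl, epi = _build(self._household_path(["R1", "R2", "R3"]), ADULTS)
        ev = family.detect_comoves(cl, ADULTS)
        lin = family.link_lineages(epi, ev)
        assert len(lin) == 1
        assert lin["n_comoves"].iloc[0] == 2
        assert lin["family_flag"].iloc[0]

    def test_never_moving_household_is_singleton_lineage(self):
        spells = make_spells(
            [("A1", "R1", "2000-01-01", None), ("A2", "R1", "2000-01-01", None)]
        )
        cl, epi = _build(spells, ADULTS)
        lin = family.link_lineages(epi, family.detect_comoves(cl, ADULTS))
        assert len(lin) == 1
        assert lin["n_comoves"].iloc[0] == 0

    def test_every_half_base_in_exactly_one_lineage(self, ons30_built):
        spells, epi = ons30_built
        ev = family.detect_comoves(spells, None)
        lin = family.link_lineages(epi, ev)
        seen = [b for bases in lin["half_bases"] for b in bases]
        assert len(seen) == len(set(seen)) == epi["half_base"].nunique()


class TestMaternalLinks:
    PERSONS = make_persons(
        [("MUM", "F", "1980-01-01"),
         ("DAD", "M", "1978-01-01"),
         ("KID", "F", "2005-06-01", "MUM")]
    )

    def _family_spells(self):
        return make_spells(
            [("MUM", "R1", "2000-01-01", None),
             ("DAD", "R1", "2003-01-01", None),
             ("KID", "R1", "2005-06-01", None)]
        )

    def test_coresident_child_linked_from_birth(self):
        _, epi = _build(self._family_spells(), self.PERSONS)
        links = family.link_mother_child(self.PERSONS, epi)
        assert len(links) == 1
        row = links.iloc[0]
        assert row["person_a"] == "MUM" and row["person_b"] == "KID"
        assert row["coresident"]
        assert row["evidence_start"] == pd.Timestamp("2005-06-01")

    def test_no_maternal_id_no_link(self):
        persons = make_persons([("P1", "F", "2005-01-01")])
        spells = make_spells([("P1", "R1", "2005-01-01", None)])
        _, epi = _build(spells, persons)
        assert len(family.link_mother_child(persons, epi)) == 0

    def test_ineligible_maternal_id_skipped(self, caplog):
        persons = make_persons(
            [("M2", "M", "1980-01-01"),          # not female
             ("K1", "F", "2005-01-01", "M2"),
             ("K2", "F", "2005-01-01", "GHOST")]  # missing
        )
        spells = make_spells([("K1", "R1", "2005-01-01", None)])
        _, epi = _build(spells, persons)
        links = family.link_mother_child(persons, epi)
        assert len(links) == 0

    def test_separated_pair_gets_centroid_distance(self):
        persons = self.PERSONS
        spells = make_spells(
            [("MUM", "RA", "2000-01-01", None),
             ("KID", "RB", "2005-06-01", None)]
        )
        dwellings = pd.DataFrame(
            {"dwelling_id": ["RA", "RB"], "lsoa_code": ["L1", "L2"],
             "parent_id": [None, None], "status": "active"}
        )
        geography = pd.DataFrame(
            {"area_code": ["L1", "L2"], "level": "LSOA",
             "parent_code": ["M1", "M1"],
             "centroid_x": [0.0, 3.0], "centroid_y": [0.0, 4.0]}
        )
        _, epi = _build(spells, persons)
        links = family.link_mother_child(
            persons, epi, dwellings, geography, at="2010-01-01"
        )
        row = links.iloc[0]
        assert not row["coresident"]
        assert row["evidence_start"] == pd.Timestamp("2005-06-01")  # birth
        assert row["distance_km"] == pytest.approx(5.0)  # 3-4-5 triangle


class TestCandidateFather:
    PERSONS = make_persons(
        [("MUM", "F", "1980-01-01"),
         ("DAD", "M", "1978-01-01"),
         ("KID", "F", "2005-06-01", "MUM")]
    )

    def _links(self, dad_arrival):
        spells = make_spells(
            [("MUM", "R1", "2000-01-01", None),
             ("DAD", "R1", dad_arrival, None),
             ("KID", "R1", "2005-06-01", None)]
        )
        _, epi = _build(spells, self.PERSONS)
        mother = family.link_mother_child(self.PERSONS, epi)
        return family.infer_candidate_father(self.PERSONS, epi, mother)

    def test_male_resident_before_birth_is_candidate(self):
        links = self._links("2004-06-01")  # one year pre-birth
        assert len(links) == 1
        assert links["person_a"].iloc[0] == "DAD"
        assert links["person_b"].iloc[0] == "KID"

    def test_male_arriving_after_birth_is_not_candidate(self):
        assert len(self._links("2007-06-01")) == 0  # two years post-birth

    def test_household_without_adult_males_yields_nothing(self):
        persons = make_persons(
            [("MUM", "F", "1980-01-01"), ("KID", "M", "2005-06-01", "MUM")]
        )
        spells = make_spells(
            [("MUM", "R1", "2000-01-01", None), ("KID", "R1", "2005-06-01", None)]
        )
        _, epi = _build(spells, persons)
        mother = family.link_mother_child(persons, epi)
        assert len(family.infer_candidate_father(persons, epi, mother)) == 0


class TestExtendedFamily:
    def test_siblings_and_grandmother_linked(self):
        persons = make_persons(
            [("GRAN", "F", "1955-01-01"),
             ("MUM", "F", "1980-01-01", "GRAN"),
             ("K1", "F", "2005-01-01", "MUM"),
             ("K2", "M", "2008-01-01", "MUM")]
        )
        spells = make_spells([(p, "R1", "2008-01-01", None)
                              for p in ("MUM", "K1", "K2")])
        _, epi = _build(spells, persons)
        links = family.link_extended_family(persons, epi)
        pairs = set(zip(links["person_a"], links["person_b"]))
        assert ("K1", "K2") in pairs          # siblings
        # grandmother-grandchild via the chained maternal ids
        assert ("GRAN", "K1") in pairs and ("GRAN", "K2") in pairs
        sib = links[(links["person_a"] == "K1") & (links["person_b"] == "K2")]
        assert sib["coresident"].iloc[0]


def test_distance_matches_bruteforce_on_spine(toy, rng):
    """Random person pairs: module distance equals a direct centroid lookup."""
    cl = household.clean_spells(toy.spells, CENSOR)
    epi = household.assign_half_ids(household.build_episodes(cl))
    at = pd.Timestamp("2008-06-15")
    people = list(toy.persons["person_id"].sample(20, random_state=1))
    links = pd.DataFrame({"person_a": people[:10], "person_b": people[10:]})
    got = family.family_distance(links, epi, toy.dwellings, toy.geography, at)

    dw_lsoa = toy.dwellings.set_index("dwelling_id")["lsoa_code"]
    geo = toy.geography.set_index("area_code")
    for i, (a, b) in enumerate(zip(links["person_a"], links["person_b"])):
        la = family.residence_at(epi, [a], at).iloc[0]
        lb = family.residence_at(epi, [b], at).iloc[0]
        if pd.isna(la) or pd.isna(lb):
            assert np.isnan(got[i])
            continue
        ca, cb = dw_lsoa[la], dw_lsoa[lb]
        if ca == cb:
            assert got[i] == 0.0
        else:
            expect = np.hypot(
                geo.loc[ca, "centroid_x"] - geo.loc[cb, "centroid_x"],
                geo.loc[ca, "centroid_y"] - geo.loc[cb, "centroid_y"],
            )
            assert got[i] == pytest.approx(expect)
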