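"""Synthetic population spine: persons, dwellings and residence spells.

Emulates the structure of a GP-registration demographic spine: people are
allocated to households, households to dwellings, dwellings to census
geography so that per-LSOA resident totals honour the preset's size rules
(and sum exactly to ``total_population`` when one is set).  A configurable
longitudinal process then generates whole-household moves, solo
departures, in-window births and communal-establishment turnover
(student halls with September cohorts, care homes with mortality exits).

All randomness flows from a single seed via named substreams, so the same
(preset, seed) pair yields byte-identical tables.  Dates are day-resolution
and intervals half-open [start, end); an open end (still registered) is a
missing value.

Ground-truth labels — household size per dwelling at the window start and
each dwelling's true residence type — are returned separately and are
never consumed by the household-construction algorithm itself.
"""

from __future__ import annotations

import gc
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .presets import SpinePreset

__all__ = ["Spine", "generate_population"]

_EPOCH = np.datetime64("1970-01-01", "D")
_INF = np.iinfo(np.int32).max  # sentinel for an open (ongoing) spell end
_DAYS_PER_YEAR = 365.25


@dataclass
class Spine:
    """A generated spine: the three input tables plus test-only truth."""

    persons: pd.DataFrame
    dwellings: pd.DataFrame
    spells: pd.DataFrame
    geography: pd.DataFrame
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __iter__(self):
        # allow ``persons, dwellings, spells = spine``
        return iter((self.persons, self.dwellings, self.spells))


def _to_days(date_like) -> int:
    return int((np.datetime64(date_like, "D") - _EPOCH).astype(int))


def _to_dates(days: np.ndarray) -> pd.Series:
    """int day counts -> datetime64[ns]; the _INF sentinel -> NaT."""
    days = np.asarray(days, dtype="int64")
    open_ = days >= _INF
    safe = np.where(open_, 0, days)
    out = pd.Series((_EPOCH + safe).astype("datetime64[ns]"))
    out[open_] = pd.NaT
    return out


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights`` (exact sum)."""
    w = np.asarray(weights, dtype=float)
    raw = total * w / w.sum()
    base = np.floor(raw).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def _repair_bounds(alloc: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Nudge an exact-sum allocation into [lo, hi] per entry, preserving the sum."""
    a = alloc.copy()
    total = int(a.sum())
    n = len(a)
    if not n * lo <= total <= n * hi:
        raise ValueError(
            f"total {total} infeasible for {n} areas with bounds [{lo}, {hi}]"
        )
    for _ in range(200):
        a = np.clip(a, lo, hi)
        diff = total - int(a.sum())
        if diff == 0:
            return a
        if diff > 0:
            room = (hi - a).astype(np.int64)
            idx = np.flatnonzero(room)
            give = _largest_remainder(diff, room[idx] + 1e-9)
            a[idx] += np.minimum(give, room[idx])
        else:
            room = (a - lo).astype(np.int64)
            idx = np.flatnonzero(room)
            take = _largest_remainder(-diff, room[idx] + 1e-9)
            a[idx] -= np.minimum(take, room[idx])
    raise RuntimeError("bounds repair did not converge")  # pragma: no cover


def _draw_lsoa_totals(preset: SpinePreset, n_lsoa: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = preset.lsoa_size_bounds
    if preset.total_population is not None:
        total = preset.total_population
        if not n_lsoa * lo <= total <= n_lsoa * hi:
            raise ValueError(
                f"total_population {total} infeasible for {n_lsoa} LSOAs "
                f"with bounds [{lo}, {hi}]"
            )
        # right-skewed sizes (a shifted lognormal): most LSOAs sit near the
        # mean, a thin urban tail approaches the upper bound
        m = max(preset.lsoa_size_mean - lo, 1.0)
        s = preset.lsoa_size_sd
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2
        raw = lo + rng.lognormal(mu, np.sqrt(sigma2), size=n_lsoa)
        raw = np.clip(raw, lo, hi)
        alloc = _largest_remainder(total, raw)
        return _repair_bounds(alloc, lo, hi)
    draws = rng.normal(preset.lsoa_size_mean, preset.lsoa_size_sd, size=n_lsoa)
    return np.clip(np.round(draws), lo, hi).astype(np.int64)


def _enforce_msoa_minimum(
    totals: np.ndarray,
    msoa_idx: np.ndarray,
    msoa_min: int,
    lo: int,
    hi: int,
    preserve_total: bool,
) -> np.ndarray:
    """Raise deficient MSOA populations to the mandated minimum.

    Residents are added to the deficient MSOA's LSOAs (capped at the LSOA
    upper bound); when the global total is fixed, the same amount is
    removed from LSOAs in comfortably-above-minimum MSOAs.
    """
    totals = totals.copy()
    target = int(totals.sum())
    n_msoa = int(msoa_idx.max()) + 1

    def msoa_sums() -> np.ndarray:
        return np.bincount(msoa_idx, weights=totals, minlength=n_msoa).astype(np.int64)

    for _ in range(50):
        sums = msoa_sums()
        deficient = np.flatnonzero(sums < msoa_min)
        diff = int(totals.sum()) - target
        if len(deficient) == 0 and (diff <= 0 or not preserve_total):
            break
        for m in deficient:
            members = np.flatnonzero(msoa_idx == m)
            room = (hi - totals[members]).astype(np.int64)
            add = np.minimum(
                _largest_remainder(int(msoa_min - sums[m]), room + 1e-9), room
            )
            totals[members] += add
        if preserve_total:
            diff = int(totals.sum()) - target
            if diff > 0:
                sums = msoa_sums()
                slack = np.minimum(totals - lo, sums[msoa_idx] - msoa_min)
                slack = np.maximum(slack, 0).astype(np.int64)
                donors = np.flatnonzero(slack)
                if len(donors) == 0:  # pragma: no cover - infeasible preset
                    break
                take = np.minimum(
                    _largest_remainder(min(diff, int(slack[donors].sum())),
                                       slack[donors] + 1e-9),
                    slack[donors],
                )
                totals[donors] -= take
    return totals


def _draw_household_sizes(
    quota: np.ndarray, preset: SpinePreset, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Fill each LSOA's private resident quota with iid household sizes.

    The final household in each LSOA is trimmed to land exactly on the
    quota (its size is then 1..8, a negligible distortion of the mix).
    Returns (household lsoa index, household size).
    """
    support = np.array(sorted(preset.household_size_distribution), dtype=np.int64)
    probs = np.array([preset.household_size_distribution[k] for k in support])
    cdf = np.cumsum(probs)
    mean_size = float((support * probs).sum())
    hh_lsoa: list[np.ndarray] = []
    hh_size: list[np.ndarray] = []
    for l, target in enumerate(quota):
        target = int(target)
        if target <= 0:
            continue
        sizes = np.empty(0, dtype=np.int64)
        while sizes.sum() < target:
            est = max(int((target - sizes.sum()) / mean_size * 1.3) + 8, 8)
            u = rng.random(est)
            sizes = np.concatenate([sizes, support[np.searchsorted(cdf, u)]])
        cs = np.cumsum(sizes)
        k = int(np.searchsorted(cs, target))
        sizes = sizes[: k + 1]
        sizes[k] = target - (cs[k - 1] if k > 0 else 0)
        hh_size.append(sizes)
        hh_lsoa.append(np.full(len(sizes), l, dtype=np.int64))
    return np.concatenate(hh_lsoa), np.concatenate(hh_size)


class _DwellingRegistry:
    """Incremental dwelling table (integer ids until final formatting)."""

    def __init__(self) -> None:
        self.lsoa: list[np.ndarray] = []
        self.oa: list[np.ndarray] = []
        self.parent: list[np.ndarray] = []
        self.status: list[np.ndarray] = []
        self.true_type: list[np.ndarray] = []
        self.n = 0

    def add(self, lsoa, oa, true_type, parent=None, status=None) -> np.ndarray:
        lsoa = np.asarray(lsoa, dtype=np.int64)
        k = len(lsoa)
        ids = np.arange(self.n, self.n + k, dtype=np.int64)
        self.n += k
        self.lsoa.append(lsoa)
        self.oa.append(np.asarray(oa, dtype=np.int64))
        self.parent.append(
            np.full(k, -1, dtype=np.int64) if parent is None
            else np.asarray(parent, dtype=np.int64)
        )
        self.status.append(
            np.full(k, "active") if status is None else np.asarray(status)
        )
        tt = np.full(k, true_type) if isinstance(true_type, str) else np.asarray(true_type)
        self.true_type.append(tt)
        return ids

    def frames(self, lsoa_codes: np.ndarray, oa_codes: np.ndarray):
        lsoa = np.concatenate(self.lsoa)
        oa = np.concatenate(self.oa)
        parent = np.concatenate(self.parent)
        did = _format_ids("D", np.arange(self.n))
        parent_str = np.where(parent >= 0, _format_ids("D", np.maximum(parent, 0)), None)
        dwellings = pd.DataFrame(
            {
                "dwelling_id": _string_col(did),
                "parent_id": _string_col(parent_str),
                "lsoa_code": lsoa_codes[lsoa],
                "oa_code": np.where(oa >= 0, oa_codes[np.maximum(oa, 0)], None),
                "status": np.concatenate(self.status),
            }
        )
        types = pd.DataFrame(
            {"dwelling_id": _string_col(did), "true_type": np.concatenate(self.true_type)}
        )
        return dwellings, types


def _format_ids(prefix: str, idx: np.ndarray) -> np.ndarray:
    # fixed-width '<U8' intermediate keeps the temporaries small at
    # multi-million scale (ids never exceed 8 digits)
    padded = np.char.zfill(np.asarray(idx, dtype=np.int64).astype("U8"), 8)
    return np.char.add(prefix, padded)


def _string_col(values: np.ndarray) -> pd.api.extensions.ExtensionArray:
    """Arrow-backed string column: compact enough for spine-scale tables."""
    return pd.array(values, dtype="string[pyarrow]")


def generate_population(
    geography: pd.DataFrame,
    preset: SpinePreset,
    start_date=None,
    end_date=None,
    seed: int = 0,
) -> Spine:
    """Generate persons, dwellings and residence spells on a geography.

    Parameters
    ----------
    geography
        Output of :func:`generate_geography` (must contain the LSOAs and
        OAs the population is placed into).
    preset
        Demographic targets and dynamics; see :class:`SpinePreset`.
    start_date, end_date
        Observation window (defaults from ``preset.dynamics``); half-open
        at day resolution.
    seed
        Master seed; the population stream is independent of the
        geography stream for the same seed.

    Returns
    -------
    Spine
        persons / dwellings / spells tables (spells are noise-free: per
        person non-overlapping and chronologically ordered), the
        geography passed in, and ``truth`` tables for testing.
    """
    dyn = preset.dynamics
    ws = _to_days(start_date or dyn.window_start)
    we = _to_days(end_date or dyn.window_end)
    if we <= ws:
        raise ValueError("observation window is empty")
    w_days = we - ws
    years = w_days / _DAYS_PER_YEAR
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))

    lsoas = geography.loc[geography["level"] == "LSOA"].reset_index(drop=True)
    oas = geography.loc[geography["level"] == "OA"].reset_index(drop=True)
    lsoa_codes = lsoas["area_code"].to_numpy()
    n_lsoa = len(lsoa_codes)
    lsoa_pos = pd.Series(np.arange(n_lsoa), index=lsoa_codes)
    oa_codes = oas["area_code"].to_numpy()
    oa_lsoa = lsoa_pos.reindex(oas["parent_code"]).to_numpy()
    # OAs grouped by LSOA for random-OA lookups
    oa_order = np.argsort(oa_lsoa, kind="stable")
    oa_sorted = np.arange(len(oa_codes))[oa_order]
    oa_counts = np.bincount(oa_lsoa, minlength=n_lsoa)
    oa_offsets = np.concatenate([[0], np.cumsum(oa_counts)])

    # LA membership of each LSOA (for move-destination locality)
    msoa_parent = geography.loc[geography["level"] == "MSOA"].set_index("area_code")["parent_code"]
    lsoa_la = msoa_parent.reindex(lsoas["parent_code"]).to_numpy()
    la_codes, lsoa_la_idx = np.unique(lsoa_la, return_inverse=True)
    la_order = np.argsort(lsoa_la_idx, kind="stable")
    la_sorted_lsoa = np.arange(n_lsoa)[la_order]
    la_counts = np.bincount(lsoa_la_idx, minlength=len(la_codes))
    la_offsets = np.concatenate([[0], np.cumsum(la_counts)])

    lsoa_totals = _draw_lsoa_totals(preset, n_lsoa, rng)
    if preset.msoa_min_residents > 0:
        msoa_codes, lsoa_msoa_idx = np.unique(
            lsoas["parent_code"].to_numpy(), return_inverse=True
        )
        lsoa_totals = _enforce_msoa_minimum(
            lsoa_totals,
            lsoa_msoa_idx,
            preset.msoa_min_residents,
            *preset.lsoa_size_bounds,
            preserve_total=preset.total_population is not None,
        )

    # ---- communal establishments: carve their window-start occupancy out
    # of the private resident quota so per-LSOA totals stay exact
    private_quota = lsoa_totals.copy()
    communal: list[tuple[int, int, str]] = []  # (lsoa, capacity, type)
    target_communal = int(round(lsoa_totals.sum() * preset.communal_fraction))
    floor = np.maximum(preset.oa_min_residents * oa_counts * 13 // 10,
                       preset.lsoa_size_bounds[0] // 2)
    placed = 0
    kind_draw = rng.random(4096)
    cap_hall = rng.integers(80, 251, size=4096)
    cap_care = rng.integers(20, 61, size=4096)
    i = 0
    while placed < target_communal and i < 4096:
        is_hall = kind_draw[i] < 0.6
        cap = int(cap_hall[i] if is_hall else cap_care[i])
        eligible = np.flatnonzero(private_quota - cap >= floor)
        if len(eligible) == 0:
            break
        # prefer larger LSOAs (communal residences cluster in dense areas)
        w = (private_quota[eligible] - floor[eligible]).astype(float)
        l = int(rng.choice(eligible, p=w / w.sum()))
        private_quota[l] -= cap
        communal.append((l, cap, "student_hall" if is_hall else "care_home"))
        placed += cap
        i += 1

    # ---- private households
    hh_lsoa, hh_size = _draw_household_sizes(private_quota, preset, rng)
    n_hh = len(hh_size)

    # OA quotas within each LSOA (largest remainder over jittered weights),
    # then households assigned to OAs by filling quotas in order
    hh_oa = np.empty(n_hh, dtype=np.int64)
    for l in range(n_lsoa):
        sel = hh_lsoa == l
        if not sel.any():
            continue
        k = oa_counts[l]
        weights = 1.0 + rng.uniform(-0.05, 0.05, size=k)
        quota = _largest_remainder(int(private_quota[l]), weights)
        bounds = np.cumsum(quota)
        cs = np.cumsum(hh_size[sel])
        oa_local = np.searchsorted(bounds, cs - 1, side="right").clip(max=k - 1)
        hh_oa[sel] = oa_sorted[oa_offsets[l] + oa_local]

    # ---- household composition -> persons
    u = rng.random(n_hh)
    n_adults = np.ones(n_hh, dtype=np.int64)
    n_adults[(hh_size == 2) & (u < 0.75)] = 2
    n_adults[(hh_size >= 3) & (u < 0.88)] = 2
    n_children = hh_size - n_adults
    has_children = n_children > 0

    n_persons = int(hh_size.sum())
    person_hh = np.repeat(np.arange(n_hh), hh_size)
    first_of_hh = np.concatenate([[0], np.cumsum(hh_size)[:-1]])
    pos = np.arange(n_persons) - first_of_hh[person_hh]
    is_adult = pos < n_adults[person_hh]
    is_child = ~is_adult

    age_years = np.empty(n_persons)
    child_age = rng.uniform(0.0, 17.5, size=int(is_child.sum()))
    age_years[is_child] = child_age
    eldest = np.zeros(n_hh)
    np.maximum.at(eldest, person_hh[is_child], child_age)
    a0_age = np.where(
        has_children,
        eldest + rng.uniform(20, 38, size=n_hh),
        rng.uniform(22, 88, size=n_hh),
    )
    a1_age = np.clip(a0_age + rng.uniform(-4, 8, size=n_hh), 19, 95)
    adult0 = is_adult & (pos == 0)
    adult1 = is_adult & (pos == 1)
    age_years[adult0] = a0_age
    age_years[adult1] = a1_age[person_hh[adult1]]

    sex = np.where(rng.random(n_persons) < 0.5, "F", "M")
    sex[adult0 & has_children[person_hh]] = "F"  # the recorded mother
    partner_male = rng.random(n_hh) < 0.9
    sex[adult1 & has_children[person_hh]] = np.where(
        partner_male[person_hh[adult1 & has_children[person_hh]]], "M", "F"
    )

    birth_days = ws - np.round(age_years * _DAYS_PER_YEAR).astype(np.int64)
    mother_pid = np.full(n_persons, -1, dtype=np.int64)
    child_rows = np.flatnonzero(is_child)
    recorded = rng.random(len(child_rows)) < dyn.maternal_coverage
    mother_pid[child_rows[recorded]] = first_of_hh[person_hh[child_rows[recorded]]]

    # ---- dwellings
    reg = _DwellingRegistry()
    home_dw = reg.add(hh_lsoa, hh_oa, "private")

    # blocks of flats: chunk a fraction of each LSOA's dwellings under a
    # shared parent dwelling (the parent itself hosts no spells)
    if preset.flats_fraction > 0:
        flat_parent = np.full(n_hh, -1, dtype=np.int64)
        parent_lsoa, parent_oa, parent_members = [], [], []
        for l in range(n_lsoa):
            members = np.flatnonzero(hh_lsoa == l)
            n_flat = int(len(members) * preset.flats_fraction)
            j = 0
            while j + 4 <= n_flat:
                size = int(rng.integers(4, 17))
                block = members[j : j + min(size, n_flat - j)]
                if len(block) < 2:
                    break
                parent_lsoa.append(l)
                parent_oa.append(hh_oa[block[0]])
                parent_members.append(block)
                j += len(block)
        if parent_members:
            pids = reg.add(parent_lsoa, parent_oa, "flats_block")
            for pid_, block in zip(pids, parent_members):
                flat_parent[block] = pid_
            reg.parent[0][flat_parent >= 0] = flat_parent[flat_parent >= 0]

    if preset.historic_fraction > 0 and n_hh > 0:
        n_hist = int(round(n_hh * preset.historic_fraction))
        if n_hist:
            hl = rng.integers(0, n_lsoa, size=n_hist)
            ho = np.array([oa_sorted[oa_offsets[l] + rng.integers(0, oa_counts[l])] for l in hl])
            reg.add(hl, ho, "private", status=np.full(n_hist, "historic"))

    # ---- whole-household moves (segments of the household's address path)
    k_moves = rng.poisson(dyn.household_move_hazard * years, size=n_hh)
    n_ev = int(k_moves.sum())
    ev_hh = np.repeat(np.arange(n_hh), k_moves)
    ev_date = ws + rng.integers(1, w_days, size=n_ev)
    order = np.lexsort((ev_date, ev_hh))
    ev_hh, ev_date = ev_hh[order], ev_date[order]

    def _random_lsoa_near(src_lsoa: np.ndarray) -> np.ndarray:
        stay = rng.random(len(src_lsoa)) < dyn.same_la_move_prob
        la = lsoa_la_idx[src_lsoa]
        local = la_sorted_lsoa[la_offsets[la] + rng.integers(0, la_counts[la])]
        anywhere = rng.integers(0, n_lsoa, size=len(src_lsoa))
        return np.where(stay, local, anywhere)

    def _random_oa_of(lsoa_idx: np.ndarray) -> np.ndarray:
        return oa_sorted[oa_offsets[lsoa_idx] + rng.integers(0, oa_counts[lsoa_idx])]

    ev_lsoa = _random_lsoa_near(hh_lsoa[ev_hh])
    ev_dw = reg.add(ev_lsoa, _random_oa_of(ev_lsoa), "private")

    # household segment table: segment 0 is the original home, segment j>0
    # starts at the j-th move
    n_seg = k_moves + 1
    seg_hh = np.repeat(np.arange(n_hh), n_seg)
    seg_first = np.concatenate([[0], np.cumsum(n_seg)[:-1]])
    seg_pos = np.arange(int(n_seg.sum())) - seg_first[seg_hh]
    seg_start = np.empty(len(seg_hh), dtype=np.int64)
    seg_dw = np.empty(len(seg_hh), dtype=np.int64)
    head = seg_pos == 0
    seg_start[head] = ws
    seg_dw[head] = home_dw
    seg_start[~head] = ev_date
    seg_dw[~head] = ev_dw
    seg_end = np.full(len(seg_hh), _INF, dtype=np.int64)
    same_hh = seg_hh[:-1] == seg_hh[1:]
    seg_end[:-1][same_hh] = seg_start[1:][same_hh]

    # ---- solo departures (adults, including children coming of age)
    adult_at = np.maximum(ws, birth_days + int(18 * _DAYS_PER_YEAR))
    eligible = adult_at < we
    wait = rng.exponential(1.0 / max(dyn.individual_move_hazard, 1e-12), size=n_persons)
    dep_day = adult_at + np.round(wait * _DAYS_PER_YEAR).astype(np.int64)
    departs = eligible & (dep_day < we) & (dep_day > ws)
    p_exit = np.where(departs, dep_day, _INF)

    # ---- in-window births to resident, non-departing adult women
    mother_rows = np.flatnonzero(
        is_adult & (sex == "F") & (age_years < 45) & ~departs
    )
    m_end = np.minimum(we, birth_days[mother_rows] + int(45 * _DAYS_PER_YEAR))
    span_years = np.maximum(m_end - ws, 0) / _DAYS_PER_YEAR
    n_births = rng.poisson(dyn.annual_birth_rate * span_years)
    b_mother = np.repeat(mother_rows, n_births)
    b_span = np.repeat(np.maximum(m_end - ws - 1, 1), n_births)
    # strictly after the window start: the start-date census equals the
    # allocated population exactly
    b_date = ws + 1 + np.floor(rng.random(len(b_mother)) * b_span).astype(np.int64)

    # assemble the person-level frame feeding spell construction
    base_persons = pd.DataFrame(
        {
            "pid": np.arange(n_persons, dtype=np.int32),
            "hh": person_hh.astype(np.int32),
            "p_start": np.full(n_persons, ws, dtype=np.int32),
            "p_exit": p_exit.astype(np.int32),
            "birth": birth_days,
            "sex": sex,
            "mother": mother_pid,
        }
    )
    if len(b_mother):
        new_pid = np.arange(n_persons, n_persons + len(b_mother))
        rec = rng.random(len(b_mother)) < dyn.maternal_coverage
        baby = pd.DataFrame(
            {
                "pid": new_pid.astype(np.int32),
                "hh": person_hh[b_mother].astype(np.int32),
                "p_start": b_date.astype(np.int32),
                "p_exit": np.full(len(b_mother), _INF, dtype=np.int32),
                "birth": b_date,
                "sex": np.where(rng.random(len(b_mother)) < 0.5, "F", "M"),
                "mother": np.where(rec, b_mother, -1),
            }
        )
        base_persons = pd.concat([base_persons, baby], ignore_index=True)

    segments = pd.DataFrame(
        {
            "hh": seg_hh.astype(np.int32),
            "seg_start": seg_start.astype(np.int32),
            "seg_end": np.clip(seg_end, None, _INF).astype(np.int32),
            "dw": seg_dw.astype(np.int32),
        }
    )
    joined = base_persons[["pid", "hh", "p_start", "p_exit"]].merge(
        segments, on="hh", how="left", sort=False
    )
    del segments
    s = np.maximum(joined["seg_start"].to_numpy(), joined["p_start"].to_numpy())
    e = np.minimum(joined["seg_end"].to_numpy(), joined["p_exit"].to_numpy())
    keep = s < e
    spell_pid = joined["pid"].to_numpy()[keep]
    spell_dw = joined["dw"].to_numpy()[keep]
    spell_s = s[keep]
    spell_e = e[keep]
    del joined, s, e, keep

    # post-departure single residences
    dep_rows = np.flatnonzero(departs)
    if len(dep_rows):
        dl = _random_lsoa_near(hh_lsoa[person_hh[dep_rows]])
        ddw = reg.add(dl, _random_oa_of(dl), "private")
        spell_pid = np.concatenate([spell_pid, dep_rows])
        spell_dw = np.concatenate([spell_dw, ddw])
        spell_s = np.concatenate([spell_s, dep_day[dep_rows]])
        spell_e = np.concatenate([spell_e, np.full(len(dep_rows), _INF, dtype=np.int64)])

    death_days = np.full(len(base_persons), _INF, dtype=np.int64)

    # ---- communal establishments
    extra_p: list[pd.DataFrame] = []
    next_pid = int(base_persons["pid"].max()) + 1 if len(base_persons) else 0
    for l, cap, kind in communal:
        dw = int(reg.add([l], [_random_oa_of(np.array([l]))[0]], kind)[0])
        if kind == "student_hall":
            year0 = pd.Timestamp(_EPOCH + np.int64(ws)).year
            first = _to_days(f"{year0}-09-15")
            if first > ws:
                first = _to_days(f"{year0 - 1}-09-15")
            arrivals = []
            a = first
            while a < we:
                arrivals.append(a)
                y = pd.Timestamp(_EPOCH + np.int64(a)).year
                a = _to_days(f"{y + 1}-09-15")
            for a in arrivals:
                dep = a + 360  # out before the next cohort arrives
                pidv = np.arange(next_pid, next_pid + cap)
                next_pid += cap
                age = rng.uniform(18, 22, size=cap)
                extra_p.append(
                    pd.DataFrame(
                        {
                            "pid": pidv,
                            "dw": dw,
                            "s": max(a, ws),
                            "e": dep if dep < we else _INF,
                            "birth": a - np.round(age * _DAYS_PER_YEAR).astype(np.int64),
                            "sex": np.where(rng.random(cap) < 0.5, "F", "M"),
                            "death": _INF,
                        }
                    )
                )
        else:  # care_home
            n_adm = int(rng.poisson(cap * w_days / 730))
            entry = np.concatenate(
                [np.full(cap, ws, dtype=np.int64),
                 ws + rng.integers(1, w_days, size=n_adm)]
            )
            stay = np.ceil(rng.exponential(730, size=len(entry))).astype(np.int64)
            exit_ = entry + stay
            open_end = exit_ >= we
            dies = (rng.random(len(entry)) < 0.85) & ~open_end
            pidv = np.arange(next_pid, next_pid + len(entry))
            next_pid += len(entry)
            age = rng.uniform(75, 95, size=len(entry))
            extra_p.append(
                pd.DataFrame(
                    {
                        "pid": pidv,
                        "dw": dw,
                        "s": entry,
                        "e": np.where(open_end, _INF, exit_),
                        "birth": entry - np.round(age * _DAYS_PER_YEAR).astype(np.int64),
                        "sex": np.where(rng.random(len(entry)) < 0.5, "F", "M"),
                        "death": np.where(dies, exit_, _INF),
                    }
                )
            )

    if extra_p:
        extra = pd.concat(extra_p, ignore_index=True)
        spell_pid = np.concatenate([spell_pid, extra["pid"].to_numpy()])
        spell_dw = np.concatenate([spell_dw, extra["dw"].to_numpy()])
        spell_s = np.concatenate([spell_s, extra["s"].to_numpy()])
        spell_e = np.concatenate([spell_e, extra["e"].to_numpy()])

    # ---- final tables -------------------------------------------------
    n_total = next_pid
    all_birth = np.empty(n_total, dtype=np.int64)
    all_sex = np.empty(n_total, dtype=object)
    all_mother = np.full(n_total, -1, dtype=np.int64)
    all_death = np.full(n_total, _INF, dtype=np.int64)
    bp = base_persons
    all_birth[bp["pid"].to_numpy()] = bp["birth"].to_numpy()
    all_sex[bp["pid"].to_numpy()] = bp["sex"].to_numpy()
    all_mother[bp["pid"].to_numpy()] = bp["mother"].to_numpy()
    all_death[bp["pid"].to_numpy()] = death_days[: len(bp)]
    if extra_p:
        all_birth[extra["pid"].to_numpy()] = extra["birth"].to_numpy()
        all_sex[extra["pid"].to_numpy()] = extra["sex"].to_numpy()
        all_death[extra["pid"].to_numpy()] = extra["death"].to_numpy()
        del extra
    del base_persons, bp
    gc.collect()

    pid_str = _format_ids("P", np.arange(n_total))
    maternal = np.where(all_mother >= 0, pid_str[np.maximum(all_mother, 0)], None)
    persons = pd.DataFrame(
        {
            "person_id": _string_col(pid_str),
            "sex": all_sex,
            "birth_date": _to_dates(all_birth),
            "death_date": _to_dates(all_death),
            "maternal_id": _string_col(maternal),
        }
    )
    del maternal

    dwellings, dwelling_types = reg.frames(lsoa_codes, oa_codes)

    # sort while the keys are still integers, then format ids
    order = np.lexsort((spell_s, spell_pid))
    spell_pid, spell_dw = spell_pid[order], spell_dw[order]
    spell_s, spell_e = spell_s[order], spell_e[order]
    del order
    gc.collect()
    person_col = _string_col(pid_str[spell_pid])
    del pid_str
    gc.collect()
    spells = pd.DataFrame(
        {
            "person_id": person_col,
            "dwelling_id": _string_col(_format_ids("D", spell_dw)),
            "start": _to_dates(spell_s),
            "end": _to_dates(spell_e),
        }
    )
    del person_col

    # truth: household size per occupied dwelling at the window start
    at_start = (spell_s <= ws) & (spell_e > ws)
    start_sizes = (
        pd.Series(spell_dw[at_start]).value_counts().sort_index()
    )
    truth_sizes = pd.DataFrame(
        {
            "dwelling_id": _format_ids("D", start_sizes.index.to_numpy()),
            "size": start_sizes.to_numpy(),
        }
    )
    return Spine(
        persons=persons,
        dwellings=dwellings,
        spells=spells,
        geography=geography,
        truth={"dwelling_types": dwelling_types, "household_sizes_start": truth_sizes},
    )
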