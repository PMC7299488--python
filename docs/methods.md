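# Methods

This note documents the models and procedures implemented in
`halflink`, the parameters that govern them, and the reasoning behind
choices the problem left open.

## Representation of time and residence

All dates are ISO calendar dates at day resolution.  Every interval —
residence spell, household episode, lineage span — is half-open,
`[start, end)`, so a move-out day equals the next move-in day without
double counting and adjacency is unambiguous.  An open end (a person
still registered) is a missing value in the raw data and becomes the
configured censor date after cleaning, flagged `imputed_end`; stability
rates are computed over the censored span.

## Spell cleaning

The cleaning rule set resolves each person's registration history into
a partition of their time: at most one dwelling per day.

- Overlapping spells: the later-starting registration is presumed
  current and kept intact; the earlier spell is truncated to end at the
  later start and flagged `truncated_overlap`.  This encodes the
  mechanism that creates overlaps in GP data — people register at the
  new practice without deregistering from the old one.
- Two spells with identical starts: the one at the lexicographically
  larger dwelling id is kept.  This tie-break is arbitrary by design;
  it exists only to make the output deterministic, and is documented as
  such.
- Spells starting after the censor date are dropped with a logged
  warning rather than an error: a single bad row should not abort a
  population-scale run.
- A minor's spell beginning before any adult has arrived at the
  dwelling is flagged `child_first` (parents registering children
  before themselves).  The flag marks a data-quality signal; the spell
  itself is kept.

Cleaning is idempotent on the interval content: a second pass changes
no start or end.

## Episodes and versioned household identifiers

Within one dwelling, the timeline is cut at every spell start and end;
between consecutive cuts the occupant set is constant.  Maximal
constant non-empty intervals are *episodes*.  Consecutive episodes
continue the same household — same base identifier, version
incremented from 1 — exactly when the gap between them is zero days
and at least one occupant is shared.

Two boundary questions are not settled by the household definition
itself; both are configuration-exposed:

- **Vacancy.**  A dwelling vacated and later reoccupied starts a new
  household, even by the identical people.  Vacancy is treated as
  household dissolution because nothing in residence data distinguishes
  a returning household from a new one with the same members; teams who
  disagree can set `continuity.allow_gap_days` above 0 to bridge short
  vacancies (for example renovation absences).
- **Adulthood.**  `adult_age` defaults to 18 years at the episode
  start, used for the `minors_only` episode flag, the `child_first`
  spell flag, co-move eligibility of candidate fathers, and nothing
  else.

Episodes whose occupants are all minors are retained and flagged,
never merged into later adult episodes: they are the visible trace of
the child-registered-first defect and deserve scrutiny, not silent
repair.

Stability per household base: the version count, total (censored)
duration, mean episode duration, composition changes per year
`(n_versions − 1) / years`, and founder retention (fraction of
version-1 occupants still present in the final version).

## Lineages and familial links

A *co-move* is a group of at least `comove.min_movers` (default 2)
people ending spells at one dwelling and starting at another, with each
member's gap and the event's departure scatter within
`comove.window_days` (default 28 — a month tolerates registration
lag).  Households are chained through co-moves when the movers are the
*final* episode's occupants at the origin (the household left or
dissolved) and appear in the *first* episode at the destination; a
departing subset founds its own lineage while the remainder continues
the original household.  A lineage with at least `family_min_comoves`
(default 2) co-moves is flagged a probable family: moving together once
may be coincidence, repeatedly is evidence.

Mother–child links come directly from recorded maternal identifiers;
links whose maternal id is missing, not female, or fewer than 12 years
older than the child are skipped and logged.  A candidate father is any
male of at least `adult_age` at the child's birth whose membership of
the child's birth household began at or before the birth date.  All
qualifying males are emitted; the link asserts significant coresidence,
never biology.  Children born before the observation window begins
cannot generate candidate-father links (no pre-birth coresidence is
observable); this is a stated limitation, not a defect.  Sibling and
maternal-grandmother links are derived by chaining maternal
identifiers.  Distances between non-coresident kin are planar
Euclidean distances between synthetic LSOA centroids, 0 within one
LSOA; real population-weighted centroids would slot into the same
interface.

## Communal-residence classification

Per-dwelling occupancy features over the window: peak simultaneous
occupancy, annual turnover (departures per year over mean occupancy),
median occupant age at mid-window, fraction aged 18–25 at arrival,
September arrival share, death-coincident exit share, and the count of
child dwellings naming the dwelling as parent.  The rule cascade
(structure first, then the hall signature, then the care-home
signature, else private):

| rule | thresholds (defaults) |
|---|---|
| block of flats | ≥ 2 child dwellings |
| student hall | peak ≥ 20 ∧ fraction 18–25 ≥ 0.8 ∧ September share ≥ 0.5 |
| care home | peak ≥ 10 ∧ median age ≥ 70 ∧ death-exit share ≥ 0.3 |

The thresholds are declared heuristics held in `RuleConfig`, evaluated
against generator ground truth (the suite asserts ≥ 0.99 accuracy on
spines whose communal dwellings sit well inside the rule regions, and
100% on fixtures constructed inside them).  No claim is made about
real-world accuracy; on real data the rules are a starting point to be
refined, particularly for care homes and for finding households inside
blocks of flats, which this package deliberately does not attempt.

## Release and validation

Aggregates are point-prevalence household counts per area (LSOA, MSOA
or LA) in size bands 1/2/3/4/5+, mirroring census household-size
tables; aggregation is additive up the hierarchy.  Cells with
`0 < count < release.suppress_threshold` (default 5, common UK
disclosure practice) are marked suppressed and their counts withheld
from written output; zero cells are structural and remain.  Secondary
(complementary) suppression is out of scope and is a known gap: a
suppressed cell inside an otherwise complete margin is recoverable by
subtraction.

Validation treats the reference's band proportion
`p = expected / area-total` as a binomial probability over the area
total `N` and checks the observed count against the
continuity-corrected normal interval `N·p ± (z·sqrt(N·p(1−p)) + 0.5)`
at level `1 − alpha` (default `alpha = 0.05`, the 95% criterion).
"Within the 95% confidence level" could be read per cell, per area, or
globally; the summary reports all three and chooses none.  The
statistic sits behind a single function so an exact binomial or
chi-square alternative can be swapped in.  The interval treats the
reference as fixed truth — appropriate for a census-style complete
enumeration; validating against another *sampled* table would need a
two-sample interval and is not what this check is for.  Calibration is
verified empirically: validating a generated spine against the expected
counts of its own household-size distribution fails ≈ 4–5% of cells at
`alpha = 0.05` (the continuity correction makes the test slightly
conservative), and an aggregate validated against itself is always
100% within interval.

## The synthetic spine

The generator's job is to produce data with the statistical structure
the algorithm assumes, plus ground truth to score against.  What it
emulates, per preset:

- **Geography**: a strict OA < LSOA < MSOA < LA forest.  The
  `ons-definitional` preset encodes the ONS rules — OAs of ≥ 100
  residents (and ≥ 40 households), LSOAs of 4–6 OAs holding
  1,000–3,000 residents averaging 1,500 residents in ~650 households,
  MSOAs of 4–5 LSOAs holding ≥ 5,000; `wales-2016` fixes 1,909 LSOAs
  in 22 local authorities, 3,113,150 residents, LSOA sizes in
  [900, 4,512] averaging 1,631.  The `toy` preset scales the same
  machinery down to a few hundred people for tests.
- **Allocation**: LSOA populations are drawn (shifted-lognormal under a
  fixed national total, truncated-normal otherwise), repaired into
  bounds and to MSOA minimums, and made to sum *exactly* to the total
  by largest-remainder rounding — exactness is what makes calibration
  targets checkable as integer identities.  Households are drawn iid
  from the preset's size distribution until each LSOA quota is met (the
  last household is trimmed to land exactly; a ~1-in-650 distortion).
  The default size mix {1: .310, 2: .350, 3: .155, 4: .120, 5: .042,
  6: .013, 7: .006, 8: .004} has mean 2.32, matching the 1,500-resident
  / 650-household LSOA average.
- **Dynamics** (none dictated by geography; set near UK magnitudes and
  exposed in `SpineDynamics`): whole-household moves at hazard
  0.10/household-year; solo departures of adults at 0.03/adult-year
  (including children who come of age mid-window); births at
  0.055/woman-year for resident women aged 15–44, joining the mother's
  household at birth; maternal-id coverage 0.95; 80% of household
  moves stay within the origin local authority.  The observation window
  defaults to 2000-01-01 – 2016-12-31.  `total_population` is the
  resident count at the window start; later births and communal
  admissions add people, as in a real spine.
- **Communal establishments** (default 1% of window-start residents):
  student halls (capacity 80–250, ages 18–22, full cohort turnover
  every 15 September) and care homes (capacity 20–60, entry ages
  75–95, stays exponential with mean two years, 85% of completed stays
  ending in death).  Their window-start occupancy is carved out of the
  hosting LSOA's quota so area totals stay exact.  A tenth of private
  dwellings sit as children under block-of-flats parent dwellings.
- **Registration noise** (applied separately by `inject_noise`, so
  clean truth always exists): stale move-outs at rate 0.03 (sized to
  the observed Welsh registration excess of ~2.7%), duplicate
  overlapping registrations at 0.01, and child-registered-first shifts
  on 10% of whole-household moves with lags uniform on 1–60 days.

What it does **not** emulate: real address geography or UPRN semantics,
mortality outside care homes, fertility clustering, immigration or
emigration, seasonal moves, multi-generational re-merging of
households, or correlated GP-practice-level recording quirks.  Passing
tests therefore demonstrate algorithmic correctness under the stated
assumptions — exact recovery of known composition, conservation laws,
calibrated validation — not performance on real Welsh data.

Determinism: all randomness flows from one seed through named
substreams per module (geography, population, noise), so regenerating
with the same preset and seed is byte-identical and module order is
irrelevant.

## Numerical and degenerate-input choices

- Episode construction is exact integer/day arithmetic; no floating
  tolerance is involved anywhere in the core algorithm.  Rates
  (changes/year) use a 365.25-day year.
- Zero-length spells (including those created by same-day truncation
  ties) are dropped; an empty input produces an empty output of the
  documented schema at every stage.
- Bounds repair (largest remainder, then clip-and-redistribute) is
  guaranteed to terminate when the preset is feasible
  (`n·min ≤ total ≤ n·max`); infeasible presets raise immediately.
- The day-scan oracle in the test suite recomputes occupancy one probe
  at a time straight from the spells, sharing no code with the episode
  builder it audits.

## Problem sizes used in the checks

The test suite exercises toy spines (~160 people) for exhaustive
oracle comparisons, 30-LSOA definitional spines (~45,000 people) for
recovery and classification checks, and a 400-LSOA spine over a
two-year window for validation calibration (2,000 cells).  The
calibration script regenerates the full 1,909-LSOA Welsh spine
(3.1M people, ~9M spells, ~45 s) and a 200-LSOA definitional spine
with full episode construction (~20 s).  Reported recovery under
default noise: total-variation distance between noisy and clean
snapshot size distributions below 0.02 (observed ≈ 0.0003, stable
across seeds to ±0.01).

## Known limitations

- Vacancy handling, the adulthood threshold, co-move windows and all
  classifier thresholds are conventions, not estimates; sensitivity to
  them should be part of any substantive analysis.
- Candidate-father inference is structurally blind to births predating
  data coverage and to non-resident fathers.
- Suppression is primary only; complementary suppression must be
  applied before genuine release.
- The validation statistic assumes the reference is a complete count;
  against sampled references it will over-reject.
- Classifier thresholds were chosen for separability on synthetic
  signatures; real communal residences are messier (mixed-use
  buildings, staff residents, respite stays).
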