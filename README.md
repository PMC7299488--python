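# halflink

Longitudinal household construction from anonymised administrative
residence data.

Population databanks that link routinely collected health and
administrative records (GP registrations, birth records, demographic
spines) know *who* lives *where* and *when* — each person carries a
de-identified identifier (an ALF-style code), each address a
de-identified dwelling code (a RALF-style code derived from the UPRN),
and each registration a move-in and move-out date.  What they do not
directly contain is the *household*: the group of people sharing an
address at the same time, followed over years as members arrive, leave,
are born, die, or move away together.  Household context matters for
epidemiology — living with a smoker, caring for an ill relative,
unstable housing in childhood — but censuses measure it only once a
decade and surveys only for small samples.

`halflink` implements a household-construction algorithm for exactly
this setting, intended for researchers and data scientists working with
population spines who need household-level covariates without access to
identifiable data.

## The algorithm

A household is defined as *one person living alone or a group of people
(not necessarily related) living at the same address, the address being
the same dwelling identifier* — a modification of the census definition
that drops the unobservable "common housekeeping" clause.

1. **Spell cleaning.**  Raw registration spells carry known defects:
   never-closed registrations at an old practice, double registrations,
   children registered at a new address before their parents.  Cleaning
   truncates overlaps (the most recent registration is presumed
   current), censors open ends, and flags every repair, so that each
   person occupies exactly one dwelling per day.
2. **Episode segmentation.**  Each dwelling's timeline is cut at every
   arrival and departure into *episodes* — maximal intervals with a
   constant, non-empty occupant set.
3. **Versioned household identifiers (HALFs).**  Adjacent episodes at
   one dwelling that share at least one occupant carry the same
   household identifier with an incremented version: household H,
   versions H.1, H.2, ... H.n.  The version count per unit time is a
   direct measure of household stability.  Cross-sectional *snapshots*
   (who lived in which household on date *t*) and longitudinal views
   both fall out of this representation.
4. **Lineage and family inference.**  Groups who leave one dwelling and
   appear at another within a short window (*co-moves*) chain household
   identifiers across addresses; households that move together
   repeatedly are flagged as probable families.  Recorded maternal
   identifiers yield mother–child links; an adult male resident in the
   child's household from or before the birth is a *candidate* father
   (a significant relationship, not asserted paternity); chained
   maternal identifiers give siblings and grandmothers, and planar
   LSOA-centroid distances quantify separation of non-coresident kin.
5. **Communal classification.**  Student halls, care homes and blocks
   of flats leave distinctive occupancy signatures (September cohort
   churn; elderly residents with death-coincident exits; parent/child
   dwelling structure).  A transparent rule cascade labels every
   dwelling.
6. **Disclosure-controlled release.**  Household-size aggregates
   (bands 1/2/3/4/5+) per LSOA/MSOA/LA at a chosen date, with small
   cells suppressed, validated cell-by-cell against census-style
   reference tables using continuity-corrected binomial confidence
   intervals at the 95% level.

Because the real spine cannot leave its safe setting, the package ships
a **synthetic spine generator** that reproduces the structure the
algorithm assumes: the ONS geography hierarchy (OA/LSOA/MSOA/LA with
their mandated size rules, including the 2016 Welsh configuration of
1,909 LSOAs in 22 local authorities holding 3,113,150 residents),
realistic household-size mixes, household moves, solo departures,
births, communal establishments, and the GP-registration defects listed
above — with ground truth emitted separately for evaluation.

## Worked example

Generate a small noisy spine and run the full pipeline:

```sh
$ spine generate --preset toy --seed 1 --out demo/in --noise stale=0.03,dup=0.01,childfirst=0.1
spine 'toy' seed 1: 156 persons, 219 dwellings, 429 spells -> demo/in

$ half run --in demo/in --out demo/out
episodes=267; stability=210; comoves=72; lineages=142; family_links=80; communal=210; aggregates=10

$ half snapshot --episodes demo/out/episodes.csv --at 2008-06-15
79 households at 2008-06-15; 155 residents
```

The 429 registration spells of 156 people resolve into 267
constant-composition episodes grouped under 210 versioned household
identifiers; 72 co-move events chain them into 142 lineages, of which
22 moved together repeatedly and are flagged as probable families.  The
snapshot shows the cross-sectional view: on 15 June 2008 the spine holds
79 households containing 155 of the 156 people (the last is born later
in the observation window).  `demo/out/aggregates.csv` holds the
suppression-ready size-band counts per LSOA and `manifest.json` records
input hashes, configuration and row counts for reproducibility.

The same stages are available as library functions
(`halflink.clean_spells`, `build_episodes`, `assign_half_ids`,
`snapshot`, `stability`, and the `family`, `communal`, `release`
modules) operating on pandas DataFrames.

## Documentation

`docs/methods.md` describes the model and its assumptions, every
tunable parameter with its default and rationale, what the synthetic
spine does and does not emulate, and known limitations.
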