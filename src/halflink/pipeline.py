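"""End-to-end pipeline: clean -> episodes -> half ids -> family -> communal -> release.

Reads the spine tables from an input directory, runs every stage under
one :class:`~halflink.config.RunConfig`, writes all output tables plus a
manifest (input hashes, configuration, row counts).  Deterministic:
identical inputs and configuration give byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import communal, family, household, io, release
from .config import RunConfig

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def run_pipeline(config: RunConfig, in_dir, out_dir) -> dict:
    """Execute the full household-construction pipeline.

    Expects persons.csv, dwellings.csv, geography.csv and spells.csv in
    ``in_dir``; writes episodes, stability, comoves, lineages, family
    links, communal classifications, aggregates, validation verdicts
    (when ``reference.csv`` is present) and ``manifest.json`` to
    ``out_dir``.  Returns the manifest row counts.  Schema violations
    raise :class:`halflink.io.SchemaError` naming the offending file.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    paths = {name: in_dir / f"{name}.csv"
             for name in ("persons", "dwellings", "geography", "spells")}
    persons = io.read_persons(paths["persons"])
    dwellings = io.read_dwellings(paths["dwellings"])
    geography = io.read_geography(paths["geography"])
    raw = io.read_spells(paths["spells"])

    spells = household.clean_spells(
        raw, config.censor_date, persons=persons, adult_age=config.adult_age
    )
    episodes = household.build_episodes(
        spells, persons=persons, adult_age=config.adult_age
    )
    episodes = household.assign_half_ids(
        episodes, allow_gap_days=config.continuity.allow_gap_days
    )
    stab = household.stability(episodes)

    comoves = family.detect_comoves(
        spells, persons,
        window_days=config.comove.window_days,
        min_movers=config.comove.min_movers,
    )
    lineages = family.link_lineages(
        episodes, comoves, family_min_comoves=config.family_min_comoves
    )
    mother = family.link_mother_child(persons, episodes, dwellings, geography,
                                      at=config.censor_date)
    fathers = family.infer_candidate_father(
        persons, episodes, mother, adult_age=config.adult_age
    )
    extended = family.link_extended_family(persons, episodes)
    links = pd.concat([mother, fathers, extended], ignore_index=True)

    feats = communal.occupancy_features(episodes, persons, dwellings)
    types = communal.classify(feats)

    excl = None
    if config.release.exclude_communal:
        excl = types.loc[types["predicted_type"] != "private", "dwelling_id"]
    agg = release.aggregate_households(
        episodes, dwellings, geography,
        at=config.censor_date, level=config.release.level,
        exclude_dwellings=excl,
    )
    agg = release.suppress(agg, threshold=config.release.suppress_threshold)

    io.write_episodes(episodes, out_dir / "episodes.csv")
    io.write_table(stab, out_dir / "stability.csv")
    comoves_out = comoves.copy()
    comoves_out["movers"] = comoves_out["movers"].map("|".join)
    io.write_table(comoves_out, out_dir / "comoves.csv")
    lineages_out = lineages.copy()
    lineages_out["half_bases"] = lineages_out["half_bases"].map("|".join)
    io.write_table(lineages_out, out_dir / "lineages.csv")
    io.write_table(links, out_dir / "family_links.csv")
    io.write_table(types, out_dir / "communal.csv")
    io.write_aggregates(agg, out_dir / "aggregates.csv")

    tables = {
        "episodes": episodes, "stability": stab, "comoves": comoves,
        "lineages": lineages, "family_links": links, "communal": types,
        "aggregates": agg,
    }
    ref_path = in_dir / "reference.csv"
    if ref_path.exists():
        reference = io.read_reference(ref_path)
        verdicts, summary = release.validate_aggregates(
            agg, reference, alpha=config.release.alpha
        )
        io.write_table(verdicts, out_dir / "validation.csv")
        tables["validation"] = verdicts
        logger.info(
            "validation: %d/%d cells within CI (%.1f%%), %d unmatched",
            summary.n_within, summary.n_cells,
            100 * summary.proportion_within, summary.n_unmatched,
        )

    row_counts = {k: int(len(v)) for k, v in tables.items()}
    io.write_manifest(
        out_dir / "manifest.json",
        inputs={k: p for k, p in paths.items()},
        config=config.model_dump(),
        row_counts=row_counts,
    )
    return row_counts
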