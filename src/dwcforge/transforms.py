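"""Bespoke altered transforms for the extension files, and the pipeline
orchestrator that turns a checklist + mapping spec into an archive bundle.

The taxon core is columnar (one row per taxon); the Distribution extension
is an *unpivot*: the wide per-region presence columns become one row per
(taxon, region) pair with a presence code that recodes to a non-skip
occurrence status. The Species Profile extension recodes a habitat code into
aquatic/terrestrial flags, and the Description extension collects the three
source fields with no matching Darwin Core term (native range, pathway,
invasion stage) as typed description rows.
"""

from __future__ import annotations

import re
from typing import Mapping, Optional, Sequence

from .core import (
    ArchiveBundle,
    DescriptionRow,
    DistributionRow,
    MappingError,
    MappingSpec,
    RegionBinding,
    SourceChecklist,
    SpeciesProfileRow,
    TaxonCoreRow,
    TERM_ORDERS,
)
from .mapping import (
    MappedTable,
    _lookup_code,
    apply_rule,
    mint_taxon_id,
    post_process,
)
from .vocab import check_event_date

__all__ = [
    "SKIP",
    "build_event_date",
    "unpivot_presence",
    "map_habitat_flags",
    "build_description_rows",
    "map_checklist",
]

# Sentinel status in a presence value map meaning "emit no distribution row".
SKIP = "absent-skip"

_YEAR_RE = re.compile(r"(\d{4})")


def _extract_year(text: str) -> Optional[str]:
    """First 4-digit year in a possibly annotated date cell, or None.

    Source checklists annotate dates ("ca. 1813", "1970?", "<2000"); the
    pre-parse strips the annotation and keeps the year. Unparseable cells
    yield no value.
    """
    m = _YEAR_RE.search(text)
    return m.group(1) if m else None


def build_event_date(first_record: str, most_recent_record: str) -> Optional[str]:
    """ISO 8601 eventDate from first/most-recent observation years.

    Both years, distinct -> ``FR/MRR`` interval; equal -> the single year
    (a zero-length interval is legal ISO 8601 but noisy); only one -> that
    year; neither -> no value. A most-recent record earlier than the first
    record is a mapping error, not a silently reversed interval.
    """
    fr = _extract_year(first_record) if first_record else None
    mrr = _extract_year(most_recent_record) if most_recent_record else None
    if fr is None and mrr is None:
        return None
    if fr is None:
        return mrr
    if mrr is None:
        return fr
    if int(mrr) < int(fr):
        raise MappingError(
            f"reversed interval: most recent record {mrr} predates first record {fr}"
        )
    value = fr if fr == mrr else f"{fr}/{mrr}"
    verdict = check_event_date(value)
    if not verdict:  # unreachable for year inputs, kept as a guard
        raise MappingError(f"built eventDate {value!r} fails ISO 8601: {verdict.reason}")
    return value


def unpivot_presence(
    record: Mapping[str, str],
    region_map: Sequence[RegionBinding],
    presence_value_map: Mapping[str, str],
    taxon_id: str,
    constants: Mapping[str, str],
    event_date: Optional[str],
    policy: str = "error",
    row_index: int = -1,
) -> list[DistributionRow]:
    """One DistributionRow per region whose presence code maps to a non-skip
    occurrence status.

    Empty presence cells and codes mapped to the skip sentinel produce no
    row; unknown codes follow the unknown-code policy.
    """
    rows: list[DistributionRow] = []
    for binding in region_map:
        code = record.get(binding.source_column, "").strip()
        if code == "":
            continue
        status = _lookup_code(
            code, presence_value_map, f"presence:{binding.source_column}",
            row_index, policy,
        )
        if status is None or status == SKIP:
            continue
        rows.append(DistributionRow(
            taxonID=taxon_id,
            locationID=binding.location_id,
            locality=binding.locality,
            countryCode=constants.get("countryCode", ""),
            occurrenceStatus=status,
            establishmentMeans=constants.get("establishmentMeans", ""),
            eventDate=event_date or "",
        ))
    return rows


def map_habitat_flags(
    habitat: str,
    habitat_value_map: Mapping[str, Sequence[str]],
    is_marine: str = "FALSE",
) -> Optional[tuple[str, str, str]]:
    """(isMarine, isFreshwater, isTerrestrial) flags, or None when the
    habitat code is empty or unmapped (no species-profile row is emitted
    rather than a row of guesses)."""
    code = habitat.strip()
    if code == "" or code not in habitat_value_map:
        return None
    freshwater, terrestrial = habitat_value_map[code]
    return (is_marine, str(freshwater), str(terrestrial))


_DESCRIPTION_FIELDS = (
    # (value-map name, source field key in the map config, description type)
    ("origin", "native range"),
    ("pathway", "pathway"),
    ("invasion_stage", "invasion stage"),
)


def build_description_rows(
    record: Mapping[str, str],
    spec: MappingSpec,
    taxon_id: str,
    policy: Optional[str] = None,
    row_index: int = -1,
) -> list[DescriptionRow]:
    """Typed description rows for the three source fields without a matching
    Darwin Core term: origin -> native range, vector of introduction ->
    pathway, degree of naturalization -> invasion stage.

    Multi-valued cells split on the configured separator into one row per
    value, preserving source order. Empty fields contribute nothing.
    """
    policy = policy or spec.unknown_policy
    language = spec.constants.get("language", "en")
    columns = spec.value_maps.get("description_columns", {})
    rows: list[DescriptionRow] = []
    for map_name, dtype in _DESCRIPTION_FIELDS:
        source_column = columns.get(map_name)
        if source_column is None:
            continue
        cell = record.get(source_column, "").strip()
        if cell == "":
            continue
        mapping = spec.value_map(map_name)
        for code in cell.split(spec.multi_value_separator):
            code = code.strip()
            if code == "":
                continue
            value = _lookup_code(code, mapping, map_name, row_index, policy)
            if value is None:
                continue
            rows.append(DescriptionRow(
                taxonID=taxon_id, description=value, type=dtype, language=language,
            ))
    return rows


# ---------------------------------------------------------------------------
# Whole-checklist pipeline
# ---------------------------------------------------------------------------

def map_checklist(
    checklist: SourceChecklist,
    spec: MappingSpec,
    metadata=None,
) -> ArchiveBundle:
    """Run the full mapping: mint IDs, build the taxon core columnwise, then
    the three extensions row-wise, and assemble the star schema.

    Deterministic: two runs on identical inputs produce equal bundles, and
    the serialized archives are byte-identical.
    """
    constants = spec.constants
    name_column = spec.value_maps.get("source_columns", {}).get("scientific_name", "taxon")
    kingdom = constants.get("kingdom", "")

    taxon_ids = [
        mint_taxon_id(record[name_column].strip(), kingdom, spec.dataset_shortname)
        for record in (checklist.record(i) for i in range(checklist.n_rows))
    ]

    # --- taxon core: declarative rules, column by column ---
    table = MappedTable(source=checklist)
    for rule in spec.rules_for("core"):
        if rule.target_term == "taxonID":
            table.columns[("core", "taxonID")] = list(taxon_ids)
            table.provenance[("core", "taxonID")] = rule
            continue
        apply_rule(rule, table, spec)
    core_records = post_process(table, {"core": TERM_ORDERS["core"]})["core"]
    core_rows = [TaxonCoreRow(**{k: v for k, v in rec.items()}) for rec in core_records]

    # --- extensions, record by record ---
    date_columns = spec.value_maps.get("source_columns", {})
    fr_col = date_columns.get("first_record", "FR")
    mrr_col = date_columns.get("most_recent_record", "MRR")
    habitat_col = date_columns.get("habitat", "habitat")

    distribution: list[DistributionRow] = []
    speciesprofile: list[SpeciesProfileRow] = []
    description: list[DescriptionRow] = []
    presence_map = spec.value_maps.get("presence", {})
    habitat_map = spec.value_maps.get("habitat", {})

    for i in range(checklist.n_rows):
        record = checklist.record(i)
        taxon_id = taxon_ids[i]
        try:
            event_date = build_event_date(
                record.get(fr_col, ""), record.get(mrr_col, "")
            )
        except MappingError as exc:
            raise MappingError(f"row {i}: {exc}") from exc
        distribution.extend(unpivot_presence(
            record, spec.region_map, presence_map, taxon_id, constants,
            event_date, policy=spec.unknown_policy, row_index=i,
        ))
        flags = map_habitat_flags(
            record.get(habitat_col, ""), habitat_map,
            is_marine=constants.get("isMarine", "FALSE"),
        )
        if flags is not None:
            speciesprofile.append(SpeciesProfileRow(
                taxonID=taxon_id, isMarine=flags[0],
                isFreshwater=flags[1], isTerrestrial=flags[2],
            ))
        description.extend(build_description_rows(record, spec, taxon_id, row_index=i))

    return ArchiveBundle(
        core=core_rows,
        distribution=distribution,
        speciesprofile=speciesprofile,
        description=description,
        metadata=metadata,
    )
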