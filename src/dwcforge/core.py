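"""Shared domain types: source-checklist snapshot, mapping specification and
the Darwin Core star-schema row types.

A checklist passes through the pipeline as *text*: every cell is a string from
the moment it is read until it is written into a CSV data file. Typed
interpretation (dates, booleans, vocabulary membership) happens only inside
transforms and validators, so the raw content is never silently coerced. An
empty cell means "no value": transforms receiving it emit nothing rather than
an empty string.
"""

from __future__ import annotations

import csv
import hashlib
import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "DwcForgeError",
    "ConfigurationError",
    "MappingError",
    "Provenance",
    "SourceChecklist",
    "TermRule",
    "RegionBinding",
    "MappingSpec",
    "TaxonCoreRow",
    "DistributionRow",
    "SpeciesProfileRow",
    "DescriptionRow",
    "EmlMetadata",
    "ArchiveBundle",
    "CORE_TERM_ORDER",
    "DISTRIBUTION_TERM_ORDER",
    "SPECIESPROFILE_TERM_ORDER",
    "DESCRIPTION_TERM_ORDER",
    "OUTPUT_FILES",
    "TAXON_ID_PATTERN",
    "SHORTNAME_PATTERN",
]


class DwcForgeError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(DwcForgeError):
    """A mapping spec, vocabulary or run configuration is invalid."""


class MappingError(DwcForgeError):
    """A rule could not be applied to the data (bad value, bad transform)."""


SHORTNAME_PATTERN = re.compile(r"^[a-z0-9]+(-[a-z0-9]+)*$")
TAXON_ID_PATTERN = re.compile(r"^[a-z0-9]+(-[a-z0-9]+)*:taxon:[0-9a-f]{32}$")

# Output order per file follows the published worked example (taxon file first
# column = language, identifier sixth); the descriptor points the id index at
# the taxonID column explicitly so readers never rely on it being first.
CORE_TERM_ORDER = (
    "language",
    "license",
    "rightsHolder",
    "datasetID",
    "datasetName",
    "taxonID",
    "scientificNameID",
    "scientificName",
    "kingdom",
    "family",
    "taxonRank",
    "nomenclaturalCode",
)
DISTRIBUTION_TERM_ORDER = (
    "taxonID",
    "locationID",
    "locality",
    "countryCode",
    "occurrenceStatus",
    "establishmentMeans",
    "eventDate",
)
SPECIESPROFILE_TERM_ORDER = ("taxonID", "isMarine", "isFreshwater", "isTerrestrial")
DESCRIPTION_TERM_ORDER = ("taxonID", "description", "type", "language")

OUTPUT_FILES = ("core", "distribution", "speciesprofile", "description")


# ---------------------------------------------------------------------------
# Source checklist snapshot
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Provenance:
    """Where a checklist snapshot came from and what it hashed to."""

    source: str
    checksum: str
    retrieved: str = ""


def _canonical_bytes(columns: Sequence[str], rows: Sequence[Sequence[str]]) -> bytes:
    """Canonical serialization used for the provenance checksum.

    Unit separator / record separator framing so that no cell content can be
    confused with the framing itself after escaping is unnecessary (cells come
    from CSV parsing and never contain \\x1f/\\x1e).
    """
    buf = io.StringIO()
    buf.write("\x1f".join(columns))
    buf.write("\x1e")
    for row in rows:
        buf.write("\x1f".join(row))
        buf.write("\x1e")
    return buf.getvalue().encode("utf-8")


@dataclass(frozen=True)
class SourceChecklist:
    """Immutable, rectangular snapshot of a raw source checklist.

    ``columns`` keeps source order; ``rows`` are tuples of cell texts aligned
    with ``columns``. Raw data stay raw: no pipeline stage mutates a snapshot,
    and the checksum can be recomputed at any time to prove it.
    """

    columns: tuple[str, ...]
    rows: tuple[tuple[str, ...], ...]
    provenance: Provenance

    def __post_init__(self) -> None:
        for i, row in enumerate(self.rows):
            if len(row) != len(self.columns):
                raise DwcForgeError(
                    f"checklist is not rectangular: row {i} has {len(row)} cells, "
                    f"expected {len(self.columns)}"
                )

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        columns: Iterable[str],
        records: Iterable[Sequence[str]],
        source: str = "<memory>",
        retrieved: str = "",
    ) -> "SourceChecklist":
        cols = tuple(str(c) for c in columns)
        rows = tuple(tuple(str(c) for c in row) for row in records)
        checksum = hashlib.sha256(_canonical_bytes(cols, rows)).hexdigest()
        return cls(cols, rows, Provenance(source, checksum, retrieved))

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        delimiter: str = ",",
        encoding: str = "utf-8",
        retrieved: str = "",
    ) -> "SourceChecklist":
        path = Path(path)
        with path.open("r", encoding=encoding, newline="") as fh:
            reader = csv.reader(fh, delimiter=delimiter)
            try:
                header = next(reader)
            except StopIteration:
                raise DwcForgeError(f"{path}: file is empty, no header row")
            width = len(header)
            rows = []
            for row in reader:
                # A short row from a trailing-comma-less writer is padded so the
                # snapshot stays rectangular; genuinely ragged rows are refused.
                if len(row) < width:
                    row = row + [""] * (width - len(row))
                elif len(row) > width:
                    raise DwcForgeError(
                        f"{path}: row {len(rows)} has {len(row)} cells, header has {width}"
                    )
                rows.append(row)
        return cls.from_records(header, rows, source=str(path), retrieved=retrieved)

    # -- access -------------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def record(self, index: int) -> dict[str, str]:
        """Row ``index`` as a column-name -> cell mapping.

        With duplicate column names the last occurrence wins; duplicates are
        an audit finding and must be resolved source-side before mapping.
        """
        return dict(zip(self.columns, self.rows[index]))

    def column(self, name: str) -> tuple[str, ...]:
        try:
            idx = self.columns.index(name)
        except ValueError:
            raise ConfigurationError(f"checklist has no column {name!r}")
        return tuple(row[idx] for row in self.rows)

    def recompute_checksum(self) -> str:
        return hashlib.sha256(_canonical_bytes(self.columns, self.rows)).hexdigest()

    def with_data(
        self, columns: Sequence[str], rows: Sequence[Sequence[str]]
    ) -> "SourceChecklist":
        """A NEW snapshot derived from this one (provenance notes the parent)."""
        return SourceChecklist.from_records(
            columns,
            rows,
            source=f"derived:{self.provenance.source}",
            retrieved=self.provenance.retrieved,
        )

    def to_csv(self, path: str | Path, delimiter: str = ",") -> None:
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
            writer.writerow(self.columns)
            writer.writerows(self.rows)


# ---------------------------------------------------------------------------
# Mapping specification
# ---------------------------------------------------------------------------

RULE_KINDS = ("static", "unaltered", "altered")
UNKNOWN_POLICIES = ("error", "skip", "flag")


@dataclass(frozen=True)
class TermRule:
    """One declarative mapping rule: how a single Darwin Core term in a single
    output file gets its value.

    static    -> ``value`` on every record, no source columns
    unaltered -> byte-identical copy of exactly one source column
    altered   -> ``transform`` applied to one or more source columns
    """

    target_term: str
    target_file: str
    kind: str
    source_columns: tuple[str, ...] = ()
    value: Optional[str] = None
    transform: Optional[str] = None
    transform_params: Mapping[str, object] = field(default_factory=dict)
    vocabulary: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise ConfigurationError(
                f"rule for {self.target_term!r}: kind must be one of {RULE_KINDS}, got {self.kind!r}"
            )
        if self.target_file not in OUTPUT_FILES:
            raise ConfigurationError(
                f"rule for {self.target_term!r}: target_file must be one of {OUTPUT_FILES}, "
                f"got {self.target_file!r}"
            )
        n = len(self.source_columns)
        if self.kind == "static":
            if n != 0:
                raise ConfigurationError(
                    f"static rule for {self.target_term!r} must not reference source columns"
                )
            if self.value is None:
                raise ConfigurationError(
                    f"static rule for {self.target_term!r} needs a fixed value"
                )
        elif self.kind == "unaltered":
            if n != 1:
                raise ConfigurationError(
                    f"unaltered rule for {self.target_term!r} must reference exactly one "
                    f"source column, got {n}"
                )
        else:  # altered
            if n < 1:
                raise ConfigurationError(
                    f"altered rule for {self.target_term!r} must reference at least one source column"
                )
            if not self.transform:
                raise ConfigurationError(
                    f"altered rule for {self.target_term!r} needs a registered transform name"
                )


@dataclass(frozen=True)
class RegionBinding:
    """Binds one wide presence column to a subnational location."""

    source_column: str
    location_id: str
    locality: str

    @property
    def iso_3166_2_code(self) -> str:
        prefix = "ISO_3166-2:"
        if not self.location_id.startswith(prefix):
            raise ConfigurationError(
                f"locationID {self.location_id!r} does not carry the {prefix} prefix"
            )
        return self.location_id[len(prefix):]


@dataclass
class MappingSpec:
    """Declarative description of a whole checklist-to-DwC mapping.

    ``constants`` hold the dataset-level static values (license, datasetID,
    kingdom, ...); ``value_maps`` hold the recode dictionaries for presence,
    habitat, native-range, pathway and invasion-stage codes. The spec is data,
    versioned alongside the source: re-running the pipeline with the same spec
    and source yields byte-identical archives.
    """

    dataset_shortname: str
    constants: dict[str, str] = field(default_factory=dict)
    term_rules: list[TermRule] = field(default_factory=list)
    region_map: list[RegionBinding] = field(default_factory=list)
    value_maps: dict[str, dict] = field(default_factory=dict)
    unknown_policy: str = "error"
    multi_value_separator: str = ","
    version: str = ""

    def __post_init__(self) -> None:
        if not SHORTNAME_PATTERN.match(self.dataset_shortname):
            raise ConfigurationError(
                f"dataset_shortname {self.dataset_shortname!r} must be lowercase "
                "alphanumeric groups joined by single hyphens"
            )
        if self.unknown_policy not in UNKNOWN_POLICIES:
            raise ConfigurationError(
                f"unknown_policy must be one of {UNKNOWN_POLICIES}, got {self.unknown_policy!r}"
            )

    def rules_for(self, target_file: str) -> list[TermRule]:
        return [r for r in self.term_rules if r.target_file == target_file]

    def value_map(self, name: str) -> dict:
        try:
            return self.value_maps[name]
        except KeyError:
            raise ConfigurationError(f"mapping spec has no value map {name!r}")


# ---------------------------------------------------------------------------
# Star-schema row types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonCoreRow:
    taxonID: str
    language: str = ""
    license: str = ""
    rightsHolder: str = ""
    datasetID: str = ""
    datasetName: str = ""
    scientificNameID: str = ""
    scientificName: str = ""
    kingdom: str = ""
    family: str = ""
    taxonRank: str = ""
    nomenclaturalCode: str = ""
    extras: tuple[tuple[str, str], ...] = ()

    def as_cells(self, order: Sequence[str] = CORE_TERM_ORDER) -> list[str]:
        return [getattr(self, term) for term in order]


@dataclass(frozen=True)
class DistributionRow:
    taxonID: str
    locationID: str = ""
    locality: str = ""
    countryCode: str = ""
    occurrenceStatus: str = ""
    establishmentMeans: str = ""
    eventDate: str = ""
    extras: tuple[tuple[str, str], ...] = ()

    def as_cells(self, order: Sequence[str] = DISTRIBUTION_TERM_ORDER) -> list[str]:
        return [getattr(self, term) for term in order]


@dataclass(frozen=True)
class SpeciesProfileRow:
    taxonID: str
    isMarine: str = ""
    isFreshwater: str = ""
    isTerrestrial: str = ""
    extras: tuple[tuple[str, str], ...] = ()

    def as_cells(self, order: Sequence[str] = SPECIESPROFILE_TERM_ORDER) -> list[str]:
        return [getattr(self, term) for term in order]


DESCRIPTION_TYPES = ("native range", "pathway", "invasion stage")


@dataclass(frozen=True)
class DescriptionRow:
    taxonID: str
    description: str = ""
    type: str = ""
    language: str = ""
    extras: tuple[tuple[str, str], ...] = ()

    def as_cells(self, order: Sequence[str] = DESCRIPTION_TERM_ORDER) -> list[str]:
        return [getattr(self, term) for term in order]


ROW_TYPES = {
    "core": TaxonCoreRow,
    "distribution": DistributionRow,
    "speciesprofile": SpeciesProfileRow,
    "description": DescriptionRow,
}

TERM_ORDERS = {
    "core": CORE_TERM_ORDER,
    "distribution": DISTRIBUTION_TERM_ORDER,
    "speciesprofile": SPECIESPROFILE_TERM_ORDER,
    "description": DESCRIPTION_TERM_ORDER,
}


# ---------------------------------------------------------------------------
# Metadata + bundle
# ---------------------------------------------------------------------------

PERMITTED_LICENSES = (
    "http://creativecommons.org/licenses/by/4.0/",
    "https://creativecommons.org/licenses/by/4.0/",
    "http://creativecommons.org/licenses/by-nc/4.0/",
    "https://creativecommons.org/licenses/by-nc/4.0/",
    "http://creativecommons.org/publicdomain/zero/1.0/",
    "https://creativecommons.org/publicdomain/zero/1.0/",
)


@dataclass
class EmlMetadata:
    """Dataset metadata destined for the EML document.

    ``license_uri`` must be one of the three licenses GBIF supports (either
    URI scheme); everything else is free text drafted collaboratively and
    carried through unchanged.
    """

    title: str
    creators: list[dict] = field(default_factory=list)
    abstract: str = ""
    license_uri: str = PERMITTED_LICENSES[4]
    license_name: str = ""
    geographic_coverage: str = ""
    taxonomic_coverage: str = ""
    temporal_coverage: str = ""
    project_description: str = ""
    provenance_statement: str = ""
    pub_date: str = ""

    def __post_init__(self) -> None:
        if self.license_uri not in PERMITTED_LICENSES:
            raise ConfigurationError(
                f"license {self.license_uri!r} is not one of the three GBIF-supported "
                "licenses (CC-BY 4.0, CC-BY-NC 4.0, CC0 1.0)"
            )


@dataclass
class ArchiveBundle:
    """The star schema in memory: taxon core plus the three extensions."""

    core: list[TaxonCoreRow] = field(default_factory=list)
    distribution: list[DistributionRow] = field(default_factory=list)
    speciesprofile: list[SpeciesProfileRow] = field(default_factory=list)
    description: list[DescriptionRow] = field(default_factory=list)
    metadata: Optional[EmlMetadata] = None

    def rows_for(self, target_file: str) -> list:
        if target_file not in OUTPUT_FILES:
            raise ConfigurationError(f"unknown output file {target_file!r}")
        return getattr(self, "core" if target_file == "core" else target_file)

    @property
    def core_ids(self) -> set[str]:
        return {row.taxonID for row in self.core}

    def extension_files(self) -> list[str]:
        return [name for name in OUTPUT_FILES[1:] if self.rows_for(name)]
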