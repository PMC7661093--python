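"""Darwin Core Archive serialization: data files, meta.xml descriptor, EML
metadata, zip bundling, reading back and star-schema validation.

The CSV dialect is fixed — UTF-8, comma, RFC 4180 quoting, LF line endings —
and declared in the descriptor, so any compliant reader is unaffected and a
given bundle always serializes to the same bytes. Row-type and term URIs
are the published Darwin Core / GBIF extension definitions, pinned here.
"""

from __future__ import annotations

import csv
import io
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from lxml import etree

from .core import (
    ArchiveBundle,
    ConfigurationError,
    DwcForgeError,
    EmlMetadata,
    OUTPUT_FILES,
    PERMITTED_LICENSES,
    ROW_TYPES,
    TAXON_ID_PATTERN,
    TERM_ORDERS,
)
from .vocab import VocabularyRegistry, default_registry

__all__ = [
    "Descriptor",
    "FileDeclaration",
    "ValidationReport",
    "build_descriptor",
    "write_data_files",
    "write_meta_xml",
    "write_eml",
    "validate_eml",
    "assemble_archive",
    "read_archive",
    "validate_star_schema",
]

DWC_TERMS_NS = "http://rs.tdwg.org/dwc/terms/"
DC_TERMS_NS = "http://purl.org/dc/terms/"
GBIF_TERMS_NS = "http://rs.gbif.org/terms/1.0/"
DWC_TEXT_NS = "http://rs.tdwg.org/dwc/text/"
EML_NS = "eml://ecoinformatics.org/eml-2.1.1"

ROW_TYPE_URIS = {
    "core": DWC_TERMS_NS + "Taxon",
    "distribution": GBIF_TERMS_NS + "Distribution",
    "speciesprofile": GBIF_TERMS_NS + "SpeciesProfile",
    "description": GBIF_TERMS_NS + "Description",
}

FILE_NAMES = {
    "core": "taxon.csv",
    "distribution": "distribution.csv",
    "speciesprofile": "speciesprofile.csv",
    "description": "description.csv",
}

# Canonical URI per term. Dublin Core terms live in the dcterms namespace,
# GBIF species-profile flags in the GBIF namespace, the rest in dwc terms.
_DC_TERMS = {"language", "license", "rightsHolder", "description", "type"}
_GBIF_TERMS = {"isMarine", "isFreshwater", "isTerrestrial"}


def term_uri(term: str) -> str:
    if term in _DC_TERMS:
        return DC_TERMS_NS + term
    if term in _GBIF_TERMS:
        return GBIF_TERMS_NS + term
    return DWC_TERMS_NS + term


def _term_from_uri(uri: str) -> Optional[str]:
    for ns in (DWC_TERMS_NS, DC_TERMS_NS, GBIF_TERMS_NS):
        if uri.startswith(ns):
            return uri[len(ns):]
    return None


# Vocabulary binding per (file, term) used by the star-schema validator.
BOUND_TERMS = {
    ("core", "language"): "language",
    ("core", "license"): "license",
    ("core", "taxonRank"): "taxonRank",
    ("distribution", "countryCode"): "countryCode",
    ("distribution", "occurrenceStatus"): "occurrenceStatus",
    ("distribution", "establishmentMeans"): "establishmentMeans",
    ("distribution", "eventDate"): "eventDate",
    ("description", "language"): "language",
}


# ---------------------------------------------------------------------------
# Descriptor
# ---------------------------------------------------------------------------

@dataclass
class FileDeclaration:
    row_type: str          # row type URI
    location: str          # file name inside the archive
    terms: list[str]       # column terms, index-aligned with the CSV
    id_index: int          # taxonID column (id in core, coreid in extensions)

    def term_uris(self) -> list[str]:
        return [term_uri(t) for t in self.terms]


@dataclass
class Descriptor:
    core: FileDeclaration
    extensions: list[FileDeclaration] = field(default_factory=list)

    def __post_init__(self) -> None:
        for decl in [self.core, *self.extensions]:
            if not 0 <= decl.id_index < len(decl.terms):
                raise ConfigurationError(
                    f"{decl.location}: id index {decl.id_index} outside column range"
                )


def build_descriptor(bundle: ArchiveBundle) -> Descriptor:
    """Descriptor for the bundle: core + one declaration per non-empty extension."""
    core_terms = list(TERM_ORDERS["core"])
    descriptor = Descriptor(core=FileDeclaration(
        row_type=ROW_TYPE_URIS["core"],
        location=FILE_NAMES["core"],
        terms=core_terms,
        id_index=core_terms.index("taxonID"),
    ))
    for name in bundle.extension_files():
        terms = list(TERM_ORDERS[name])
        descriptor.extensions.append(FileDeclaration(
            row_type=ROW_TYPE_URIS[name],
            location=FILE_NAMES[name],
            terms=terms,
            id_index=terms.index("taxonID"),
        ))
    return descriptor


# ---------------------------------------------------------------------------
# Data files
# ---------------------------------------------------------------------------

def _rows_to_csv_bytes(terms, rows) -> bytes:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n", quoting=csv.QUOTE_MINIMAL)
    writer.writerow(terms)
    for row in rows:
        writer.writerow(row.as_cells(terms))
    return buf.getvalue().encode("utf-8")


def write_data_files(bundle: ArchiveBundle, directory: str | Path) -> list[Path]:
    """One CSV per populated row set; header = DwC term names in declared
    order; byte-deterministic for a given bundle. Empty extensions are
    omitted entirely (no file, no descriptor entry)."""
    report = validate_star_schema(bundle)
    if not report.passed:
        raise DwcForgeError(
            "refusing to write an invalid bundle:\n" + report.to_text()
        )
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in OUTPUT_FILES:
        rows = bundle.rows_for(name)
        if name != "core" and not rows:
            continue
        path = directory / FILE_NAMES[name]
        try:
            path.write_bytes(_rows_to_csv_bytes(TERM_ORDERS[name], rows))
        except OSError as exc:
            raise DwcForgeError(f"failed to write {path}: {exc}") from exc
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# meta.xml
# ---------------------------------------------------------------------------

_CSV_ATTRS = {
    "encoding": "UTF-8",
    "fieldsTerminatedBy": ",",
    "linesTerminatedBy": "\\n",
    "fieldsEnclosedBy": '"',
    "ignoreHeaderLines": "1",
}


def _file_element(parent, decl: FileDeclaration, tag: str) -> None:
    el = etree.SubElement(parent, "{%s}%s" % (DWC_TEXT_NS, tag),
                          rowType=decl.row_type, **_CSV_ATTRS)
    files = etree.SubElement(el, "{%s}files" % DWC_TEXT_NS)
    loc = etree.SubElement(files, "{%s}location" % DWC_TEXT_NS)
    loc.text = decl.location
    id_tag = "id" if tag == "core" else "coreid"
    etree.SubElement(el, "{%s}%s" % (DWC_TEXT_NS, id_tag), index=str(decl.id_index))
    for index, uri in enumerate(decl.term_uris()):
        etree.SubElement(el, "{%s}field" % DWC_TEXT_NS, index=str(index), term=uri)


def write_meta_xml(bundle: ArchiveBundle, directory: str | Path) -> Path:
    """Emit the archive descriptor declaring the taxon core and every
    non-empty extension with per-column term URIs and id/coreid indexes."""
    descriptor = build_descriptor(bundle)
    root = etree.Element("{%s}archive" % DWC_TEXT_NS,
                         nsmap={None: DWC_TEXT_NS},
                         metadata="eml.xml")
    _file_element(root, descriptor.core, "core")
    for ext in descriptor.extensions:
        _file_element(root, ext, "extension")
    path = Path(directory) / "meta.xml"
    path.write_bytes(etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ))
    return path


# ---------------------------------------------------------------------------
# EML
# ---------------------------------------------------------------------------

def write_eml(metadata: EmlMetadata, directory: str | Path,
              package_id: str = "") -> Path:
    """Emit dataset metadata as an EML document (GBIF Metadata Profile
    subset: identification, creators, license, coverages, project,
    provenance). The license must be one of the three GBIF-supported URIs.
    """
    if metadata.license_uri not in PERMITTED_LICENSES:
        raise ConfigurationError(
            f"license {metadata.license_uri!r} is not one of the three GBIF-supported licenses"
        )
    nsmap = {"eml": EML_NS}
    root = etree.Element("{%s}eml" % EML_NS, nsmap=nsmap)
    root.set("packageId", package_id or metadata.title.lower().replace(" ", "-"))
    root.set("system", "http://gbif.org")
    root.set("scope", "system")
    dataset = etree.SubElement(root, "dataset")
    etree.SubElement(dataset, "title").text = metadata.title
    for person in metadata.creators:
        creator = etree.SubElement(dataset, "creator")
        individual = etree.SubElement(creator, "individualName")
        if person.get("given_name"):
            etree.SubElement(individual, "givenName").text = person["given_name"]
        etree.SubElement(individual, "surName").text = person.get("surname", "")
        if person.get("organization"):
            etree.SubElement(creator, "organizationName").text = person["organization"]
        if person.get("role"):
            etree.SubElement(creator, "positionName").text = person["role"]
    if metadata.pub_date:
        etree.SubElement(dataset, "pubDate").text = metadata.pub_date
    if metadata.abstract:
        abstract = etree.SubElement(dataset, "abstract")
        etree.SubElement(abstract, "para").text = metadata.abstract
    rights = etree.SubElement(dataset, "intellectualRights")
    para = etree.SubElement(rights, "para")
    para.text = "This work is licensed under "
    ulink = etree.SubElement(para, "ulink", url=metadata.license_uri)
    etree.SubElement(ulink, "citetitle").text = (
        metadata.license_name or metadata.license_uri
    )
    if any([metadata.geographic_coverage, metadata.taxonomic_coverage,
            metadata.temporal_coverage]):
        coverage = etree.SubElement(dataset, "coverage")
        if metadata.geographic_coverage:
            geo = etree.SubElement(coverage, "geographicCoverage")
            etree.SubElement(geo, "geographicDescription").text = (
                metadata.geographic_coverage
            )
        if metadata.temporal_coverage:
            temporal = etree.SubElement(coverage, "temporalCoverage")
            etree.SubElement(temporal, "rangeOfDates").text = metadata.temporal_coverage
        if metadata.taxonomic_coverage:
            taxo = etree.SubElement(coverage, "taxonomicCoverage")
            etree.SubElement(taxo, "generalTaxonomicCoverage").text = (
                metadata.taxonomic_coverage
            )
    if metadata.project_description:
        project = etree.SubElement(dataset, "project")
        etree.SubElement(project, "title").text = metadata.title
        funding = etree.SubElement(project, "abstract")
        etree.SubElement(funding, "para").text = metadata.project_description
    if metadata.provenance_statement:
        methods = etree.SubElement(dataset, "methods")
        step = etree.SubElement(methods, "methodStep")
        desc = etree.SubElement(step, "description")
        etree.SubElement(desc, "para").text = metadata.provenance_statement
    path = Path(directory) / "eml.xml"
    path.write_bytes(etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ))
    return path


def validate_eml(path: str | Path) -> list[str]:
    """Structural conformance check of an emitted EML document.

    Verifies well-formedness, the presence of the profile's required
    elements (title, at least one creator with a name, abstract or
    coverage) and that the license link is one of the three permitted URIs.
    Returns a list of problems (empty = valid).
    """
    problems: list[str] = []
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        return [f"not well-formed XML: {exc}"]
    root = tree.getroot()
    if root.tag != "{%s}eml" % EML_NS:
        problems.append(f"root element is {root.tag}, expected EML")
    dataset = root.find("dataset")
    if dataset is None:
        return problems + ["no <dataset> element"]
    if not (dataset.findtext("title") or "").strip():
        problems.append("missing dataset title")
    creators = dataset.findall("creator")
    if not creators:
        problems.append("no creator")
    elif not any((c.findtext("individualName/surName") or "").strip()
                 for c in creators):
        problems.append("no creator has a surname")
    links = dataset.findall("intellectualRights/para/ulink")
    if not links:
        problems.append("no license link in intellectualRights")
    elif links[0].get("url") not in PERMITTED_LICENSES:
        problems.append(f"license URL {links[0].get('url')!r} is not permitted")
    return problems


# ---------------------------------------------------------------------------
# Zip bundling + reading
# ---------------------------------------------------------------------------

# Fixed timestamp inside the zip: archive bytes depend only on content.
_ZIP_DATE = (2020, 1, 1, 0, 0, 0)


def assemble_archive(directory: str | Path, zip_path: str | Path | None = None) -> Path:
    """Bundle the data files + meta.xml + eml.xml from ``directory`` into a
    Darwin Core Archive zip (files at the archive root, deterministic
    bytes). Refuses to bundle without descriptor or metadata."""
    directory = Path(directory)
    meta = directory / "meta.xml"
    eml = directory / "eml.xml"
    if not meta.exists():
        raise DwcForgeError(f"{directory}: no meta.xml descriptor; write it first")
    if not eml.exists():
        raise DwcForgeError(f"{directory}: no eml.xml metadata; write it first")
    declared = _declared_locations(meta)
    missing = [loc for loc in declared if not (directory / loc).exists()]
    if missing:
        raise DwcForgeError(
            f"{directory}: descriptor references missing data files: {missing}"
        )
    zip_path = Path(zip_path) if zip_path else directory / "dwca.zip"
    members = sorted(declared) + ["meta.xml", "eml.xml"]
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name in members:
            info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            zf.writestr(info, (directory / name).read_bytes())
    return zip_path


def _declared_locations(meta_path: Path) -> list[str]:
    tree = etree.parse(str(meta_path))
    return [el.text for el in tree.iter("{%s}location" % DWC_TEXT_NS)]


def _parse_declaration(el) -> FileDeclaration:
    location = el.findtext("{%s}files/{%s}location" % (DWC_TEXT_NS, DWC_TEXT_NS))
    id_el = el.find("{%s}id" % DWC_TEXT_NS)
    if id_el is None:
        id_el = el.find("{%s}coreid" % DWC_TEXT_NS)
    fields = sorted(
        el.findall("{%s}field" % DWC_TEXT_NS), key=lambda f: int(f.get("index"))
    )
    terms = []
    for f in fields:
        term = _term_from_uri(f.get("term"))
        terms.append(term if term is not None else f.get("term"))
    return FileDeclaration(
        row_type=el.get("rowType"),
        location=location,
        terms=terms,
        id_index=int(id_el.get("index")) if id_el is not None else 0,
    )


@dataclass
class ReadResult:
    bundle: ArchiveBundle
    descriptor: Descriptor
    warnings: list[str] = field(default_factory=list)


def read_archive(zip_path: str | Path) -> ReadResult:
    """Reconstruct an ArchiveBundle from a DwC-A zip, driven by meta.xml
    (never by header guessing). ``read(write(bundle))`` equals the bundle
    field-for-field. Columns with unknown term URIs are preserved verbatim
    in each row's ``extras`` and reported as warnings."""
    warnings: list[str] = []
    with zipfile.ZipFile(zip_path) as zf:
        names = set(zf.namelist())
        if "meta.xml" not in names:
            raise DwcForgeError(f"{zip_path}: no meta.xml — not a Darwin Core Archive")
        root = etree.fromstring(zf.read("meta.xml"))
        core_el = root.find("{%s}core" % DWC_TEXT_NS)
        if core_el is None:
            raise DwcForgeError(f"{zip_path}: descriptor declares no core file")
        core_decl = _parse_declaration(core_el)
        if core_decl.row_type != ROW_TYPE_URIS["core"]:
            raise DwcForgeError(
                f"{zip_path}: core row type {core_decl.row_type!r} is not the Taxon core"
            )
        ext_decls = [
            _parse_declaration(el)
            for el in root.findall("{%s}extension" % DWC_TEXT_NS)
        ]
        uri_to_name = {uri: name for name, uri in ROW_TYPE_URIS.items()}
        bundle = ArchiveBundle()
        for decl, file_key in [(core_decl, "core")] + [
            (d, uri_to_name.get(d.row_type)) for d in ext_decls
        ]:
            if file_key is None:
                warnings.append(
                    f"unknown extension row type {decl.row_type!r}; skipped"
                )
                continue
            if decl.location not in names:
                raise DwcForgeError(
                    f"{zip_path}: descriptor references {decl.location!r} "
                    "which is not in the archive"
                )
            text = zf.read(decl.location).decode("utf-8")
            reader = csv.reader(io.StringIO(text))
            header = next(reader, None)
            if header is None:
                continue
            row_cls = ROW_TYPES[file_key]
            known = set(TERM_ORDERS[file_key])
            rows = bundle.rows_for(file_key)
            unknown_terms = [t for t in decl.terms if t not in known]
            for t in unknown_terms:
                warnings.append(
                    f"{decl.location}: unknown term {t!r}; column preserved verbatim"
                )
            for cells in reader:
                kwargs = {}
                extras = []
                for term, cell in zip(decl.terms, cells):
                    if term in known:
                        kwargs[term] = cell
                    else:
                        extras.append((term, cell))
                rows.append(row_cls(extras=tuple(extras), **kwargs))
    return ReadResult(
        bundle=bundle,
        descriptor=Descriptor(core=core_decl, extensions=ext_decls),
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Star-schema validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationFinding:
    rule: str
    severity: str
    file: str
    row: int
    message: str


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    @property
    def errors(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "error"]

    def to_text(self) -> str:
        lines = [f"validation: {'PASSED' if self.passed else 'FAILED'} "
                 f"({len(self.errors)} error(s))"]
        lines += [
            f"  [{f.severity}] {f.rule} in {f.file} row {f.row}: {f.message}"
            for f in self.findings
        ]
        return "\n".join(lines)


def validate_star_schema(
    bundle: ArchiveBundle,
    registry: Optional[VocabularyRegistry] = None,
) -> ValidationReport:
    """Validate the one-core-to-many-extensions star schema.

    Errors: duplicate core taxonIDs, malformed taxonID patterns, orphan
    extension rows (taxonID absent from the core), empty scientificName,
    and vocabulary failures on bound terms. Finding order is deterministic:
    core first, then extensions in declared file order, row-major.
    """
    registry = registry or default_registry()
    report = ValidationReport()

    seen: dict[str, int] = {}
    for i, row in enumerate(bundle.core):
        if not TAXON_ID_PATTERN.match(row.taxonID):
            report.findings.append(ValidationFinding(
                "malformed-taxon-id", "error", "core", i,
                f"taxonID {row.taxonID!r} does not match '<shortname>:taxon:<hex32>'",
            ))
        if row.taxonID in seen:
            report.findings.append(ValidationFinding(
                "duplicate-taxon-id", "error", "core", i,
                f"taxonID {row.taxonID!r} already used by core row {seen[row.taxonID]}",
            ))
        else:
            seen[row.taxonID] = i
        if not row.scientificName.strip():
            report.findings.append(ValidationFinding(
                "empty-scientific-name", "error", "core", i,
                "scientificName is empty",
            ))
        _check_bound_terms(report, registry, "core", i, row)

    core_ids = set(seen)
    for name in OUTPUT_FILES[1:]:
        for i, row in enumerate(bundle.rows_for(name)):
            if row.taxonID not in core_ids:
                report.findings.append(ValidationFinding(
                    "orphan-extension-row", "error", name, i,
                    f"taxonID {row.taxonID!r} does not occur in the taxon core",
                ))
            _check_bound_terms(report, registry, name, i, row)
            if name == "speciesprofile":
                for flag in ("isMarine", "isFreshwater", "isTerrestrial"):
                    value = getattr(row, flag)
                    if value not in ("TRUE", "FALSE"):
                        report.findings.append(ValidationFinding(
                            "malformed-flag", "error", name, i,
                            f"{flag} must be TRUE or FALSE, got {value!r}",
                        ))
            if name == "description" and not row.description.strip():
                report.findings.append(ValidationFinding(
                    "empty-description", "error", name, i, "description is empty",
                ))
    return report


def _check_bound_terms(report, registry, file_key, row_index, row) -> None:
    for (fkey, term), vocab_name in BOUND_TERMS.items():
        if fkey != file_key:
            continue
        value = getattr(row, term, "")
        if value == "":
            continue
        verdict = registry.check_term(vocab_name, value)
        if not verdict:
            report.findings.append(ValidationFinding(
                "vocabulary", "error", file_key, row_index,
                f"{term}={value!r}: {verdict.reason}",
            ))
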