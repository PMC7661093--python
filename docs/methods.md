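# Methods

## The pipeline

`dwcforge` implements a four-stage publication workflow for species
checklists:

1. **Source management** — the raw checklist is read into an immutable,
   rectangular snapshot (`SourceChecklist`) carrying a SHA-256 provenance
   checksum. A tidy-data audit enumerates structural departures from
   one-variable-per-column / one-observation-per-row; only three defect
   classes are auto-fixable (fully empty rows, fully empty columns,
   cell-edge whitespace), and fixing always returns a *new* snapshot —
   raw data stay raw, and the checksum proves it. Everything else
   (duplicate column names, mixed value families) requires a source-side
   correction: the audit refuses to guess.
2. **Mapping** — a declarative `MappingSpec` (YAML, versioned) drives the
   transformation. Rules are static, unaltered or altered (see README);
   each rule appends one Darwin Core term column to the working table, so
   the link between source columns and mapped terms survives until
   post-processing drops the source columns and partitions the output into
   the star-schema row sets.
3. **Documentation** — dataset metadata is authored as a structured YAML
   document and emitted as an EML file covering the GBIF Metadata Profile
   subset actually used for checklists: identification, creators, one of
   the three GBIF-supported licenses (CC-BY 4.0, CC-BY-NC 4.0, CC0 1.0 —
   any other license is refused), geographic/taxonomic/temporal coverage,
   project and provenance statements.
4. **Publication** — data files, `meta.xml` and `eml.xml` are bundled into
   a DwC-A zip. Upload, registration and DOI minting are human steps on
   network services and are out of scope; the `datasetID` constant is
   updated in the mapping spec once a DOI exists and the pipeline re-run.

## Identifier convention

`taxonID = <shortname>:taxon:<digest>` where the digest is MD5 over the
R version-2 XDR serialization of the scientific-name string (a length-1
character vector; 14-byte stream header skipped; ASCII or UTF-8 flag in the
element header as appropriate). This is bit-for-bit what `digest::digest(x)`
computes in R, making identifiers interchangeable with the established
R-based checklist workflows. The convention was frozen by verifying two
independently published reference identifiers (*Acanthus mollis* L. →
`509ddbba…`, *A. spinosus* L. → `a65145fd…`) and a UTF-8 name against the R
implementation directly. The kingdom is part of the identity tuple and is
required non-empty when minting — a half-specified taxon would get an
unstable ID — but under the frozen convention the digest is a function of
the name alone; the package keeps that behaviour rather than a
"nicer-looking" name+kingdom hash precisely because compatibility with the
published identifiers is the point. Consequence worth knowing: homonymous
names across kingdoms would collide. For single-kingdom checklists (the
target use case) this is immaterial; cross-kingdom registries should extend
the shortname per kingdom.

## Parameters that matter

* `unknown_policy` (`error` | `skip` | `flag`, default **error**) — what an
  altered rule does with a source code missing from its value map. The
  default is deliberate: checklist updates introduce new codes, and the
  review workflow should see a hard failure (or a flagged `UNMAPPED:` value
  under `flag`), never a silent drop.
* `multi_value_separator` (default `","`) — splits multi-valued origin and
  pathway cells into one description row per value, preserving order.
* Region bindings — each wide presence column is bound to an ISO 3166-2
  location (`presence_Fl` → `BE-VLG` "flemish region", `presence_Br` →
  `BE-BRU` "brussels-capital region", `presence_Wa` → `BE-WAL` "walloon
  region"). Only the Flemish binding appears in the published mapping
  table; the other two codes are ISO 3166-2 registry lookups.
* Source code tables (presence, habitat, origin, pathway, invasion stage)
  are configuration data in the mapping spec, since the upstream encodings
  are publisher-specific. The shipped case-study maps use `X`/`?`/`-` for
  present/doubtful/skip, `T`/`F`/`T/F` habitat codes, level-1 WGSRPD
  origin codes, abbreviated vectors (`Hort.` → CBD escape-from-horticulture,
  …) and `Cas.`/`Nat.`/`Inv.` stages; the published output cells are the
  fixed points these choices reproduce.

## Dates

`eventDate` is built from first-record and most-recent-record cells. A
pre-parse extracts the first 4-digit year from annotated cells
("ca. 1813", "1970?"); unparseable cells yield no value. Both years
distinct → `FR/MRR`; equal → the single year (a zero-length interval is
legal ISO 8601 but noisy); one year → that year; a most-recent record
earlier than the first record raises rather than emitting a reversed
interval. The grammar accepted is `YYYY`, `YYYY-MM`, `YYYY-MM-DD` and
`start/end` intervals, forward-running at the stated precision (calendar
validity of full dates is delegated to `datetime.date`).

## Vocabularies

All controlled vocabularies ship as pinned text files with `source` and
`version` headers: ISO 3166-1 alpha-2 (all 249 officially assigned codes),
ISO 3166-2:BE, ISO 639-1 (184 codes), the GBIF rank / occurrence-status /
establishment-means vocabularies (matched case-sensitively in their
canonical lowercase), WGSRPD level-1 codes, the CBD 2014 pathway
classification (as `cbd_2014_pathway:` terms) and the invasion-stage
degrees of establishment. The pathway and invasion-stage lists follow the
cited classifications' structure and are replaceable data files. Grammar
vocabularies (eventDate, the `<area> (WGSRPD:n)` native-range form) are
code, registered alongside.

## Validation

`validate_star_schema` reports, in deterministic order (core first, then
extensions, row-major): duplicate core `taxonID`s (one error per extra
occurrence), malformed identifier patterns, empty scientific names, orphan
extension rows, vocabulary failures on bound terms, and malformed
TRUE/FALSE flags. `write_data_files` refuses invalid bundles, so a written
archive is a validated archive. The EML check is structural (required
elements, permitted license URIs, well-formedness) rather than XSD
validation: the package does not carry the multi-file EML schema set, and
the subset emitted is fixed, so the structural check covers exactly what
the emitter can produce.

## Synthetic data

The generator emulates the source schema of a regional alien-plants
checklist: unique synthesized names ("Genus epithet Auth." from pooled
syllables — no real-taxon dependence, hence stable digests), one family
and rank per row, an LSID-style name identifier, three per-region presence
columns, first/most-recent years (first ≤ most recent; ~10% missing first
records), and coded origin/stage/pathway/habitat cells (~15% of pathways
multi-valued; one habitat code deliberately unmappable to exercise the
skip path). Defects — empty rows, edge whitespace, unknown presence codes,
reversed date pairs, duplicate rows, an empty extra column — are injected
*after* clean generation and recorded one-by-one in a ledger together with
the exact downstream counts (non-skip presence cells, mappable habitats,
expected description rows). Tests therefore assert against the generator's
own bookkeeping, never against a re-implementation of the pipeline.

What the generator does *not* emulate: real nomenclature (synonyms,
homonyms, hybrids), free-text habitat or pathway descriptions, multi-sheet
spreadsheets, or encoding corruption. Passing tests show the pipeline's
algebra, bookkeeping and serialization are exact on schema-conformant
inputs; they do not show robustness to arbitrarily malformed real-world
spreadsheets, which the audit stage is designed to surface for human
correction instead.

Default problem sizes used by the test suite and the acceptance script —
checklists of 200 taxa across ten seeds for the counting and validation
properties, 60–80 taxa for byte-identity and round-trip checks — keep every
property exact (they are equality assertions, not statistical ones) while
the whole suite runs in seconds.

## Numerical / representational choices

* Cells are text end-to-end; an empty cell is "no value" and transforms
  emit nothing for it (extensions omit absent information rather than
  writing empty strings).
* CSV dialect fixed and declared in the descriptor: UTF-8, comma,
  RFC 4180 quoting, LF. Zip entries carry a fixed timestamp. Together
  with the content-derived IDs this makes whole-archive output a pure
  function of (source, spec, metadata).
* The taxon-core column order follows the published mapping table
  (`language` first, `taxonID` sixth); `meta.xml` points the `id` index at
  the `taxonID` column explicitly, so readers never assume it is first.
* Capitalization is preserved from the source; the all-lowercase rendering
  of some published table cells is treated as journal typesetting.
* Habitat codes missing from the habitat map always use skip semantics
  (no species-profile row) rather than the unknown-code policy: an absent
  profile row is the defined representation of "habitat unknown", not an
  error state.

## Known limitations

* No taxonomic name parsing, backbone matching or synonym modelling — the
  aggregator does that after publication.
* No network steps (IPT upload, GBIF registration, DOI minting).
* The EML conformance check is structural, not schema validation (above).
* `read_archive` handles the archive layout this package writes plus
  unknown extra columns (preserved verbatim with warnings); it is not a
  general-purpose reader for arbitrary third-party archives (multi-file
  cores, non-CSV dialects beyond the declared attributes).
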