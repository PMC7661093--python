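# dwcforge

Turn a traditional species checklist — a spreadsheet with one row per taxon —
into a validated, publication-ready **Darwin Core Archive** (DwC-A): a taxon
core plus Distribution, Species Profile and Description extensions, a
`meta.xml` descriptor and an EML metadata document, bundled as a zip that any
GBIF-compatible publishing tool (e.g. an IPT) auto-maps from its headers.

It is written for data publishers in biodiversity informatics who maintain
checklists (alien-species registries, regional floras, taxonomic inventories)
and want the transformation to Darwin Core to be **declarative, reproducible
and idempotent**: the raw source snapshot is immutable, every term mapping is
configuration rather than code, and re-running the pipeline on identical
inputs yields byte-identical archives — so a diff of the processed files
shows exactly what a source update changed.

## The model

The archive is a **star schema**: one core table of taxa keyed by `taxonID`,
and extension tables whose rows each reference a core `taxonID`
(one-to-many). Three kinds of term mapping cover everything:

* **static** — a fixed value for every record (`license`, `datasetID`,
  `kingdom`, …);
* **unaltered** — a byte-identical copy of one source column
  (`scientificName` ← `taxon`, `family` ← `family`);
* **altered** — a transformation of one or more source columns, usually a
  recode into a controlled vocabulary: ISO 3166 for `countryCode` and
  `locationID`, ISO 8601 for `eventDate`, the GBIF vocabularies for
  `taxonRank` / `occurrenceStatus` / `establishmentMeans`, WGSRPD area codes
  for native ranges, the CBD pathway classification and the unified
  invasion-framework degrees of establishment. All vocabularies ship as
  pinned, versioned data files; nothing is fetched at run time.

Identifiers are minted from content, not from row numbers:

```
taxonID = <dataset shortname>:taxon:<32-hex digest of the scientific name>
```

The digest is the MD5 of the name string under R's value-serialization
framing — the exact quantity R's `digest()` computes — so archives built
here are digest-compatible with the widely used R checklist workflows, and
an ID never shifts when taxa are inserted, removed or reordered.

Four bespoke transforms build the extensions: a wide-to-long *unpivot* of
per-region presence columns into Distribution rows; first/most-recent
record years into an ISO 8601 `eventDate` interval (`2016/2018`); habitat
codes into `isFreshwater`/`isTerrestrial` flags; and the three source
fields with no Darwin Core term (origin, vector of introduction, degree of
naturalization) into typed Description rows.

## Worked example

The package ships a one-row checklist for *Acanthus spinosus* L. together
with the full mapping spec of the Belgian alien-plants registry:

```bash
python examples/build_archive.py
```

prints

```
taxon core:
  taxonID           alien-plants-belgium:taxon:a65145fd1f24f081a1931f9874af48d9
  scientificName    Acanthus spinosus L.
  taxonRank         species   nomenclaturalCode ICN
distribution:
  ISO_3166-2:BE-VLG  flemish region  present  introduced  2016/2018
species profile:
  marine=FALSE freshwater=FALSE terrestrial=TRUE
descriptions:
  [native range] Europe (WGSRPD:1)
  [pathway] cbd_2014_pathway:escape_horticulture
  [invasion stage] casual

star-schema validation: PASSED
archive written to scratch/worked-example/dwca.zip
```

Reading this: the taxon is present and introduced in the Flemish region of
Belgium, first recorded in 2016 and last in 2018; it is a terrestrial plant,
native to Europe (WGSRPD level-1 area 1), a casual escape from horticulture.
Each line is one row of the core or of an extension, keyed by the same
content-derived `taxonID`.

The same pipeline is available from the shell:

```bash
dwcforge synth --n-taxa 50 --seed 1 --out scratch/demo      # synthetic source
dwcforge audit --input scratch/demo/synthetic_1_50.csv       # tidy-data audit
dwcforge map --input scratch/demo/synthetic_1_50.csv \
             --spec src/dwcforge/data/casestudy/mapping.yaml \
             --metadata src/dwcforge/data/casestudy/metadata.yaml \
             --out scratch/run                               # DwC mapping
dwcforge package --dir scratch/run/processed                 # DwC-A zip
dwcforge validate --archive scratch/run/processed/dwca.zip   # star schema
```

Other examples: `examples/mint_identifiers.py` (stable IDs),
`examples/audit_messy_checklist.py` (audit + sanctioned fixes),
`examples/synthesize_and_validate.py` (ledger-backed validator recall).

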