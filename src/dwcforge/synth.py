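"""Seed-controlled synthetic source checklists with an exact content ledger.

The generator emulates the source schema of an alien-species checklist —
one row per taxon with columns taxon, family, taxonRank, scientificNameID,
three per-region presence columns, first/most-recent record years, origin,
degree of naturalization (D/N), vector of introduction (V/I) and habitat —
and can deliberately inject structural defects (empty rows/columns, edge
whitespace, unknown codes, reversed date pairs, duplicate rows).

Every injected defect and every downstream-relevant count (non-skip
presence cells, mappable habitats, expected description rows) is recorded
in the ledger at generation time, so tests assert against the generator's
own bookkeeping rather than re-implementing the pipeline. Same parameters
and seed, same output, byte for byte.

Scientific names are synthesized from pooled syllables ("Genus species
Auth.") — no dependence on real taxa, and therefore stable identifier
digests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from typing import Optional

from .core import ArchiveBundle, SourceChecklist
from .mapping import mint_taxon_id

__all__ = [
    "GeneratorParams", "Ledger", "generate_checklist",
    "BundleDefectLedger", "corrupt_bundle", "SOURCE_COLUMNS",
]

SOURCE_COLUMNS = (
    "taxon", "family", "taxonRank", "scientificNameID",
    "presence_Fl", "presence_Br", "presence_Wa",
    "FR", "MRR", "origin", "D/N", "V/I", "habitat",
)

_GENUS_SYLLABLES = ("Acan", "Bora", "Cala", "Dros", "Eri", "Fallo", "Gera",
                    "Helio", "Impa", "Lysi")
_GENUS_SUFFIX = ("thus", "go", "mia", "era", "geron", "pia", "nium", "tropium",
                 "tiens", "machia")
_EPITHET = ("mollis", "spinosa", "vulgaris", "alba", "japonica", "canadensis",
            "officinalis", "arvensis", "maritima", "glabra", "hirsuta", "minor")
_AUTHORS = ("L.", "Mill.", "Lam.", "DC.", "Thunb.", "Pers.", "Willd.", "(L.) Scop.")
_FAMILIES = ("Acanthaceae", "Asteraceae", "Boraginaceae", "Brassicaceae",
             "Fabaceae", "Lamiaceae", "Poaceae", "Rosaceae")

# Default code pools mirror the shipped case-study mapping spec.
_PRESENCE_CODES = ("X", "?", "-", "")      # present, doubtful, skip, no data
_HABITAT_CODES = ("T", "F", "T/F", "M", "")  # M is unmappable on purpose
_ORIGIN_CODES = ("E", "AF", "AS-Te", "AS-Tr", "AUS", "NAM", "SAM", "")
_PATHWAY_CODES = ("Hort.", "Agric.", "Orn.", "Seeds", "Wool", "Ballast", "")
_STAGE_CODES = ("Cas.", "Nat.", "Inv.", "")

# Codes the default presence map sends to a non-skip occurrence status.
_NON_SKIP_PRESENCE = {"X", "?"}
_MAPPABLE_HABITATS = {"T", "F", "T/F"}


@dataclass(frozen=True)
class GeneratorParams:
    n_taxa: int = 50
    seed: int = 0
    p_empty_row: float = 0.0
    p_empty_column: float = 0.0
    p_whitespace: float = 0.0
    p_unknown_presence: float = 0.0
    p_reversed_dates: float = 0.0
    p_duplicate_row: float = 0.0
    dataset_shortname: str = "synthetic-checklist"

    def __post_init__(self) -> None:
        if self.n_taxa < 0:
            raise ValueError("n_taxa must be >= 0")
        for name in ("p_empty_row", "p_empty_column", "p_whitespace",
                     "p_unknown_presence", "p_reversed_dates", "p_duplicate_row"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass
class Ledger:
    """Exact bookkeeping of what was generated and what was injected."""

    n_taxa: int = 0
    defects: list[dict] = field(default_factory=list)
    # downstream-exact counts (defect-free cells only)
    non_skip_presence_cells: int = 0
    unknown_presence_cells: int = 0
    mappable_habitats: int = 0
    expected_description_rows: int = 0
    reversed_date_rows: int = 0

    def count(self, kind: str) -> int:
        return sum(1 for d in self.defects if d["kind"] == kind)

    def add(self, kind: str, **where) -> None:
        self.defects.append({"kind": kind, **where})

    def as_dict(self) -> dict:
        return asdict(self)


def _make_name(rng: random.Random, used: set[str]) -> str:
    while True:
        name = (
            rng.choice(_GENUS_SYLLABLES) + rng.choice(_GENUS_SUFFIX)
            + " " + rng.choice(_EPITHET) + " " + rng.choice(_AUTHORS)
        )
        if name not in used:
            used.add(name)
            return name


def generate_checklist(params: GeneratorParams) -> tuple[SourceChecklist, Ledger]:
    """Generate a synthetic source checklist plus its exact ledger.

    With all defect probabilities at zero the output is perfectly tidy:
    the audit finds nothing. Defects are injected *after* the clean content
    is generated, and each injection is recorded with its location.
    """
    rng = random.Random(params.seed)
    ledger = Ledger(n_taxa=params.n_taxa)
    used_names: set[str] = set()
    rows: list[list[str]] = []

    for i in range(params.n_taxa):
        name = _make_name(rng, used_names)
        family = rng.choice(_FAMILIES)
        lsid = f"http://ipni.org/urn:lsid:ipni.org:names:{rng.randrange(10000, 99999)}-1"
        presence = [rng.choice(_PRESENCE_CODES) for _ in range(3)]
        fr_year = rng.randrange(1800, 2015)
        mrr_year = rng.randrange(fr_year, 2021)
        fr, mrr = str(fr_year), str(mrr_year)
        if rng.random() < 0.1:
            fr = ""       # no first-record year on file
        origin = rng.choice(_ORIGIN_CODES)
        stage = rng.choice(_STAGE_CODES)
        pathway = rng.choice(_PATHWAY_CODES)
        if pathway and rng.random() < 0.15:
            pathway = pathway + "," + rng.choice([c for c in _PATHWAY_CODES if c and c != pathway])
        habitat = rng.choice(_HABITAT_CODES)
        rows.append([name, family, "species", lsid, *presence,
                     fr, mrr, origin, stage, pathway, habitat])

    # guarantee no accidental fully-empty column in clean output
    if params.n_taxa > 0:
        for j, col in enumerate(SOURCE_COLUMNS):
            if all(row[j] == "" for row in rows):
                default = {"presence_Fl": "X", "presence_Br": "X", "presence_Wa": "X",
                           "origin": "E", "D/N": "Cas.", "V/I": "Hort.",
                           "habitat": "T", "FR": "1950", "MRR": "1950"}.get(col, "x")
                rows[0][j] = default

    # ---- defect injection (recorded in the ledger as it happens) ----
    for i, row in enumerate(rows):
        if params.p_reversed_dates and row[7] and row[8] and rng.random() < params.p_reversed_dates:
            fr_v, mrr_v = row[7], row[8]
            if fr_v != mrr_v:
                row[7], row[8] = mrr_v, fr_v
                ledger.add("reversed-dates", row=i)
                ledger.reversed_date_rows += 1
        if params.p_unknown_presence and rng.random() < params.p_unknown_presence:
            j = rng.randrange(4, 7)
            if row[j] == "":
                row[j] = "Z"
                ledger.add("unknown-presence-code", row=i, column=SOURCE_COLUMNS[j])
        if params.p_whitespace and rng.random() < params.p_whitespace:
            j = rng.randrange(len(SOURCE_COLUMNS))
            if row[j]:
                row[j] = " " + row[j] + " "
                ledger.add("whitespace-cell", row=i, column=SOURCE_COLUMNS[j])

    n_dups = sum(1 for i in range(len(rows)) if params.p_duplicate_row
                 and rng.random() < params.p_duplicate_row)
    for _ in range(n_dups):
        i = rng.randrange(len(rows))
        pos = rng.randrange(len(rows) + 1)
        rows.insert(pos, list(rows[i]))
        ledger.add("duplicate-row", source_row=i, inserted_at=pos)

    n_empty = sum(1 for i in range(params.n_taxa) if params.p_empty_row
                  and rng.random() < params.p_empty_row)
    for _ in range(n_empty):
        pos = rng.randrange(len(rows) + 1)
        rows.insert(pos, [""] * len(SOURCE_COLUMNS))
        ledger.add("empty-row", inserted_at=pos)

    columns = list(SOURCE_COLUMNS)
    if params.p_empty_column and rng.random() < params.p_empty_column:
        columns.append("remarks")
        for row in rows:
            row.append("")
        ledger.add("empty-column", column="remarks")

    checklist = SourceChecklist.from_records(
        columns, rows, source=f"synthetic(seed={params.seed}, n={params.n_taxa})"
    )

    # ---- exact downstream counts, from the final cell contents ----
    for row in rows:
        if all(cell == "" for cell in row):
            continue
        for j in (4, 5, 6):
            code = row[j].strip()
            if code in _NON_SKIP_PRESENCE:
                ledger.non_skip_presence_cells += 1
            elif code and code not in _PRESENCE_CODES:
                ledger.unknown_presence_cells += 1
        if row[12].strip() in _MAPPABLE_HABITATS:
            ledger.mappable_habitats += 1
        if row[9].strip():
            ledger.expected_description_rows += 1
        if row[10].strip():
            ledger.expected_description_rows += 1
        v_i = row[11].strip()
        if v_i:
            ledger.expected_description_rows += len(
                [c for c in v_i.split(",") if c.strip()]
            )
    return checklist, ledger


# ---------------------------------------------------------------------------
# Bundle-level defect injection (for validator recall tests)
# ---------------------------------------------------------------------------

@dataclass
class BundleDefectLedger:
    defects: list[dict] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.defects)

    def add(self, kind: str, **where) -> None:
        self.defects.append({"kind": kind, **where})


def corrupt_bundle(
    bundle: ArchiveBundle,
    seed: int,
    n_orphans: int = 0,
    n_duplicates: int = 0,
    n_vocab: int = 0,
) -> tuple[ArchiveBundle, BundleDefectLedger]:
    """Inject exactly the requested star-schema defects into a copy of the
    bundle, each producing exactly one validator error finding.

    orphans    -> distribution rows re-keyed to a validly-patterned taxonID
                  that no core row carries
    duplicates -> core rows copied verbatim (one duplicate-ID error per copy)
    vocab      -> a distribution countryCode replaced by a non-ISO value
    """
    rng = random.Random(seed)
    ledger = BundleDefectLedger()
    out = ArchiveBundle(
        core=list(bundle.core),
        distribution=list(bundle.distribution),
        speciesprofile=list(bundle.speciesprofile),
        description=list(bundle.description),
        metadata=bundle.metadata,
    )
    shortname = out.core[0].taxonID.split(":", 1)[0] if out.core else "synthetic-checklist"

    from dataclasses import replace
    orphaned: set[int] = set()
    for n in range(n_orphans):
        candidates = [i for i in range(len(out.distribution)) if i not in orphaned]
        if not candidates:
            break
        i = rng.choice(candidates)
        ghost = mint_taxon_id(f"Phantoma absens {n} Nob.", "Plantae", shortname)
        out.distribution[i] = replace(out.distribution[i], taxonID=ghost)
        orphaned.add(i)
        ledger.add("orphan", file="distribution", row=i)
    for _ in range(n_duplicates):
        if not out.core:
            break
        i = rng.randrange(len(out.core))
        out.core.append(out.core[i])
        ledger.add("duplicate-taxon-id", row=i)
    mutated: set[int] = set()
    for _ in range(n_vocab):
        candidates = [i for i in range(len(out.distribution))
                      if i not in mutated
                      and out.distribution[i].taxonID in out.core_ids]
        if not candidates:
            break
        i = rng.choice(candidates)
        out.distribution[i] = replace(out.distribution[i], countryCode="Belgium")
        mutated.add(i)
        ledger.add("vocabulary", file="distribution", row=i)
    return out, ledger
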