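"""The mapping algebra: term rules applied to a fixed source checklist.

Identifiers are minted first, then each rule appends one Darwin Core term
column to the working table (the source cells are never modified, so the
link between original columns and mapped terms is preserved for review).
Post-processing drops the source columns, leaving only the declared DwC
terms in their declared order, partitioned into the star-schema row sets.

Identifier convention
---------------------
``taxonID`` is ``<shortname>:taxon:<digest>``, where the digest is the MD5
of the scientific-name string *as serialized by R's value-serialization
format* (version-2 XDR layout of a length-1 character vector, stream header
skipped) — the exact quantity computed by ``digest::digest(name)`` in the R
workflows this package interoperates with. The convention was fixed against
two independently published reference identifiers and is frozen: archives
minted here are stable against, and interchangeable with, those workflows.
A content-derived identifier never shifts when rows are inserted, reordered
or deleted — permuting the source permutes the rows but changes no ID.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

from .core import (
    ConfigurationError,
    MappingError,
    MappingSpec,
    SourceChecklist,
    TermRule,
    SHORTNAME_PATTERN,
)
from .vocab import VocabularyRegistry, default_registry

__all__ = [
    "MappedTable",
    "mint_taxon_id",
    "apply_static_rule",
    "apply_unaltered_rule",
    "apply_altered_rule",
    "post_process",
    "TRANSFORMS",
    "register_transform",
]


# ---------------------------------------------------------------------------
# taxonID minting
# ---------------------------------------------------------------------------

def _r_character_digest(text: str) -> str:
    """MD5 of ``text`` framed as an R-serialized length-1 character vector.

    Layout (version-2 XDR, header skipped): STRSXP type word, length 1,
    CHARSXP flags word (ASCII or UTF-8 bit set), byte length, then the
    UTF-8 bytes. Deterministic and platform-independent.
    """
    raw = text.encode("utf-8")
    flags = 0x00040009 if text.isascii() else 0x00008009
    payload = (
        struct.pack(">II", 16, 1)
        + struct.pack(">I", flags)
        + struct.pack(">I", len(raw))
        + raw
    )
    return hashlib.md5(payload).hexdigest()


def mint_taxon_id(scientific_name: str, kingdom: str, dataset_shortname: str) -> str:
    """Mint the stable taxonID ``<shortname>:taxon:<32-hex digest>``.

    The digest is a pure function of the scientific-name string (see module
    docstring for the convention); it is independent of row order and of
    every other row. ``kingdom`` is part of the taxon's identity tuple and
    is required non-empty — an ID minted for a half-specified taxon would
    not be stable — but under the frozen convention it does not perturb the
    digest.
    """
    if not scientific_name:
        raise MappingError("refusing to mint a taxonID for an empty scientific name")
    if not kingdom:
        raise MappingError(
            f"refusing to mint a taxonID for {scientific_name!r} without a kingdom"
        )
    if not SHORTNAME_PATTERN.match(dataset_shortname):
        raise ConfigurationError(
            f"dataset shortname {dataset_shortname!r} is not a lowercase-hyphen identifier"
        )
    return f"{dataset_shortname}:taxon:{_r_character_digest(scientific_name)}"


# ---------------------------------------------------------------------------
# Transform registry (altered rules)
# ---------------------------------------------------------------------------

# A transform maps the row's source cells (in rule order) plus parameters to
# an output text or None (= no value). It sees only its own row: no
# cross-row state, so adding a taxon never changes another taxon's output.
Transform = Callable[[Sequence[str], Mapping[str, object], MappingSpec], Optional[str]]

TRANSFORMS: dict[str, Transform] = {}


def register_transform(name: str) -> Callable[[Transform], Transform]:
    def deco(fn: Transform) -> Transform:
        TRANSFORMS[name] = fn
        return fn
    return deco


def _lookup_code(
    code: str,
    mapping: Mapping[str, str],
    rule_name: str,
    row_index: int,
    policy: str,
) -> Optional[str]:
    """Recode one source code through a value map under the unknown-policy."""
    if code in mapping:
        return mapping[code]
    if policy == "error":
        raise MappingError(
            f"row {row_index}: unknown code {code!r} for rule {rule_name!r}; "
            "add it to the value map or relax the unknown-code policy"
        )
    if policy == "skip":
        return None
    return f"UNMAPPED:{code}"  # policy == "flag": pass through, flagged for review


@register_transform("recode")
def _recode_transform(
    cells: Sequence[str], params: Mapping[str, object], spec: MappingSpec
) -> Optional[str]:
    """Single-column recode through a named value map (the spreadsheet
    analogue of recode()/case_when())."""
    code = cells[0].strip()
    if code == "":
        return None
    mapping = spec.value_map(str(params["value_map"]))
    policy = str(params.get("policy", spec.unknown_policy))
    return _lookup_code(
        code, mapping, str(params["value_map"]), int(params.get("row", -1)), policy
    )


# ---------------------------------------------------------------------------
# MappedTable and rule application
# ---------------------------------------------------------------------------

@dataclass
class MappedTable:
    """A source checklist with accumulated (file, term) -> value columns.

    Term columns are only ever appended; each carries the rule that produced
    it as provenance. ``None`` cells mean "no value" and are rendered as
    absent (never as empty strings pretending to be data).
    """

    source: SourceChecklist
    columns: dict[tuple[str, str], list[Optional[str]]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], TermRule] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.source.n_rows

    def term(self, target_file: str, term: str) -> list[Optional[str]]:
        try:
            return self.columns[(target_file, term)]
        except KeyError:
            raise ConfigurationError(
                f"no mapped column for term {term!r} in file {target_file!r}"
            )

    def _add(self, rule: TermRule, values: list[Optional[str]]) -> None:
        key = (rule.target_file, rule.target_term)
        if key in self.columns:
            raise ConfigurationError(
                f"term {rule.target_term!r} already mapped in file {rule.target_file!r}"
            )
        self.columns[key] = values
        self.provenance[key] = rule


def _check_vocab(
    rule: TermRule,
    values: Sequence[Optional[str]],
    registry: VocabularyRegistry,
) -> None:
    if rule.vocabulary is None:
        return
    for i, value in enumerate(values):
        if value is None:
            continue
        verdict = registry.check_term(rule.vocabulary, value)
        if not verdict:
            raise MappingError(
                f"rule for {rule.target_file}/{rule.target_term}: row {i} value "
                f"{value!r} fails vocabulary {rule.vocabulary!r}: {verdict.reason}"
            )


def apply_static_rule(
    rule: TermRule,
    table: MappedTable,
    registry: Optional[VocabularyRegistry] = None,
) -> MappedTable:
    """Fixed value on every record (the record-level metadata terms)."""
    if rule.kind != "static":
        raise ConfigurationError(f"apply_static_rule got a {rule.kind!r} rule")
    registry = registry or default_registry()
    values: list[Optional[str]] = [rule.value] * table.n_rows
    _check_vocab(rule, values[:1] if values else [rule.value], registry)
    table._add(rule, values)
    return table


def apply_unaltered_rule(
    rule: TermRule,
    table: MappedTable,
    registry: Optional[VocabularyRegistry] = None,
) -> MappedTable:
    """Byte-identical copy of one source column; empty cells carry no value."""
    if rule.kind != "unaltered":
        raise ConfigurationError(f"apply_unaltered_rule got a {rule.kind!r} rule")
    registry = registry or default_registry()
    (column,) = rule.source_columns
    cells = table.source.column(column)  # raises ConfigurationError if missing
    values = [cell if cell != "" else None for cell in cells]
    _check_vocab(rule, values, registry)
    table._add(rule, values)
    return table


def apply_altered_rule(
    rule: TermRule,
    table: MappedTable,
    spec: MappingSpec,
    registry: Optional[VocabularyRegistry] = None,
) -> MappedTable:
    """Transformation of one or more source columns via a registered transform."""
    if rule.kind != "altered":
        raise ConfigurationError(f"apply_altered_rule got a {rule.kind!r} rule")
    registry = registry or default_registry()
    if rule.transform not in TRANSFORMS:
        raise ConfigurationError(
            f"rule for {rule.target_term!r}: transform {rule.transform!r} is not registered"
        )
    transform = TRANSFORMS[rule.transform]
    source_cols = [table.source.column(c) for c in rule.source_columns]
    values: list[Optional[str]] = []
    for i in range(table.n_rows):
        cells = [col[i] for col in source_cols]
        try:
            values.append(transform(cells, dict(rule.transform_params, row=i), spec))
        except MappingError as exc:
            raise MappingError(
                f"rule for {rule.target_file}/{rule.target_term}, row {i}: {exc}"
            ) from exc
    _check_vocab(rule, values, registry)
    table._add(rule, values)
    return table


def apply_rule(
    rule: TermRule,
    table: MappedTable,
    spec: MappingSpec,
    registry: Optional[VocabularyRegistry] = None,
) -> MappedTable:
    if rule.kind == "static":
        return apply_static_rule(rule, table, registry)
    if rule.kind == "unaltered":
        return apply_unaltered_rule(rule, table, registry)
    return apply_altered_rule(rule, table, spec, registry)


def post_process(
    table: MappedTable,
    output_order: Mapping[str, Sequence[str]],
) -> dict[str, list[dict[str, str]]]:
    """Drop the source columns; emit per-file records in declared term order.

    Returns ``{file: [ {term: value, ...}, ... ]}`` with ``None`` cells
    omitted from each record. A term declared in the output order but never
    produced by any rule is a configuration error.
    """
    out: dict[str, list[dict[str, str]]] = {}
    for target_file, terms in output_order.items():
        for term in terms:
            if (target_file, term) not in table.columns:
                raise ConfigurationError(
                    f"output order declares term {term!r} for file {target_file!r} "
                    "but no rule produced it"
                )
        records = []
        for i in range(table.n_rows):
            record = {}
            for term in terms:
                value = table.columns[(target_file, term)][i]
                if value is not None:
                    record[term] = value
            records.append(record)
        out[target_file] = records
    return out
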