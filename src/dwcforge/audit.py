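"""Tidy-data audit of a raw source checklist, plus the sanctioned
structural fixes.

The audit enumerates departures from the tidy layout (one variable per
column, one observation per row): fully empty rows and columns, duplicate
column names, duplicate full rows, cells with leading/trailing whitespace
and columns that mix mutually exclusive value families. Only the first two
defect classes plus whitespace are auto-fixable; everything else needs a
source-side correction agreed with the dataset author — the raw/processed
boundary stays sharp.

Findings are ordered deterministically (column-level findings first, then
row-major) so reports can be compared byte-for-byte across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .core import DwcForgeError, SourceChecklist

__all__ = ["Finding", "AuditReport", "audit_tidy", "apply_structural_fixes",
           "UnfixableFindingError"]

SEVERITIES = ("error", "warning", "info")

# rule id -> severity; the registry is extensible, these are the built-ins
RULES = {
    "duplicate-column": "error",
    "empty-column": "warning",
    "empty-row": "warning",
    "duplicate-row": "warning",
    "mixed-value-family": "warning",
    "whitespace-cell": "info",
}

FIXABLE_RULES = ("empty-column", "empty-row", "whitespace-cell")


class UnfixableFindingError(DwcForgeError):
    """Raised when asked to auto-fix findings that need human judgment."""


@dataclass(frozen=True)
class Finding:
    rule: str
    severity: str
    row: Optional[int]      # 0-based data row; None for column-level findings
    column: Optional[str]   # column name; None for row-level findings
    message: str

    def as_dict(self) -> dict:
        return {
            "rule": self.rule,
            "severity": self.severity,
            "row": self.row,
            "column": self.column,
            "message": self.message,
        }


@dataclass
class AuditReport:
    findings: list[Finding] = field(default_factory=list)
    structural_changes: list[str] = field(default_factory=list)
    source_checksum: str = ""

    @property
    def passed(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    def by_rule(self, rule: str) -> list[Finding]:
        return [f for f in self.findings if f.rule == rule]

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "source_checksum": self.source_checksum,
                "findings": [f.as_dict() for f in self.findings],
                "structural_changes": list(self.structural_changes),
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [f"audit: {'PASSED' if self.passed else 'FAILED'} "
                 f"({len(self.findings)} finding(s))"]
        for f in self.findings:
            where = []
            if f.column is not None:
                where.append(f"column {f.column!r}")
            if f.row is not None:
                where.append(f"row {f.row}")
            loc = ", ".join(where) or "table"
            lines.append(f"  [{f.severity}] {f.rule} at {loc}: {f.message}")
        for change in self.structural_changes:
            lines.append(f"  fixed: {change}")
        return "\n".join(lines)


def _value_family(cell: str, value_maps: Mapping[str, Mapping]) -> Optional[str]:
    """Name of the first configured value family the cell belongs to."""
    for name, mapping in value_maps.items():
        if cell in mapping:
            return name
    return None


def audit_tidy(
    checklist: SourceChecklist,
    value_maps: Optional[Mapping[str, Mapping]] = None,
) -> AuditReport:
    """Audit a checklist snapshot against the tidy-data layout.

    ``value_maps``, when given, enable the mixed-value-family rule: a column
    whose non-empty cells fall into more than one configured code family
    (e.g. presence codes mixed with habitat codes) is flagged, since one
    column should hold one variable.
    """
    report = AuditReport(source_checksum=checklist.provenance.checksum)
    cols, rows = checklist.columns, checklist.rows

    # --- column-level findings, in column order ---
    seen: dict[str, int] = {}
    for name in cols:
        seen[name] = seen.get(name, 0) + 1
    for name, count in seen.items():
        if count > 1:
            report.findings.append(Finding(
                "duplicate-column", RULES["duplicate-column"], None, name,
                f"column name {name!r} appears {count} times; rename in the source",
            ))
    for j, name in enumerate(cols):
        if rows and all(row[j] == "" for row in rows):
            report.findings.append(Finding(
                "empty-column", RULES["empty-column"], None, name,
                f"column {name!r} is entirely empty",
            ))
    if value_maps:
        for j, name in enumerate(cols):
            families = {}
            for row in rows:
                if row[j] == "":
                    continue
                fam = _value_family(row[j].strip(), value_maps)
                families.setdefault(fam, row[j])
            named = {f for f in families if f is not None}
            if len(named) > 1 or (named and None in families):
                report.findings.append(Finding(
                    "mixed-value-family", RULES["mixed-value-family"], None, name,
                    f"column {name!r} mixes value families "
                    f"{sorted(str(f) for f in families)}",
                ))

    # --- row-level findings, row-major ---
    seen_rows: dict[tuple[str, ...], int] = {}
    for i, row in enumerate(rows):
        if all(cell == "" for cell in row):
            report.findings.append(Finding(
                "empty-row", RULES["empty-row"], i, None,
                f"row {i} is entirely empty",
            ))
            continue
        if row in seen_rows:
            report.findings.append(Finding(
                "duplicate-row", RULES["duplicate-row"], i, None,
                f"row {i} duplicates row {seen_rows[row]}",
            ))
        else:
            seen_rows[row] = i
        for j, cell in enumerate(row):
            if cell != cell.strip():
                report.findings.append(Finding(
                    "whitespace-cell", RULES["whitespace-cell"], i, cols[j],
                    f"cell ({i}, {cols[j]!r}) has leading/trailing whitespace",
                ))
    return report


def apply_structural_fixes(
    checklist: SourceChecklist,
    report: AuditReport,
    include_errors: bool = False,
) -> SourceChecklist:
    """Apply the sanctioned structural fixes and return a NEW snapshot.

    Drops fully empty rows and columns and trims cell-edge whitespace
    (internal whitespace is data — scientific names contain meaningful
    spaces). The input snapshot is untouched; every change is appended to
    ``report.structural_changes``. Re-applying to an already-tidy snapshot
    is a no-op. Error-severity findings (duplicate columns) are never
    auto-fixed: passing ``include_errors=True`` raises instead, with the
    explanation that these require source-side correction.
    """
    if report.source_checksum and report.source_checksum != checklist.provenance.checksum:
        raise DwcForgeError(
            "audit report was produced from a different checklist snapshot "
            f"(report checksum {report.source_checksum[:12]}..., "
            f"checklist {checklist.provenance.checksum[:12]}...)"
        )
    if include_errors:
        errors = [f for f in report.findings if f.severity == "error"]
        if errors:
            names = sorted({f.column for f in errors if f.column})
            raise UnfixableFindingError(
                f"refusing to auto-fix error-severity findings ({', '.join(names)}): "
                "duplicate column names require human judgment; consult the dataset "
                "author and correct the source"
            )

    # Trimming can expose new fully-empty rows/columns (a row of blank-only
    # cells), so fixes are applied to a fixpoint; the result of one call is
    # always already tidy and a second call is a no-op.
    current, working = checklist, report
    while True:
        fixed = _fix_once(current, working, report)
        if fixed is current:
            return current
        current = fixed
        working = audit_tidy(current)


def _fix_once(
    checklist: SourceChecklist,
    report: AuditReport,
    change_log: AuditReport,
) -> SourceChecklist:
    drop_rows = {f.row for f in report.by_rule("empty-row")}
    drop_cols = {f.column for f in report.by_rule("empty-column")}
    report = change_log

    new_cols, keep_idx = [], []
    for j, name in enumerate(checklist.columns):
        if name in drop_cols:
            report.structural_changes.append(f"dropped empty column {name!r}")
        else:
            new_cols.append(name)
            keep_idx.append(j)

    new_rows = []
    trimmed = 0
    for i, row in enumerate(checklist.rows):
        if i in drop_rows:
            report.structural_changes.append(f"dropped empty row {i}")
            continue
        out = []
        for j in keep_idx:
            cell = row[j]
            if cell != cell.strip():
                trimmed += 1
            out.append(cell.strip())
        new_rows.append(out)
    if trimmed:
        report.structural_changes.append(
            f"trimmed edge whitespace in {trimmed} cell(s)"
        )

    if not drop_rows and not drop_cols and trimmed == 0:
        return checklist  # already tidy: byte-identical output, empty change log
    return checklist.with_data(new_cols, new_rows)
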