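"""Controlled vocabularies and grammars that certify term values.

Two kinds of vocabulary exist:

* **closed-set** — a pinned, versioned list of allowed values shipped as a
  text data file with the package (no network fetch at run time: the public
  registries drift, the archive must not). Membership is case-sensitive
  unless the vocabulary declares case-folding.
* **grammar** — a formal pattern or little language; here the ISO 8601
  subset used for ``eventDate`` (single dates at year, month or day
  precision, and ``start/end`` intervals whose start does not come after
  the end at the stated precision).

``check_term`` is a pure function: same vocabulary + value, same verdict.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Optional

from .core import ConfigurationError

__all__ = [
    "Vocabulary",
    "Verdict",
    "VocabularyRegistry",
    "default_registry",
    "check_term",
    "check_event_date",
    "parse_event_date",
]


@dataclass(frozen=True)
class Verdict:
    ok: bool
    reason: str = ""

    def __bool__(self) -> bool:  # allows `if check_term(...)`
        return self.ok


@dataclass(frozen=True)
class Vocabulary:
    """A named closed value set or grammar with provenance."""

    name: str
    kind: str  # "closed-set" | "grammar"
    values: frozenset[str] = frozenset()
    grammar: Optional[Callable[[str], Verdict]] = None
    source_uri: str = ""
    version: str = ""
    case_fold: bool = False

    def __post_init__(self) -> None:
        if self.kind == "closed-set" and not self.values:
            raise ConfigurationError(f"closed-set vocabulary {self.name!r} is empty")
        if self.kind == "grammar" and self.grammar is None:
            raise ConfigurationError(f"grammar vocabulary {self.name!r} has no grammar")

    def check(self, value: str) -> Verdict:
        if self.kind == "grammar":
            return self.grammar(value)
        probe = value.casefold() if self.case_fold else value
        universe = (
            frozenset(v.casefold() for v in self.values) if self.case_fold else self.values
        )
        if probe in universe:
            return Verdict(True)
        return Verdict(
            False,
            f"{value!r} is not in vocabulary {self.name!r} "
            f"({self.source_uri or 'unregistered source'})",
        )


# ---------------------------------------------------------------------------
# ISO 8601 eventDate grammar (year / month / day precision + intervals)
# ---------------------------------------------------------------------------

_DATE_RE = re.compile(r"^(\d{4})(?:-(\d{2})(?:-(\d{2}))?)?$")


def parse_event_date(value: str) -> Optional[tuple[int, ...]]:
    """Parse one date token into a (year[, month[, day]]) tuple, or None.

    Calendar validity of full dates is delegated to :class:`datetime.date`;
    month-precision tokens only need a month in 1..12.
    """
    m = _DATE_RE.match(value)
    if not m:
        return None
    year = int(m.group(1))
    if m.group(2) is None:
        return (year,)
    month = int(m.group(2))
    if m.group(3) is None:
        if not 1 <= month <= 12:
            return None
        return (year, month)
    day = int(m.group(3))
    try:
        datetime.date(year, month, day)
    except ValueError:
        return None
    return (year, month, day)


def _interval_bounds(parts: tuple[int, ...], end: bool) -> tuple[int, int, int]:
    """Widen a reduced-precision date to its earliest (start) or latest (end) day."""
    year = parts[0]
    if len(parts) == 1:
        return (year, 12, 31) if end else (year, 1, 1)
    month = parts[1]
    if len(parts) == 2:
        if end:
            last = (datetime.date(year + (month == 12), month % 12 + 1, 1)
                    - datetime.timedelta(days=1))
            return (year, month, last.day)
        return (year, month, 1)
    return (year, parts[1], parts[2])


def check_event_date(value: str) -> Verdict:
    """Verdict on an eventDate text: single date or ``start/end`` interval.

    Intervals must run forwards: the earliest day the start could denote must
    not come after the latest day of the end (so ``2016-05/2016`` passes but
    ``2018/2016`` does not).
    """
    if value == "":
        return Verdict(False, "empty eventDate")
    if "/" in value:
        pieces = value.split("/")
        if len(pieces) != 2:
            return Verdict(False, f"{value!r}: an interval has exactly one '/'")
        start, end = (parse_event_date(p) for p in pieces)
        if start is None or end is None:
            bad = pieces[0] if start is None else pieces[1]
            return Verdict(False, f"{bad!r} is not a YYYY, YYYY-MM or YYYY-MM-DD date")
        if _interval_bounds(start, end=False) > _interval_bounds(end, end=True):
            return Verdict(False, f"{value!r}: interval start is after its end")
        return Verdict(True)
    if parse_event_date(value) is None:
        return Verdict(False, f"{value!r} is not a YYYY, YYYY-MM or YYYY-MM-DD date")
    return Verdict(True)


def _native_range_grammar(value: str) -> Verdict:
    """Area name annotated with a level-1 WGSRPD code, e.g. 'Europe (WGSRPD:1)'."""
    m = re.match(r"^.+ \(WGSRPD:([1-9])\)$", value)
    if not m:
        return Verdict(
            False, f"{value!r} does not match '<area name> (WGSRPD:<level-1 code>)'"
        )
    return Verdict(True)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_VOCAB_FILES = {
    "countryCode": "iso3166-1-alpha2.txt",
    "iso3166-2-BE": "iso3166-2-be.txt",
    "language": "iso639-1.txt",
    "taxonRank": "gbif-taxon-rank.txt",
    "occurrenceStatus": "gbif-occurrence-status.txt",
    "establishmentMeans": "gbif-establishment-means.txt",
    "wgsrpd-level1": "wgsrpd-level1.txt",
    "pathway": "cbd-pathway.txt",
    "invasion-stage": "invasion-stage.txt",
    "license": "gbif-license.txt",
}


def _load_vocab_file(name: str, filename: str) -> Vocabulary:
    text = (
        resources.files("dwcforge.data.vocab").joinpath(filename).read_text("utf-8")
    )
    values, source_uri, version = [], "", ""
    for line in text.splitlines():
        line = line.rstrip("\n")
        if line.startswith("#"):
            body = line.lstrip("# ")
            if body.startswith("source:"):
                source_uri = body.split(":", 1)[1].strip()
            elif body.startswith("version:"):
                version = body.split(":", 1)[1].strip()
            continue
        if line.strip():
            values.append(line.strip())
    return Vocabulary(
        name=name,
        kind="closed-set",
        values=frozenset(values),
        source_uri=source_uri,
        version=version,
    )


class VocabularyRegistry:
    """Named lookup of vocabularies; loads pinned data files lazily."""

    def __init__(self) -> None:
        self._vocabularies: dict[str, Vocabulary] = {}
        self._register_grammars()

    def _register_grammars(self) -> None:
        self.register(
            Vocabulary(
                name="eventDate",
                kind="grammar",
                grammar=check_event_date,
                source_uri="https://www.iso.org/iso-8601-date-and-time-format.html",
                version="ISO 8601-1:2019 subset (date + interval)",
            )
        )
        self.register(
            Vocabulary(
                name="native-range",
                kind="grammar",
                grammar=_native_range_grammar,
                source_uri="https://www.tdwg.org/standards/wgsrpd/",
                version="WGSRPD ed. 2, level-1 annotation grammar",
            )
        )

    def register(self, vocabulary: Vocabulary) -> None:
        self._vocabularies[vocabulary.name] = vocabulary

    def get(self, name: str) -> Vocabulary:
        if name not in self._vocabularies:
            if name in _VOCAB_FILES:
                self._vocabularies[name] = _load_vocab_file(name, _VOCAB_FILES[name])
            else:
                raise ConfigurationError(f"no vocabulary registered under {name!r}")
        return self._vocabularies[name]

    def names(self) -> list[str]:
        return sorted(set(self._vocabularies) | set(_VOCAB_FILES))

    def check_term(self, vocabulary_name: str, value: str) -> Verdict:
        return self.get(vocabulary_name).check(value)


_default: Optional[VocabularyRegistry] = None


def default_registry() -> VocabularyRegistry:
    global _default
    if _default is None:
        _default = VocabularyRegistry()
    return _default


def check_term(vocabulary_name: str, value: str) -> Verdict:
    """Conformance verdict for ``value`` against a registered vocabulary."""
    return default_registry().check_term(vocabulary_name, value)
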