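"""Reading and writing the structured text configuration files: the mapping
spec (term rules, constants, region bindings, value maps) and the dataset
metadata document. Both are versioned YAML, reviewed alongside the source
data, so a published archive is reproducible from (source, spec, metadata).
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .core import (
    ConfigurationError,
    EmlMetadata,
    MappingSpec,
    RegionBinding,
    TermRule,
)

__all__ = ["load_mapping_spec", "dump_mapping_spec", "load_metadata"]

_SPEC_VERSION = "1"


def _build_rule(entry: dict[str, Any]) -> TermRule:
    try:
        return TermRule(
            target_term=entry["term"],
            target_file=entry["file"],
            kind=entry["kind"],
            source_columns=tuple(entry.get("source_columns", [])),
            value=entry.get("value"),
            transform=entry.get("transform"),
            transform_params=dict(entry.get("transform_params", {})),
            vocabulary=entry.get("vocabulary"),
        )
    except KeyError as exc:
        raise ConfigurationError(f"term rule {entry!r}: missing key {exc}") from exc


def load_mapping_spec(path: str | Path) -> MappingSpec:
    with Path(path).open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: mapping spec must be a YAML mapping")
    version = str(doc.get("spec_version", _SPEC_VERSION))
    if version != _SPEC_VERSION:
        raise ConfigurationError(
            f"{path}: unsupported spec_version {version!r} (supported: {_SPEC_VERSION})"
        )
    try:
        shortname = doc["dataset_shortname"]
    except KeyError:
        raise ConfigurationError(f"{path}: dataset_shortname is required")
    region_map = [
        RegionBinding(
            source_column=r["source_column"],
            location_id=r["location_id"],
            locality=r["locality"],
        )
        for r in doc.get("region_map", [])
    ]
    value_maps = {}
    for name, mapping in (doc.get("value_maps") or {}).items():
        if not isinstance(mapping, dict):
            raise ConfigurationError(f"{path}: value map {name!r} must be a mapping")
        value_maps[name] = {
            str(k): (list(v) if isinstance(v, (list, tuple)) else str(v))
            for k, v in mapping.items()
        }
    return MappingSpec(
        dataset_shortname=shortname,
        constants={str(k): str(v) for k, v in (doc.get("constants") or {}).items()},
        term_rules=[_build_rule(e) for e in doc.get("term_rules", [])],
        region_map=region_map,
        value_maps=value_maps,
        unknown_policy=doc.get("unknown_policy", "error"),
        multi_value_separator=doc.get("multi_value_separator", ","),
        version=str(doc.get("version", "")),
    )


def dump_mapping_spec(spec: MappingSpec, path: str | Path) -> None:
    doc = {
        "spec_version": _SPEC_VERSION,
        "version": spec.version,
        "dataset_shortname": spec.dataset_shortname,
        "unknown_policy": spec.unknown_policy,
        "multi_value_separator": spec.multi_value_separator,
        "constants": dict(spec.constants),
        "term_rules": [
            {
                "term": r.target_term,
                "file": r.target_file,
                "kind": r.kind,
                **({"source_columns": list(r.source_columns)} if r.source_columns else {}),
                **({"value": r.value} if r.value is not None else {}),
                **({"transform": r.transform} if r.transform else {}),
                **({"transform_params": dict(r.transform_params)} if r.transform_params else {}),
                **({"vocabulary": r.vocabulary} if r.vocabulary else {}),
            }
            for r in spec.term_rules
        ],
        "region_map": [
            {"source_column": b.source_column, "location_id": b.location_id,
             "locality": b.locality}
            for b in spec.region_map
        ],
        "value_maps": spec.value_maps,
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def load_metadata(path: str | Path) -> EmlMetadata:
    with Path(path).open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "title" not in doc:
        raise ConfigurationError(f"{path}: metadata document needs at least a title")
    return EmlMetadata(
        title=doc["title"],
        creators=list(doc.get("creators", [])),
        abstract=doc.get("abstract", ""),
        license_uri=doc.get("license_uri", EmlMetadata.__dataclass_fields__["license_uri"].default),
        license_name=doc.get("license_name", ""),
        geographic_coverage=doc.get("geographic_coverage", ""),
        taxonomic_coverage=doc.get("taxonomic_coverage", ""),
        temporal_coverage=doc.get("temporal_coverage", ""),
        project_description=doc.get("project_description", ""),
        provenance_statement=doc.get("provenance_statement", ""),
        pub_date=str(doc.get("pub_date", "")),
    )
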