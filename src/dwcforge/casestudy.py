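"""The packaged worked example: a one-row checklist (Acanthus spinosus L.),
its full mapping spec and its dataset metadata.

These ship inside the package so the documented end-to-end example — and
every golden assertion derived from the published mapping table — runs
without any external download.
"""

from __future__ import annotations

import tempfile
from importlib import resources
from pathlib import Path

from .core import EmlMetadata, MappingSpec, SourceChecklist
from .specio import load_mapping_spec, load_metadata

__all__ = ["load_spec", "load_checklist", "load_dataset_metadata", "data_path"]


def data_path(name: str):
    return resources.files("dwcforge.data.casestudy").joinpath(name)


def load_spec() -> MappingSpec:
    """The alien-plants-belgium mapping specification."""
    with resources.as_file(data_path("mapping.yaml")) as path:
        return load_mapping_spec(path)


def load_checklist() -> SourceChecklist:
    """The hand-written one-row source fixture for Acanthus spinosus L."""
    with resources.as_file(data_path("acanthus_spinosus.csv")) as path:
        return SourceChecklist.from_csv(path)


def load_dataset_metadata() -> EmlMetadata:
    with resources.as_file(data_path("metadata.yaml")) as path:
        return load_metadata(path)
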