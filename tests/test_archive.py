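"""Archive serialization: data files, descriptor, EML, zip, round-trip and
star-schema validation (with injected-defect recall)."""

from dataclasses import replace
from pathlib import Path

import pytest
from lxml import etree

from dwcforge.archive import (
    BOUND_TERMS,
    ROW_TYPE_URIS,
    assemble_archive,
    build_descriptor,
    read_archive,
    term_uri,
    validate_eml,
    validate_star_schema,
    write_data_files,
    write_eml,
    write_meta_xml,
)
from dwcforge.core import (
    ArchiveBundle,
    ConfigurationError,
    DistributionRow,
    DwcForgeError,
    EmlMetadata,
    TaxonCoreRow,
    CORE_TERM_ORDER,
)
from dwcforge.synth import GeneratorParams, corrupt_bundle, generate_checklist
from dwcforge.transforms import map_checklist

DWC_TEXT_NS = "http://rs.tdwg.org/dwc/text/"


def write_all(bundle, directory: Path, metadata=None):
    write_data_files(bundle, directory)
    write_meta_xml(bundle, directory)
    write_eml(metadata or bundle.metadata, directory, package_id="test-archive")
    return assemble_archive(directory)


def test_taxon_csv_header_lists_core_terms_in_declared_order(case_bundle, tmp_path):
    write_data_files(case_bundle, tmp_path)
    header = (tmp_path / "taxon.csv").read_text().splitlines()[0]
    assert header.split(",") == list(CORE_TERM_ORDER)


def test_empty_extension_produces_no_file_and_no_descriptor_entry(tmp_path):
    row = TaxonCoreRow(
        taxonID="demo-list:taxon:" + "0" * 32, scientificName="Bora minor DC.",
    )
    bundle = ArchiveBundle(core=[row])
    write_data_files(bundle, tmp_path)
    assert (tmp_path / "taxon.csv").exists()
    assert not (tmp_path / "distribution.csv").exists()
    descriptor = build_descriptor(bundle)
    assert descriptor.extensions == []


def test_write_is_byte_deterministic(case_bundle, tmp_path):
    d1, d2 = tmp_path / "one", tmp_path / "two"
    z1 = write_all(case_bundle, d1)
    z2 = write_all(case_bundle, d2)
    for name in ("taxon.csv", "distribution.csv", "meta.xml", "eml.xml"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
    assert z1.read_bytes() == z2.read_bytes()


def test_meta_xml_declares_extensions_and_id_indexes(case_bundle, tmp_path):
    write_data_files(case_bundle, tmp_path)
    meta = write_meta_xml(case_bundle, tmp_path)
    root = etree.parse(str(meta)).getroot()
    core = root.find(f"{{{DWC_TEXT_NS}}}core")
    extensions = root.findall(f"{{{DWC_TEXT_NS}}}extension")
    assert core.get("rowType") == ROW_TYPE_URIS["core"]
    assert len(extensions) == 3  # worked bundle populates all three extensions
    # id/coreid indexes point at the taxonID column in every file
    id_index = int(core.find(f"{{{DWC_TEXT_NS}}}id").get("index"))
    fields = core.findall(f"{{{DWC_TEXT_NS}}}field")
    assert fields[id_index].get("term") == term_uri("taxonID")
    for ext in extensions:
        coreid = int(ext.find(f"{{{DWC_TEXT_NS}}}coreid").get("index"))
        ext_fields = ext.findall(f"{{{DWC_TEXT_NS}}}field")
        assert ext_fields[coreid].get("term") == term_uri("taxonID")


def test_descriptor_term_uri_matches_header_at_every_index(case_bundle, tmp_path):
    write_data_files(case_bundle, tmp_path)
    write_meta_xml(case_bundle, tmp_path)
    root = etree.parse(str(tmp_path / "meta.xml")).getroot()
    for el in [root.find(f"{{{DWC_TEXT_NS}}}core"),
               *root.findall(f"{{{DWC_TEXT_NS}}}extension")]:
        location = el.findtext(f"{{{DWC_TEXT_NS}}}files/{{{DWC_TEXT_NS}}}location")
        header = (tmp_path / location).read_text().splitlines()[0].split(",")
        for field in el.findall(f"{{{DWC_TEXT_NS}}}field"):
            index = int(field.get("index"))
            assert field.get("term") == term_uri(header[index])


def test_eml_structure_and_license(case_metadata, tmp_path):
    path = write_eml(case_metadata, tmp_path)
    assert validate_eml(path) == []
    text = path.read_text()
    assert "Manual of the Alien Plants of Belgium" in text
    assert "http://creativecommons.org/publicdomain/zero/1.0/" in text


def test_eml_refuses_non_gbif_license(tmp_path):
    with pytest.raises(ConfigurationError):
        EmlMetadata(title="t", license_uri="https://example.org/license")


def test_eml_validator_flags_missing_title(tmp_path):
    bad = tmp_path / "eml.xml"
    bad.write_text(
        '<eml:eml xmlns:eml="eml://ecoinformatics.org/eml-2.1.1">'
        "<dataset><creator><individualName><surName>X</surName>"
        "</individualName></creator>"
        '<intellectualRights><para><ulink url="http://creativecommons.org/publicdomain/zero/1.0/">'
        "<citetitle>CC0</citetitle></ulink></para></intellectualRights>"
        "</dataset></eml:eml>"
    )
    assert any("title" in p for p in validate_eml(bad))


def test_assemble_refuses_without_descriptor_or_metadata(case_bundle, tmp_path):
    write_data_files(case_bundle, tmp_path)
    with pytest.raises(DwcForgeError, match="meta.xml"):
        assemble_archive(tmp_path)
    write_meta_xml(case_bundle, tmp_path)
    with pytest.raises(DwcForgeError, match="eml.xml"):
        assemble_archive(tmp_path)


def test_zip_contains_exactly_the_expected_members(case_bundle, tmp_path):
    import zipfile
    z = write_all(case_bundle, tmp_path)
    with zipfile.ZipFile(z) as zf:
        assert sorted(zf.namelist()) == sorted([
            "taxon.csv", "distribution.csv", "speciesprofile.csv",
            "description.csv", "meta.xml", "eml.xml",
        ])


def test_round_trip_reconstructs_bundle_field_for_field(case_bundle, tmp_path):
    z = write_all(case_bundle, tmp_path)
    result = read_archive(z)
    assert result.warnings == []
    assert result.bundle.core == case_bundle.core
    assert result.bundle.distribution == case_bundle.distribution
    assert result.bundle.speciesprofile == case_bundle.speciesprofile
    assert result.bundle.description == case_bundle.description


def test_round_trip_on_synthetic_bundle(synthetic_bundle, case_metadata, tmp_path):
    z = write_all(synthetic_bundle, tmp_path, metadata=case_metadata)
    result = read_archive(z)
    for name in ("core", "distribution", "speciesprofile", "description"):
        assert result.bundle.rows_for(name) == synthetic_bundle.rows_for(name)


def test_unknown_term_uri_is_preserved_verbatim_with_warning(case_bundle, tmp_path):
    z = write_all(case_bundle, tmp_path)
    # append a column with an unrecognized term URI to the core declaration
    meta = tmp_path / "meta.xml"
    root = etree.parse(str(meta)).getroot()
    core = root.find(f"{{{DWC_TEXT_NS}}}core")
    n = len(core.findall(f"{{{DWC_TEXT_NS}}}field"))
    etree.SubElement(core, f"{{{DWC_TEXT_NS}}}field", index=str(n),
                     term="http://example.org/terms/mysteryTerm")
    meta.write_bytes(etree.tostring(root, xml_declaration=True, encoding="UTF-8"))
    taxon = tmp_path / "taxon.csv"
    lines = taxon.read_text().splitlines()
    taxon.write_text(lines[0] + ",mystery\n" + lines[1] + ",42\n")
    z = assemble_archive(tmp_path)
    result = read_archive(z)
    assert any("mysteryTerm" in w for w in result.warnings)
    assert result.bundle.core[0].extras == (("http://example.org/terms/mysteryTerm", "42"),)


# ---------------------------------------------------------------------------
# star-schema validation
# ---------------------------------------------------------------------------

def test_worked_bundle_validates_clean(case_bundle):
    report = validate_star_schema(case_bundle)
    assert report.passed and report.findings == []


def test_single_orphan_yields_exactly_one_error(case_bundle):
    bundle = ArchiveBundle(
        core=list(case_bundle.core),
        distribution=list(case_bundle.distribution),
        speciesprofile=list(case_bundle.speciesprofile),
        description=list(case_bundle.description),
    )
    bundle.distribution.append(replace(
        bundle.distribution[0],
        taxonID="alien-plants-belgium:taxon:" + "f" * 32,
    ))
    report = validate_star_schema(bundle)
    assert len(report.errors) == 1
    assert report.errors[0].rule == "orphan-extension-row"


def test_malformed_taxon_id_and_empty_name_detected():
    bundle = ArchiveBundle(core=[TaxonCoreRow(taxonID="not-an-id", scientificName="")])
    rules = {f.rule for f in validate_star_schema(bundle).errors}
    assert rules == {"malformed-taxon-id", "empty-scientific-name"}


@pytest.mark.parametrize("seed", range(1, 11))
def test_validator_recall_equals_injected_defect_count(seed, case_spec):
    """k injected orphan/duplicate/vocabulary defects -> exactly k errors;
    zero defects -> zero findings (n=200 per seed)."""
    checklist, _ = generate_checklist(GeneratorParams(n_taxa=200, seed=seed))
    bundle = map_checklist(checklist, case_spec)
    assert validate_star_schema(bundle).findings == []
    corrupted, ledger = corrupt_bundle(
        bundle, seed=seed, n_orphans=2, n_duplicates=2, n_vocab=1
    )
    report = validate_star_schema(corrupted)
    assert len(report.errors) == ledger.k == 5
    assert sorted(f.rule for f in report.errors) == sorted(
        {"orphan": "orphan-extension-row",
         "duplicate-taxon-id": "duplicate-taxon-id",
         "vocabulary": "vocabulary"}[d["kind"]] for d in ledger.defects
    )
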