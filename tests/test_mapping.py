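"""Identifier minting and the static/unaltered/altered rule algebra."""

import pytest
from hypothesis import given, settings, strategies as st

from dwcforge.core import (
    ConfigurationError,
    MappingError,
    MappingSpec,
    SourceChecklist,
    TermRule,
)
from dwcforge.mapping import (
    MappedTable,
    apply_altered_rule,
    apply_static_rule,
    apply_unaltered_rule,
    mint_taxon_id,
    post_process,
)
from dwcforge.transforms import map_checklist


# ---------------------------------------------------------------------------
# mint_taxon_id — the two published reference identifiers fix the convention
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "name, expected",
    [
        ("Acanthus mollis L.",
         "alien-plants-belgium:taxon:509ddbbaa5ecbb8d91899905cfc9491c"),
        ("Acanthus spinosus L.",
         "alien-plants-belgium:taxon:a65145fd1f24f081a1931f9874af48d9"),
    ],
)
def test_mint_matches_published_reference_identifiers(name, expected):
    assert mint_taxon_id(name, "Plantae", "alien-plants-belgium") == expected


def test_mint_is_deterministic_and_name_sensitive():
    a = mint_taxon_id("Bora minor DC.", "Plantae", "demo-list")
    assert a == mint_taxon_id("Bora minor DC.", "Plantae", "demo-list")
    assert a.startswith("demo-list:taxon:")
    assert a != mint_taxon_id("Bora minor Mill.", "Plantae", "demo-list")


def test_mint_handles_non_ascii_names():
    # oracle: R digest of the same UTF-8 string (frozen value)
    assert (
        mint_taxon_id("Acanthus × mollis L.", "Plantae", "demo-list")
        == "demo-list:taxon:c07a06ce9396b28963a102cca5e9017e"
    )


@pytest.mark.parametrize(
    "name, kingdom", [("", "Plantae"), ("Acanthus mollis L.", "")]
)
def test_mint_refuses_half_specified_taxa(name, kingdom):
    with pytest.raises(MappingError, match="refusing to mint"):
        mint_taxon_id(name, kingdom, "demo-list")


def test_mint_rejects_bad_shortname():
    with pytest.raises(ConfigurationError, match="shortname"):
        mint_taxon_id("Bora minor DC.", "Plantae", "Demo List")


# ---------------------------------------------------------------------------
# rule application
# ---------------------------------------------------------------------------

def _table(columns, rows):
    return MappedTable(source=SourceChecklist.from_records(columns, rows))


def _spec(**value_maps):
    return MappingSpec(dataset_shortname="demo-list", value_maps=value_maps)


def test_static_rule_sets_fixed_value_on_every_row():
    table = _table(["x"], [["1"], ["2"], ["3"]])
    rule = TermRule("nomenclaturalCode", "core", "static", value="ICN")
    apply_static_rule(rule, table)
    assert table.term("core", "nomenclaturalCode") == ["ICN"] * 3


def test_static_rule_on_empty_table_is_vacuous():
    table = _table(["x"], [])
    rule = TermRule("license", "core", "static",
                    value="http://creativecommons.org/publicdomain/zero/1.0/",
                    vocabulary="license")
    apply_static_rule(rule, table)
    assert table.term("core", "license") == []


def test_static_rule_vocabulary_failure_names_rule_and_value():
    table = _table(["x"], [["1"]])
    rule = TermRule("license", "core", "static", value="WTFPL", vocabulary="license")
    with pytest.raises(MappingError, match="license.*WTFPL"):
        apply_static_rule(rule, table)


def test_unaltered_rule_copies_cells_and_propagates_empties():
    table = _table(
        ["scientificNameID"],
        [["http://ipni.org/urn:lsid:ipni.org:names:44920-1"], [""]],
    )
    rule = TermRule("scientificNameID", "core", "unaltered",
                    source_columns=("scientificNameID",))
    apply_unaltered_rule(rule, table)
    values = table.term("core", "scientificNameID")
    assert values[0] == "http://ipni.org/urn:lsid:ipni.org:names:44920-1"
    assert values[1] is None  # empty source cell -> no value, not ""


def test_unaltered_rule_missing_column_is_configuration_error():
    table = _table(["a"], [["1"]])
    rule = TermRule("family", "core", "unaltered", source_columns=("family",))
    with pytest.raises(ConfigurationError, match="no column"):
        apply_unaltered_rule(rule, table)


def test_altered_rule_recodes_through_value_map():
    spec = _spec(stage={"Cas.": "casual", "Nat.": "naturalized"})
    table = _table(["D/N"], [["Cas."], ["Nat."], [""]])
    rule = TermRule("degreeOfEstablishment", "core", "altered",
                    source_columns=("D/N",), transform="recode",
                    transform_params={"value_map": "stage"})
    apply_altered_rule(rule, table, spec)
    assert table.term("core", "degreeOfEstablishment") == ["casual", "naturalized", None]


@pytest.mark.parametrize(
    "policy, expectation",
    [
        ("error", None),
        ("skip", [None]),
        ("flag", ["UNMAPPED:Z"]),
    ],
)
def test_unknown_code_policies(policy, expectation):
    spec = MappingSpec(dataset_shortname="demo-list",
                       value_maps={"presence": {"X": "present"}},
                       unknown_policy=policy)
    table = _table(["presence_Fl"], [["Z"]])
    rule = TermRule("occurrenceStatus", "core", "altered",
                    source_columns=("presence_Fl",), transform="recode",
                    transform_params={"value_map": "presence"})
    if expectation is None:
        with pytest.raises(MappingError, match="row 0.*'Z'"):
            apply_altered_rule(rule, table, spec)
    else:
        apply_altered_rule(rule, table, spec)
        assert table.term("core", "occurrenceStatus") == expectation


def test_unregistered_transform_is_configuration_error():
    spec = _spec()
    table = _table(["a"], [["1"]])
    rule = TermRule("x", "core", "altered", source_columns=("a",),
                    transform="frobnicate")
    with pytest.raises(ConfigurationError, match="frobnicate.*not registered"):
        apply_altered_rule(rule, table, spec)


def test_post_process_drops_source_and_orders_terms():
    table = _table(["src"], [["a"], ["b"]])
    apply_static_rule(TermRule("kingdom", "core", "static", value="Plantae"), table)
    apply_unaltered_rule(
        TermRule("scientificName", "core", "unaltered", source_columns=("src",)),
        table,
    )
    out = post_process(table, {"core": ["scientificName", "kingdom"]})
    assert out == {"core": [
        {"scientificName": "a", "kingdom": "Plantae"},
        {"scientificName": "b", "kingdom": "Plantae"},
    ]}


def test_post_process_refuses_undeclared_term():
    table = _table(["src"], [["a"]])
    with pytest.raises(ConfigurationError, match="no rule produced"):
        post_process(table, {"core": ["scientificName"]})


# ---------------------------------------------------------------------------
# whole-pipeline properties
# ---------------------------------------------------------------------------

def test_permuting_rows_changes_no_taxon_id(case_spec, clean_checklist_200):
    checklist, _ = clean_checklist_200
    bundle = map_checklist(checklist, case_spec)
    permuted = checklist.with_data(checklist.columns, list(reversed(checklist.rows)))
    bundle_perm = map_checklist(permuted, case_spec)
    ids = [r.taxonID for r in bundle.core]
    assert [r.taxonID for r in bundle_perm.core] == list(reversed(ids))
    assert set(ids) == {r.taxonID for r in bundle_perm.core}


def test_adding_a_taxon_changes_no_existing_row(case_spec, case_checklist):
    bundle_one = map_checklist(case_checklist, case_spec)
    extra = list(case_checklist.rows) + [(
        "Borago officinalis L.", "Boraginaceae", "species",
        "http://ipni.org/urn:lsid:ipni.org:names:12345-1",
        "X", "X", "", "1950", "2000", "E", "Nat.", "Agric.", "T",
    )]
    bundle_two = map_checklist(
        case_checklist.with_data(case_checklist.columns, extra), case_spec
    )
    assert bundle_two.core[0] == bundle_one.core[0]
    assert bundle_two.distribution[0] == bundle_one.distribution[0]
    assert len(bundle_two.core) == 2


@settings(max_examples=25, deadline=None)
@given(cells=st.lists(
    st.text(alphabet="abc XYZ.", min_size=0, max_size=8), min_size=1, max_size=8,
))
def test_rule_kind_oracle(cells):
    """For every row: a static rule's output is row-independent and an
    unaltered rule's output equals the source cell."""
    table = _table(["src"], [[c] for c in cells])
    apply_static_rule(TermRule("datasetName", "core", "static", value="fixed"), table)
    apply_unaltered_rule(
        TermRule("verbatim", "core", "unaltered", source_columns=("src",)), table
    )
    statics = table.term("core", "datasetName")
    copies = table.term("core", "verbatim")
    assert set(statics) == {"fixed"}
    for cell, copied in zip(cells, copies):
        assert copied == (cell if cell != "" else None)
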