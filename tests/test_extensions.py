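"""Extension builders: presence unpivot, eventDate intervals, habitat flags
and typed description rows — with the generator ledger as counting oracle."""

import pytest

from dwcforge.core import MappingError, RegionBinding
from dwcforge.transforms import (
    build_description_rows,
    build_event_date,
    map_checklist,
    map_habitat_flags,
    unpivot_presence,
)
from dwcforge.vocab import check_term, check_event_date
from dwcforge.archive import BOUND_TERMS

REGIONS = [
    RegionBinding("presence_Fl", "ISO_3166-2:BE-VLG", "flemish region"),
    RegionBinding("presence_Br", "ISO_3166-2:BE-BRU", "brussels-capital region"),
    RegionBinding("presence_Wa", "ISO_3166-2:BE-WAL", "walloon region"),
]
PRESENCE = {"X": "present", "?": "doubtful", "-": "absent-skip"}
CONSTANTS = {"countryCode": "BE", "establishmentMeans": "introduced"}


def test_unpivot_single_present_region_reproduces_worked_cells():
    rows = unpivot_presence(
        {"presence_Fl": "X", "presence_Br": "", "presence_Wa": ""},
        REGIONS, PRESENCE, "t:taxon:0", CONSTANTS, "2016/2018",
    )
    assert len(rows) == 1
    row = rows[0]
    assert row.locationID == "ISO_3166-2:BE-VLG"
    assert row.locality == "flemish region"
    assert row.countryCode == "BE"
    assert row.occurrenceStatus == "present"
    assert row.establishmentMeans == "introduced"
    assert row.eventDate == "2016/2018"


def test_unpivot_emits_one_row_per_present_region():
    rows = unpivot_presence(
        {"presence_Fl": "X", "presence_Br": "X", "presence_Wa": "X"},
        REGIONS, PRESENCE, "t:taxon:0", CONSTANTS, None,
    )
    assert [r.locationID for r in rows] == [
        "ISO_3166-2:BE-VLG", "ISO_3166-2:BE-BRU", "ISO_3166-2:BE-WAL"
    ]
    assert all(r.eventDate == "" for r in rows)


def test_unpivot_skip_code_and_unknown_policy():
    record = {"presence_Fl": "-", "presence_Br": "Z", "presence_Wa": ""}
    assert unpivot_presence(record, REGIONS, PRESENCE, "t", CONSTANTS, None,
                            policy="skip") == []
    with pytest.raises(MappingError, match="'Z'"):
        unpivot_presence(record, REGIONS, PRESENCE, "t", CONSTANTS, None,
                         policy="error", row_index=4)


def test_region_binding_exposes_iso_code():
    assert REGIONS[0].iso_3166_2_code == "BE-VLG"
    assert check_term("iso3166-2-BE", REGIONS[1].iso_3166_2_code)


@pytest.mark.parametrize(
    "fr, mrr, expected",
    [
        ("2016", "2018", "2016/2018"),
        ("1999", "1999", "1999"),          # degenerate interval collapses
        ("2016", "", "2016"),
        ("", "2018", "2018"),
        ("", "", None),
        ("ca. 1813", "1970?", "1813/1970"),  # annotations pre-parsed away
        ("<2000", "", "2000"),
    ],
)
def test_build_event_date(fr, mrr, expected):
    value = build_event_date(fr, mrr)
    assert value == expected
    if value is not None:
        assert check_event_date(value)


def test_build_event_date_reversed_is_an_error():
    with pytest.raises(MappingError, match="reversed"):
        build_event_date("2018", "2016")


def test_build_event_date_unparseable_cells_yield_no_value():
    assert build_event_date("unknown", "n.d.") is None


HABITATS = {"T": ("FALSE", "TRUE"), "F": ("TRUE", "FALSE"), "T/F": ("TRUE", "TRUE")}


@pytest.mark.parametrize(
    "code, expected",
    [
        ("T", ("FALSE", "FALSE", "TRUE")),
        ("F", ("FALSE", "TRUE", "FALSE")),
        ("T/F", ("FALSE", "TRUE", "TRUE")),
        ("", None),
        ("M", None),  # unmapped habitat: no row rather than guesses
    ],
)
def test_map_habitat_flags(code, expected):
    assert map_habitat_flags(code, HABITATS) == expected


def test_description_rows_for_worked_taxon(case_spec):
    record = {"origin": "E", "V/I": "Hort.", "D/N": "Cas."}
    rows = build_description_rows(record, case_spec, "t:taxon:0")
    assert [(r.description, r.type, r.language) for r in rows] == [
        ("Europe (WGSRPD:1)", "native range", "en"),
        ("cbd_2014_pathway:escape_horticulture", "pathway", "en"),
        ("casual", "invasion stage", "en"),
    ]


def test_description_rows_split_multi_values_in_source_order(case_spec):
    record = {"origin": "", "V/I": "Seeds,Hort.", "D/N": ""}
    rows = build_description_rows(record, case_spec, "t")
    assert [r.description for r in rows] == [
        "cbd_2014_pathway:contaminant_seed",
        "cbd_2014_pathway:escape_horticulture",
    ]


def test_description_rows_empty_fields_yield_nothing(case_spec):
    assert build_description_rows({"origin": "", "V/I": "", "D/N": ""},
                                  case_spec, "t") == []


# ---------------------------------------------------------------------------
# conservation + vocabulary closure over a whole synthetic archive
# ---------------------------------------------------------------------------

def test_distribution_count_equals_ledger_presence_cells(
    clean_checklist_200, synthetic_bundle
):
    _, ledger = clean_checklist_200
    assert len(synthetic_bundle.distribution) == ledger.non_skip_presence_cells


def test_speciesprofile_and_description_counts_match_ledger(
    clean_checklist_200, synthetic_bundle
):
    _, ledger = clean_checklist_200
    assert len(synthetic_bundle.speciesprofile) == ledger.mappable_habitats
    assert len(synthetic_bundle.description) == ledger.expected_description_rows


def test_every_bound_term_in_synthetic_archive_passes_its_vocabulary(
    synthetic_bundle,
):
    for (file_key, term), vocab_name in BOUND_TERMS.items():
        for row in synthetic_bundle.rows_for(file_key):
            value = getattr(row, term)
            if value:
                assert check_term(vocab_name, value), (file_key, term, value)
    for row in synthetic_bundle.speciesprofile:
        assert {row.isMarine, row.isFreshwater, row.isTerrestrial} <= {"TRUE", "FALSE"}
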