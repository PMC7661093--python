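# Mapping spec for the worked example: the Belgian alien-plants checklist.
# The source-code encodings (presence, habitat, origin, V/I, D/N) are
# configuration data; the published output cells are the fixed points.
spec_version: "1"
version: "2020-05"
dataset_shortname: alien-plants-belgium
unknown_policy: error
multi_value_separator: ","

constants:
  language: en
  license: http://creativecommons.org/publicdomain/zero/1.0/
  rightsHolder: Botanic Garden Meise
  datasetID: https://doi.org/10.15468/wtda1m
  datasetName: Manual of the Alien Plants of Belgium
  kingdom: Plantae
  nomenclaturalCode: ICN
  countryCode: BE
  establishmentMeans: introduced
  isMarine: "FALSE"

term_rules:
  - {term: language, file: core, kind: static, value: en, vocabulary: language}
  - {term: license, file: core, kind: static,
     value: "http://creativecommons.org/publicdomain/zero/1.0/", vocabulary: license}
  - {term: rightsHolder, file: core, kind: static, value: Botanic Garden Meise}
  - {term: datasetID, file: core, kind: static, value: "https://doi.org/10.15468/wtda1m"}
  - {term: datasetName, file: core, kind: static,
     value: Manual of the Alien Plants of Belgium}
  - {term: taxonID, file: core, kind: altered, source_columns: [taxon],
     transform: mint_taxon_id}
  - {term: scientificNameID, file: core, kind: unaltered, source_columns: [scientificNameID]}
  - {term: scientificName, file: core, kind: unaltered, source_columns: [taxon]}
  - {term: kingdom, file: core, kind: static, value: Plantae}
  - {term: family, file: core, kind: unaltered, source_columns: [family]}
  - {term: taxonRank, file: core, kind: unaltered, source_columns: [taxonRank],
     vocabulary: taxonRank}
  - {term: nomenclaturalCode, file: core, kind: static, value: ICN}

region_map:
  - {source_column: presence_Fl, location_id: "ISO_3166-2:BE-VLG", locality: flemish region}
  - {source_column: presence_Br, location_id: "ISO_3166-2:BE-BRU", locality: brussels-capital region}
  - {source_column: presence_Wa, location_id: "ISO_3166-2:BE-WAL", locality: walloon region}

value_maps:
  source_columns:
    scientific_name: taxon
    first_record: FR
    most_recent_record: MRR
    habitat: habitat
  presence:
    "X": present
    "?": doubtful
    "-": absent-skip
  habitat:            # code -> [isFreshwater, isTerrestrial]
    "T": ["FALSE", "TRUE"]
    "F": ["TRUE", "FALSE"]
    "T/F": ["TRUE", "TRUE"]
    "F/T": ["TRUE", "TRUE"]
  description_columns:
    origin: origin
    pathway: V/I
    invasion_stage: D/N
  origin:
    "E": "Europe (WGSRPD:1)"
    "AF": "Africa (WGSRPD:2)"
    "AS-Te": "Asia-Temperate (WGSRPD:3)"
    "AS-Tr": "Asia-Tropical (WGSRPD:4)"
    "AUS": "Australasia (WGSRPD:5)"
    "PAC": "Pacific (WGSRPD:6)"
    "NAM": "Northern America (WGSRPD:7)"
    "SAM": "Southern America (WGSRPD:8)"
    "ANT": "Antarctic (WGSRPD:9)"
  pathway:
    "Hort.": "cbd_2014_pathway:escape_horticulture"
    "Agric.": "cbd_2014_pathway:escape_agriculture"
    "Orn.": "cbd_2014_pathway:escape_ornamental"
    "Seeds": "cbd_2014_pathway:contaminant_seed"
    "Wool": "cbd_2014_pathway:contaminant_on_animals"
    "Ballast": "cbd_2014_pathway:stowaway_ballast_water"
    "Tourists": "cbd_2014_pathway:stowaway_people"
  invasion_stage:
    "Cas.": casual
    "Nat.": naturalized
    "Inv.": invasive
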