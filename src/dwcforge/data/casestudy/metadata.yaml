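# Dataset metadata for the worked example (GBIF Metadata Profile subset).
title: Manual of the Alien Plants of Belgium
creators:
  - {surname: Verloove, given_name: Filip, organization: Botanic Garden Meise, role: author}
  - {surname: Groom, given_name: Quentin, organization: Botanic Garden Meise, role: author}
abstract: >
  Authoritative checklist of the non-native vascular plants recorded in
  Belgium since 1800, with per-region occurrence status, dates of first and
  most recent observation, native range, degree of naturalization, vector
  of introduction and habitat.
license_uri: http://creativecommons.org/publicdomain/zero/1.0/
license_name: Creative Commons Zero (CC0) 1.0
geographic_coverage: Belgium (Flanders, Wallonia and the Brussels-Capital Region)
taxonomic_coverage: Vascular plants (kingdom Plantae)
temporal_coverage: 1800/2020
project_description: >
  Published as part of an open species-registry workflow for tracking
  invasive alien species.
provenance_statement: >
  Source checklist maintained by the Botanic Garden Meise and transformed
  to Darwin Core with a versioned, declarative mapping specification; the
  transformation is deterministic and re-runnable on each checklist release.
pub_date: "2020-05-06"
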