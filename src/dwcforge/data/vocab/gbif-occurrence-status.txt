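# name: occurrenceStatus
# kind: closed-set
# source: http://rs.gbif.org/vocabulary/gbif/occurrence_status.xml
# version: 2015-07-10
present
common
rare
irregular
doubtful
absent
excluded
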