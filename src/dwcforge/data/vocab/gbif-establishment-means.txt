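# name: establishmentMeans
# kind: closed-set
# source: http://rs.gbif.org/vocabulary/gbif/establishment_means.xml
# version: 2015-04-17
native
introduced
naturalised
invasive
managed
uncertain
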