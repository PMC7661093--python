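# name: taxonRank
# kind: closed-set
# source: http://rs.gbif.org/vocabulary/gbif/rank.xml
# version: 2015-04-24
domain
kingdom
subkingdom
superphylum
phylum
subphylum
superclass
class
subclass
supercohort
cohort
subcohort
superorder
order
suborder
infraorder
superfamily
family
subfamily
tribe
subtribe
genus
subgenus
section
subsection
series
subseries
speciesAggregate
species
subspecificAggregate
subspecies
variety
subvariety
form
subform
cultivarGroup
cultivar
strain
informal
unranked
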