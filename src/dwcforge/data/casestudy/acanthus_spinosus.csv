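taxon,family,taxonRank,scientificNameID,presence_Fl,presence_Br,presence_Wa,FR,MRR,origin,D/N,V/I,habitat
Acanthus spinosus L.,Acanthaceae,species,http://ipni.org/urn:lsid:ipni.org:names:44920-1,X,,,2016,2018,E,Cas.,Hort.,T
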