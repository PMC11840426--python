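collection_id,taxon,age_class,pellets_containing,individuals
Historic,Sminthopsis douglasi,unknown,,13
Historic,Sminthopsis macroura,unknown,,
Historic,Planigale spp.,unknown,,
Historic,Rattus villosissimus,unknown,,137
Historic,Leggadina forresti,unknown,,47
Historic,Mus musculus,unknown,,
Historic,Aves spp.,unknown,,108
Historic,Squamata,unknown,,26
Historic,Anura,unknown,,14
Historic,unidentifiable,unknown,,
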