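collection_id,taxon,age_class,pellets_containing,individuals
Initial,Sminthopsis douglasi,juvenile,30,36
Initial,Sminthopsis douglasi,adult,82,99
Initial,Sminthopsis macroura,juvenile,7,9
Initial,Sminthopsis macroura,adult,6,7
Initial,Planigale spp.,unknown,32,46
Initial,Rattus villosissimus,juvenile,16,20
Initial,Rattus villosissimus,adult,83,86
Initial,Leggadina forresti,juvenile,0,0
Initial,Leggadina forresti,adult,2,2
Initial,Taeniopygia sp.,unknown,24,51
Initial,Artamus sp.,unknown,16,17
Initial,Mirafra javanica,unknown,10,11
Initial,Melopsittacus undulatus,unknown,5,6
Initial,Anthus australis,unknown,2,2
Initial,Aves spp.,unknown,23,26
Initial,Anura,unknown,3,4
Initial,Gekkonidae,unknown,1,1
Initial,Agamidae,unknown,0,0
Initial,unidentifiable,unknown,16,16
Winter,Sminthopsis douglasi,juvenile,18,19
Winter,Sminthopsis douglasi,adult,46,49
Winter,Sminthopsis macroura,juvenile,5,6
Winter,Sminthopsis macroura,adult,6,7
Winter,Planigale spp.,unknown,19,36
Winter,Rattus villosissimus,juvenile,34,57
Winter,Rattus villosissimus,adult,79,93
Winter,Leggadina forresti,juvenile,0,0
Winter,Leggadina forresti,adult,2,2
Winter,Taeniopygia sp.,unknown,26,42
Winter,Artamus sp.,unknown,13,15
Winter,Mirafra javanica,unknown,10,10
Winter,Melopsittacus undulatus,unknown,5,7
Winter,Anthus australis,unknown,0,0
Winter,Aves spp.,unknown,43,51
Winter,Anura,unknown,4,4
Winter,Gekkonidae,unknown,1,1
Winter,Agamidae,unknown,3,3
Winter,unidentifiable,unknown,25,25
Summer,Sminthopsis douglasi,juvenile,4,4
Summer,Sminthopsis douglasi,adult,19,20
Summer,Sminthopsis macroura,juvenile,1,1
Summer,Sminthopsis macroura,adult,3,3
Summer,Planigale spp.,unknown,8,14
Summer,Rattus villosissimus,juvenile,24,30
Summer,Rattus villosissimus,adult,79,85
Summer,Leggadina forresti,juvenile,1,1
Summer,Leggadina forresti,adult,3,3
Summer,Taeniopygia sp.,unknown,3,4
Summer,Artamus sp.,unknown,3,3
Summer,Mirafra javanica,unknown,2,2
Summer,Melopsittacus undulatus,unknown,1,1
Summer,Anthus australis,unknown,2,2
Summer,Aves spp.,unknown,9,9
Summer,Anura,unknown,0,0
Summer,Gekkonidae,unknown,0,0
Summer,Agamidae,unknown,0,0
Summer,unidentifiable,unknown,19,19
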