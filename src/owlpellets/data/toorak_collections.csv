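collection_id,n_pellets_total,n_individuals_total,date_range,notes
Initial,280,439,up to April 2023,undated initial roost clearance; possibly ~5 years of pellets
Winter,269,427,April-October 2023,collections 2 and 3 combined (156 + 113 pellets)
Summer,157,201,October 2023-April 2024,collection 4; rodent plague in force
Historic,210,400,1994-2001,published historical dataset; only some per-taxon counts reconstructible
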