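species,test_min_cm,test_max_cm,erosion_kg_ind_yr,provenance
Echinometra mathaei,0,3,0.05,synthetic stand-in
Echinometra mathaei,3,6,0.15,synthetic stand-in
Echinometra mathaei,6,10,0.30,synthetic stand-in
Diadema setosum,0,5,0.50,synthetic stand-in
Diadema setosum,5,12,1.50,synthetic stand-in
Echinothrix calamaris,0,12,0.80,synthetic stand-in
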