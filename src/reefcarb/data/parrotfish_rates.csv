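species_or_group,size_min_cm,size_max_cm,bite_rate_h,feeding_hours,scar_fraction,scar_volume_cm3,substrate_density_g_cm3,provenance
scraper,10,20,180,8,0.05,0.03,1.5,synthetic stand-in
scraper,20,30,150,8,0.08,0.10,1.5,synthetic stand-in
scraper,30,40,120,8,0.10,0.30,1.5,synthetic stand-in
scraper,40,60,100,8,0.10,0.60,1.5,synthetic stand-in
excavator,10,20,150,8,0.25,0.10,1.5,synthetic stand-in
excavator,20,30,130,8,0.35,0.35,1.5,synthetic stand-in
excavator,30,40,110,8,0.40,0.60,1.5,synthetic stand-in
excavator,40,60,90,8,0.50,1.50,1.5,synthetic stand-in
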