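genus,morphology,growth_mean_cm_yr,growth_lo95_cm_yr,growth_hi95_cm_yr,density_g_cm3,geometry_multiplier,provenance
Acropora,branching,0.40,0.30,0.50,1.50,1.0,synthetic stand-in
Acropora,table,0.82,0.62,1.02,1.40,1.0,synthetic stand-in
Pocillopora,branching,0.35,0.26,0.44,1.55,1.0,synthetic stand-in
Porites,massive,0.19,0.14,0.24,1.80,1.0,synthetic stand-in
Porites,encrusting,0.11,0.08,0.14,1.60,1.0,synthetic stand-in
Montipora,encrusting,0.11,0.08,0.14,1.60,1.0,synthetic stand-in
Favites,massive,0.17,0.12,0.22,1.75,1.0,synthetic stand-in
OtherCoral,other,0.20,0.14,0.26,1.60,1.0,synthetic stand-in
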