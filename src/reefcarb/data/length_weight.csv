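species,a,b,group,provenance
Chlorurus sordidus,0.0150,3.04,excavator,synthetic stand-in
Chlorurus strongylocephalus,0.0165,3.00,excavator,synthetic stand-in
Scarus ghobban,0.0140,3.02,scraper,synthetic stand-in
Scarus frenatus,0.0180,2.95,scraper,synthetic stand-in
Scarus rubroviolaceus,0.0160,2.98,scraper,synthetic stand-in
Hipposcarus harid,0.0130,3.00,scraper,synthetic stand-in
Calotomus carolinus,0.0210,2.90,browser,synthetic stand-in
Leptoscarus vaigiensis,0.0190,2.92,browser,synthetic stand-in
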