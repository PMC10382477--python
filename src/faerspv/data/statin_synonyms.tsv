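# HMG-CoA reductase inhibitors (statins): CANONICAL<TAB>SYNONYM
atorvastatin	ATORVASTATIN
atorvastatin	ATORVASTATIN CALCIUM
atorvastatin	LIPITOR
simvastatin	SIMVASTATIN
simvastatin	ZOCOR
rosuvastatin	ROSUVASTATIN
rosuvastatin	ROSUVASTATIN CALCIUM
rosuvastatin	CRESTOR
pravastatin	PRAVASTATIN
pravastatin	PRAVASTATIN SODIUM
pravastatin	PRAVACHOL
lovastatin	LOVASTATIN
lovastatin	MEVACOR
lovastatin	ALTOPREV
fluvastatin	FLUVASTATIN
fluvastatin	FLUVASTATIN SODIUM
fluvastatin	LESCOL
pitavastatin	PITAVASTATIN
pitavastatin	LIVALO
cerivastatin	CERIVASTATIN
cerivastatin	BAYCOL
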