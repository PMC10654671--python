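token	canonical	category	description
mcrA	mcrA	methanogenesis_marker	methyl-coenzyme M reductase alpha subunit
mcrB	mcrB	methanogenesis_marker	methyl-coenzyme M reductase beta subunit
mcrC	mcrC	methanogenesis_marker	methyl-coenzyme M reductase component C
mcrD	mcrD	methanogenesis_marker	methyl-coenzyme M reductase component D
mcrG	mcrG	methanogenesis_marker	methyl-coenzyme M reductase gamma subunit
pmoA	pmoA	methanotrophy_marker	particulate methane monooxygenase alpha subunit
pmoB	pmoB	methanotrophy_marker	particulate methane monooxygenase beta subunit
pmoC	pmoC	methanotrophy_marker	particulate methane monooxygenase gamma subunit
mmoX	mmoX	methanotrophy_marker	soluble methane monooxygenase alpha subunit
mmoY	mmoY	methanotrophy_marker	soluble methane monooxygenase beta subunit
mmoZ	mmoZ	methanotrophy_marker	soluble methane monooxygenase gamma subunit
mtsA	mtsA	methylthiol_transferase	methylthiol:coenzyme M methyltransferase
mtaA	mtaA	methylthiol_transferase	methylcobalamin:coenzyme M methyltransferase
mtaB	mtaB	methyl_methanol	methanol:corrinoid methyltransferase
mttB	mttB	methyl_trimethylamine	trimethylamine:corrinoid methyltransferase
mtbB	mtbB	methyl_dimethylamine	dimethylamine:corrinoid methyltransferase
mtmB	mtmB	methyl_methylamine	monomethylamine:corrinoid methyltransferase
acs	acs	acetate_activation	acetyl-CoA synthetase (AMP-forming)
pta	pta	acetate_activation	phosphotransacetylase
ack	ack	acetate_activation	acetate kinase
act	act	acetate_activation	acetyltransferase
Acetate pt 1	acs	acetate_activation	DRAM methanogenesis-sheet label for acetyl-CoA synthetase
Acetate pt 2	ack	acetate_activation	DRAM methanogenesis-sheet label for acetate kinase
Acetate pt 3	act	acetate_activation	DRAM methanogenesis-sheet label for acetyltransferase
SCFA and alcohol conversions: acetate pt. 1	pta	acetate_activation	DRAM SCFA-sheet label for phosphotransacetylase
SCFA and alcohol conversions: acetate pt. 2	ack	acetate_activation	DRAM SCFA-sheet label for acetate kinase
nirK	nirK	nitrogen_redox	copper-containing nitrite reductase (nitrite to nitric oxide)
nirS	nirS	nitrogen_redox	cytochrome cd1 nitrite reductase (nitrite to nitric oxide)
narG	narG	nitrogen_redox	membrane-bound nitrate reductase alpha subunit
napA	napA	nitrogen_redox	periplasmic nitrate reductase
norB	norB	nitrogen_redox	nitric oxide reductase
nosZ	nosZ	nitrogen_redox	nitrous oxide reductase
ureC	ureC	urea_hydrolysis	urease alpha subunit
phsA	phsA	sulfur_redox	thiosulfate reductase
sreA	sreA	sulfur_redox	thiosulfate/polysulfide reductase
ccoN	ccoN	complex_iv_high	cbb3-type (high-affinity) cytochrome c oxidase subunit I
coxA	coxA	complex_iv_low	aa3-type (low-affinity) cytochrome c oxidase subunit I
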