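gene_id	category	product	tu_id
sll0741	oxidoreductase	nifJ pyruvate-ferredoxin/flavodoxin oxidoreductase	TU3296
sll0743	oxidoreductase	hypothetical protein	TU3296
sll0744	oxidoreductase	dihydroorotate dehydrogenase (fumarate)	TU3296
sll1221	oxidoreductase	hoxF bidirectional [NiFe] hydrogenase diaphorase subunit	TU1714
sll1222	oxidoreductase	unknown protein	TU1714
sll1223	oxidoreductase	hoxU bidirectional [NiFe] hydrogenase diaphorase subunit	TU1714
sll1224	oxidoreductase	hoxY NAD-reducing hydrogenase small subunit	TU1714
sll1225	oxidoreductase	unknown protein	TU1714
sll1226	oxidoreductase	hoxH NAD-reducing hydrogenase large subunit	TU1714
slr1434	oxidoreductase	pntB H+-translocating NAD(P) transhydrogenase subunit beta	TU1089
sll1450	transporter	nrtA nitrate/nitrite transport system substrate binding protein	TU1023
sll1451	transporter	nrtB nitrate/nitrite transport system permease protein	TU1023
sll1452	transporter	nrtC nitrate/nitrite transport system ATP binding protein	TU1023
sll1453	transporter	nrtD nitrate/nitrite transport system ATP binding protein	TU1023
slr1214	two_component_system	twitching motility two-component system response regulator PilG	TU905
slr1215	two_component_system	unknown protein	TU907
slr2116	glycosyl_transferase	spsA spore coat polysaccharide biosynthesis protein	TU1673
sll1009	protease	frpC iron-regulated protein	TU491
slr1523	insertion_sequence	transposase	TU1659
sll1985	insertion_sequence	transposase	TU1589
sll7001	insertion_sequence	transposase	NA
sll7003	insertion_sequence	toxin FitB	TU7001
ssl0172	insertion_sequence	transposase	TU3163
slr1260	other	hypothetical protein	TU1446
slr0668	other	unknown protein	TU3532
slr5127	other	unknown protein	TU5127
sll0710	other	unknown protein	TU97
sll1307	other	unknown protein	TU1224
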