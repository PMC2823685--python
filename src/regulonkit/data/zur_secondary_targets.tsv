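cds	gene	product	m_array	rtpcr_fold
cg0045	-	ABC-type transporter, permease subunit	-1.12	n.s.
cg0215	cspA	cold-shock protein A	1.24	n.s.
cg0793	-	putative secreted protein	1.67	4.01
cg0796	prpD1	citrate dehydratase	1	6.68
cg1109	porB	anion-specific porin precursor	1.12	7.67
cg1332	-	putative secreted protein	1.42	2.57
cg1447	-	putative Co/Zn/Cd efflux transporter	3.16	25.8
cg1670	-	hypothetical protein	1.07	4.81
cg2181	-	ABC-type transporter, substrate-binding protein	1.1	4.91
cg2261	amtB	secondary ammonium transporter	-1.01	n.s.
cg2560	aceA	isocitrate lyase	1.56	n.s.
cg2925	ptsS	phosphotransferase system component	-1.35	n.s.
cg3096	ald	acetaldehyde dehydrogenase	1.69	103
cg3138	-	putative membrane protease subunit	3.14	n.s.
cg3139	-	hypothetical protein	2.03	n.s.
cg3140	tagA1	DNA-3-methyladenine glycolase I	1.88	n.s.
cg3195	-	putative flavin-containing monooxygenase	1.44	3.22
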