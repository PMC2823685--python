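cds	gene	product	motif	m_array	rtpcr_fold
cg0040	-	secreted protein	-	3.34	4.5
cg0041	znuA2	ABC-type Zn/Mn transporter, substrate-binding protein	-	5.68	27900
cg0042	znuB2	ABC-type Zn/Mn transporter, permease subunit	TAATGATAACGGTTATCATTT	2.25	331
cg0043	znuC2	ABC-type Zn/Mn transporter, ATPase subunit	AAATGATAACCGTTATCATTA	2.13	50.2
cg0794	yciC	P-loop GTPase of the COG0523 family	TATTGAAAATGATTCCCAAAA	2.75	10.5
cg0795	-	oxidoreductase	TAATGGAAATTGTTTTCAATA	5.43	45500
cg2911	znuA1	ABC-type Zn/Mn transporter, substrate-binding protein	TGTTGACATCCTTTTTCAATA	3.52	43.8
cg2912	znuC1	ABC-type Zn/Mn transporter, ATPase subunit	-	2.79	75.8
cg2913	znuB1	ABC-type Zn/Mn transporter, permease subunit	-	1.29	29.0
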