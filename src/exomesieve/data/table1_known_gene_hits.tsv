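patient	gene	hgvs	n_of_6	dbsnp	maf_exac_abraom	clinvar	acmg
SM001.049	ATM	c.7000_7003delTACA;p.(Tyr2334Glnfs*4)	–	rs786203421	ND/ND	Pathogenic	Pathogenic
MJ1007	BARD1	c.2215dupT; p.(Tyr739Leufs*2)	–	ND	ND/ND	ND	Probably Pathogenic
MJ2003	RINT1	c.961T>A; p.(Phe321Ile)	5 of 6	ND	ND/ND	ND	VUS
MJ2001	RAD51B	c.728A>G;p.(Lys243Arg)	4 of 6	rs34594234	0.007/0.005	ND	VUS
MJ2037	BRCA1	c.5006C>T p.(Ala1669Val)	5 of 6	ND	ND/ND	ND	VUS
MJ2007/2012	BRCA1	c.4963T>C; p.(Ser1655Pro)	6 of 6	ND	ND/ND	ND	VUS
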