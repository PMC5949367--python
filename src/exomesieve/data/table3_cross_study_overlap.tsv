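patient	gene	type_current	hgvs_current	dbsnp_current	maf_current	type_prior	hgvs_prior	dbsnp_prior	maf_prior	study
SM001.040	NOTCH2	missense	c.2292T>A; p.(Asn764Lys)	ND	0.00002/ND	missense	c.854G>A; p.(Arg285His)	rs782452794	0.000008/ND	Wen et al.
SM001.040	NOTCH2	missense	c.2292T>A; p.(Asn764Lys)	ND	0.00002/ND	missense	c.6178C>T; p.(Arg2060Cys)	rs746551843	0.000008/ND	Wen et al.
MJ2013S	CAPN9	splice site	c.1657+2T>G; p.(spl?)	rs143145032	0.001/0.002	frameshift del	c.1976_1982delAGAATG; p.(Glu659Glyfs*20)	ND	0.002/ND	Thompson et al.
MJ2014S and MJ2016S	DNAH7	nonsense	c.10359T>G; p.(Tyr3453*)	ND	0.000008/ND	frameshift ins	c.4787dupA; p.(Tyr1596*)	rs573013205	0.002/ND	Thompson et al.
SM001.06	MST1R	splice site	c.1231-1G>C; p.(spl?)	ND	0.00008/ND	nonsense	c.3322C>T; p.(Arg1108*)	rs150876558	0.0001/ND	Thompson et al.
SM001.088	MSH3	missense	c.2659G>A; p.(Asp887Asn)	ND	0.00002/ND	in frame del	c.162_179del; p.(Ala57_Ala62del)	ND	ND/ND	Thompson et al.
MJ2007/ MJ2012	ROS1	missense	c.1108T>C; p.(Ser370Pro)	rs56274823	0.002/ND	splice site	c.5079+2T>C; p.(spl?)	ND	ND/ND	Thompson et al.
MJ2007/ MJ2012	ROS1	missense	c.1108T>C; p.(Ser370Pro)	rs56274823	0.002/ND	nonsense	c.3303G>A; p.(Trp1101*)	rs200145587	0.00009/ND	Thompson et al.
MJ2004S	LAMB4	splice site	c.34+1G>A; p.(spl?)	rs7788865	0.001 (AF 0.0166)/ 0.003	frameshift del	c.5265delA; p.(Lys1755Asnfs*11)	rs568834649	0.008/0.004	Thompson et al.
SM001.040	DDX10	missense	c.1088G>A; p.(Arg363His)	ND	0.0001/ND	nonsense	c.973G>T; p.(Glu325*)	ND	ND/ND	Kiiski et al.
MJ2016S	PZP	nonsense	c.2038C>T; p.(Arg680*)	rs145240281	0.005/ND	nonsense	c.2038C>T; p.(Arg680*)	rs145240281	0.005 (EU 0.01013)/ ND	Thompson et al.
MJ2015S	KRT76	nonsense	c.826G>T; p.(Glu276*)	rs149868801	0.007/0.006	nonsense	c.826G>T; p.(Glu276*)	rs149868801	0.007/0.006	Thompson et al.
MJ2014S	NIN	in frame del	c.1736_1738delAAG; p.(Glu579del)	ND	0.0003/0.005	frameshift del	c.4261delG; p.(Glu1421Lysfs*18)	ND	ND/ND	Thompson et al.
MJ2013S	SLX4	missense	c.4766G>A; p.(Arg1589His)	rs746314060	0.00004/0.0008	missense	c.2484G>C; p.(Glu828Asp)	rs199656607	0.0001/ND	Kiiski et al.
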