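cohort	patient	gene	type	hgvs	n_of_6	dbsnp	maf_exac_abraom
discovery	SM001.040	NOTCH2	missense	c.2292T>A;p.(Asn764Lys)	6 of 6	ND	0.00002/ND
discovery	MJ2014S and MJ2016S	DNAH7	nonsense	c.10359T>G;p.(Tyr3453*)	–	ND	0.000008/ND
discovery	MJ2016S	RAF1	frameshift	c.1241dupA;p.(Asp415fs)	–	ND	ND/ND
discovery	SM001.06	MST1R	splice site	c.1231-1G>C;p.(spl?)	–	ND	0.00008/ND
discovery	MJ2004S	LAMB4	splice site	c.34+1G>A;p.(spl?)	–	rs7788865	0.001/0.003
discovery	MJ2014S	NIN	in frame del	c.1736_1738delAAG;p.(Glu579del)	–	ND	0.0003/0.005
discovery	MJ2013S	SLX4	missense	c.4766G>A;p.(Arg1589His)	5 of 6	rs74631406	0.00004/0.0008
discovery	MJ2037S	ERCC1	nonsense	c.875G>A;p.(Trp292*)	–	rs116640350	0.002 (AF0.02627)/0.0008
discovery	MJ2007/2012	SLC22A16	frameshift	c.226delG;p.(Ala76fs*66)	–	ND	ND/ND
discovery	MJ2007/2012	PTPRD	missense	c.1856C>T;p.(Thr619Ile)	2 of 6	ND	ND/0.0008
discovery	MJ2007/2012	ARHGEF12	missense	c.545C>T;p.(Ser182Phe)	3 of 6	rs147982337	0.002/0.002
discovery	MJ2007/2012	ERBB2	missense	c.563G>A;p.(Arg188His)	3 of 6	ND	0.00002/0.002
validation	-	NOTCH2	missense	c.2579T>G;p.(Leu860Trp)	3 of 6	ND	ND/ND
validation	-	NOTCH2	missense	c.3625T>G;p.(Phe1209Val)	5 of 6	rs147223770	0.003/0.002
validation	-	NOTCH2	missense	c.7223T>A;p.(Leu2408His)	4 of 6	rs35586704	0.002/0.007
validation	-	DNAH7	missense	c.3265C>T;p.(Pro1089Ser)	5 of 6	ND	ND/ND
validation	-	DNAH7	missense	c.11947C>T;p.(Arg3983Trp)	5 of 6	rs114621989	0.009/0.006
validation	-	RAF1	missense	c.923C>T;p.(Pro308Leu)	3 of 6	rs5746220	0.002/0.008
validation	-	MST1R	missense	c.4180T>A;p.(Ser1394Thr)	4 of 6	rs141338964	0.0002/ND
validation	-	LAMB4	missense	c.1843C>A;p.(Pro615Thr)	5 of 6	rs201909531	0.0003/0.0008
validation	-	NIN	missense	c.848C>T;p.(Ser283Leu)	3 of 6	rs763293400	0.0001/ND
validation	-	SLX4	missense	c.3368C>A;p.(Ser1123Tyr)	3 of 6	rs144647122	0.0003/0.0008
validation	-	ERCC1	nonsense	c.875G>A;p.(Trp292*)	–	rs116640350	0.002/0.0008
validation	-	SLC22A16	missense	c.599C>T;p.(Ala200Val)	5 of 6	rs61729086	0.003/0.005
validation	-	PTPRD	missense	c.2585G>T;p.(Arg862Leu)	5 of 6	rs142397137	0.0001/ND
validation	-	ARHGEF12	missense	c.3986G>A;p.(Arg1329Gln)	3 of 6	ND	ND/ND
validation	-	ERBB2	missense	c.236A>C;p.(Glu79Ala)	6 of 6	rs61737968	0.0009/0.005
validation	-	ERBB2	missense	c.1586T>C;p.(Val529Ala)	3 of 6	ND	ND/ND
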