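chrom_pos	ref_alt	gene	type	hgvs	n_of_6	dbsnp	maf_exac_abraom	present_in_aunt
1:3328745	G/A	PRDM16	Missense	c.1984G>A; p.(Val662Met)	1 of 6	ND	ND/0.001	No
1:116670844	G/T	MAB21L3	Stop gained	c.739G>T; p.(Glu247*)	2 of 6	rs149122915	0.0002/ND	No
3:48716158	G/A	NCKIPSD	Missense	c.1804C>T; p.(Arg602Cys)	2 of 6	ND	0.000008/0.001	No
5:149514363	A/G	PDGFRB	Missense	c.581T>C; p.(Ile194Thr)	5 of 6	rs2229560	0.001/0.002	No
6:117622137	C/T	ROS1	Missense	c.6733G>A; p.(Gly2245Ser)	2 of 6	rs142264513	0.0008/0.002	No
7:116380062	A/G	MET	Missense	c.1451A>G; p.(His484Arg)	2 of 6	ND	0.00005/ND	No
8:17815082	T/G	PCM1	Missense	c.1838T>G; p.(Ile613Ser)	0 of 6	rs181777656	0.003 (OT 0.01)/0.002	No
14:55467701	T/C	WDHD1	Missense	c.703A>G; p.(Ile235Val)	1 of 6	rs139440460	0.004/0.004	No
15:40897315	A/G	KNL1	Missense	c.43A>G; p.(Ile15Val)	0 of 6	ND	0.00003/ND	No
6:110778048	C/-	SLC22A16	Frameshift	c.226delG; p.(Ala76fs*66)	–	ND	ND/ND	Yes
6:117715381	A/G	ROS1	Missense	c.1108T>C; p.(Ser370Pro)	2 of 6	rs56274823	0.002/ND	Yes
9:6255967	G/C	IL33	Splice acceptor	c.613-1G>C; p.(spl?)	–	rs146597587	0.002/0.001	Yes
9:8501026	G/A	PTPRD	Missense	c.1856C>T; p.(Thr619Ile)	2 of 6	ND	ND/0.001	Yes
11:120298916	C/T	ARHGEF12	Missense	c.545C>T; p.(Ser182Phe)	3 of 6	rs147982337	0.002/0.002	Yes
17:37865694	G/A	ERBB2	Missense	c.563G>A; p.(Arg188His)	3 of 6	ND	0.00002/0.002	Yes
17:41222968	A/G	BRCA1	Missense	c.4963T>C; p.(Ser1655Pro)	6 of 6	ND	ND/ND	Yes
X:24861673	T/C	POLA1	Missense	c.3908T>C; p.(Met1303Thr)	2 of 6	ND	ND/ND	Yes
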