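gene	study	hgvs_c	variant_type
NOTCH2	Wen et al.	c.854G>A	missense
NOTCH2	Wen et al.	c.6178C>T	missense
CAPN9	Thompson et al.	c.1976_1982delAGAATG	frameshift del
DNAH7	Thompson et al.	c.4787dupA	frameshift ins
MST1R	Thompson et al.	c.3322C>T	nonsense
MSH3	Thompson et al.	c.162_179del	in frame del
ROS1	Thompson et al.	c.5079+2T>C	splice site
ROS1	Thompson et al.	c.3303G>A	nonsense
LAMB4	Thompson et al.	c.5265delA	frameshift del
DDX10	Kiiski et al.	c.973G>T	nonsense
PZP	Thompson et al.	c.2038C>T	nonsense
KRT76	Thompson et al.	c.826G>T	nonsense
NIN	Thompson et al.	c.4261delG	frameshift del
SLX4	Kiiski et al.	c.2484G>C	missense
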