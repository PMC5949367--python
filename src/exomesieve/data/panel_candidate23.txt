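# 23 candidate breast cancer predisposition genes: union of the 7
# family-segregating genes, 5 cancer-related genes with LOF variants,
# and 12 genes overlapping prior WES candidate catalogs (ROS1 is in
# two of the component lists).
SLC22A16
ROS1
IL33
PTPRD
ARHGEF12
ERBB2
POLA1
GALNT3
RAF1
PICALM
KL
ERCC1
CAPN9
KRT76
PZP
DNAH7
MST1R
LAMB4
NIN
MSH3
SLX4
DDX10
NOTCH2
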