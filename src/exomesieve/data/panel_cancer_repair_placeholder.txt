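# PLACEHOLDER cancer / DNA-repair gene panel.
# The discovery study restricted missense and in-frame candidates to a
# supplementary list of 832 genes assembled from commercial cancer
# panels, consensus cancer genes, and DNA-repair pathways.  That exact
# list is not redistributed here; this reconstruction covers the
# well-established cancer and DNA-repair genes (including every gene
# the study's own result tables imply was on the panel) and is fully
# replaceable via configuration.  No analysis in this package depends
# on its exact contents or size.
ABL1
ABL2
AKT1
AKT2
AKT3
ALK
APC
APEX1
APEX2
AR
ARHGEF12
ARID1A
ARID1B
ARID2
ASXL1
ATM
ATR
ATRX
AURKA
AURKB
AXIN1
AXIN2
BAP1
BARD1
BCL2
BCL6
BLM
BMPR1A
BRAF
BRCA1
BRCA2
BRIP1
BUB1
BUB1B
CAPN9
CBL
CCND1
CCNE1
CDC73
CDH1
CDK4
CDK6
CDKN1B
CDKN2A
CDKN2B
CEBPA
CHEK1
CHEK2
CREBBP
CTNNB1
CYLD
DDB1
DDB2
DDX10
DICER1
DIS3L2
DNMT3A
EGFR
EP300
EPCAM
ERBB2
ERBB3
ERBB4
ERCC1
ERCC2
ERCC3
ERCC4
ERCC5
ERCC6
ERCC8
ESR1
EXO1
EXT1
EXT2
EZH2
FAM175A
FAN1
FANCA
FANCB
FANCC
FANCD2
FANCE
FANCF
FANCG
FANCI
FANCL
FANCM
FAT1
FBXW7
FGFR1
FGFR2
FGFR3
FGFR4
FH
FLCN
FLT3
GALNT3
GALNT12
GATA2
GATA3
GEN1
GPC3
GREM1
HNF1A
HOXB13
HRAS
IDH1
IDH2
IL33
JAK1
JAK2
JAK3
KDM5C
KDM6A
KDR
KEAP1
KIT
KL
KMT2A
KMT2C
KMT2D
KNL1
KRAS
LIG1
LIG3
LIG4
MAP2K1
MAP2K2
MAP3K1
MAX
MDM2
MDM4
MED12
MEN1
MET
MITF
MLH1
MLH3
MPL
MRE11
MSH2
MSH3
MSH6
MST1R
MTOR
MUTYH
MYC
MYCN
MYD88
NBN
NCKIPSD
NEIL1
NEIL2
NEIL3
NF1
NF2
NHEJ1
NIN
NOTCH1
NOTCH2
NOTCH3
NPM1
NRAS
NSD1
NTHL1
NTRK1
NTRK2
NTRK3
OGG1
PALB2
PARP1
PARP2
PAX5
PBRM1
PCM1
PDGFRA
PDGFRB
PHOX2B
PICALM
PIK3CA
PIK3R1
PMS1
PMS2
POLA1
POLB
POLD1
POLE
POLH
POLQ
POT1
PPM1D
PRDM16
PRKAR1A
PTCH1
PTEN
PTPN11
PTPRD
RAD17
RAD18
RAD21
RAD50
RAD51
RAD51B
RAD51C
RAD51D
RAD52
RAD54B
RAD54L
RAF1
RB1
RECQL
RECQL4
RECQL5
RET
REV1
REV3L
RHOA
RINT1
RNF43
ROS1
RPA1
RUNX1
SDHA
SDHAF2
SDHB
SDHC
SDHD
SETD2
SF3B1
SLC22A16
SLX4
SMAD3
SMAD4
SMARCA4
SMARCB1
SMARCE1
SMC1A
SMO
SPOP
SRC
STAG2
STK11
SUFU
TERT
TET2
TGFBR1
TGFBR2
TOP1
TP53
TP53BP1
TSC1
TSC2
TSHR
UIMC1
VHL
WDHD1
WRN
WT1
XPA
XPC
XRCC1
XRCC2
XRCC3
XRCC4
XRCC5
XRCC6
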