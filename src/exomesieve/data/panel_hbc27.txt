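# 27 well-established and emerging hereditary breast cancer
# predisposition genes screened before the novel-gene cascade.
ATM
BARD1
BLM
BRCA1
BRCA2
BRIP1
CDH1
CHEK2
FANCC
FANCM
MLH1
MSH2
MUTYH
NBN
NF1
PALB2
PMS2
PTEN
RAD51C
RAD51D
STK11
TP53
FAM175A
MRE11
RAD51B
RECQL
RINT1
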