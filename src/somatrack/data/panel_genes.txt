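# 48-gene amplicon cancer panel
ABL1
AKT1
ALK
APC
ATM
BRAF
CDH1
CDKN2A
CSF1R
CTNNB1
EGFR
ERBB2
ERBB4
FBXW7
FGFR1
FGFR2
FGFR3
FLT3
GNA11
GNAQ
GNAS
HNF1A
HRAS
IDH1
JAK2
JAK3
KDR
KIT
KRAS
MET
MLH1
MPL
NOTCH1
NPM1
NRAS
PDGFRA
PIK3CA
PTEN
PTPN11
RB1
RET
SMAD4
SMARCB1
SMO
SRC
STK11
TP53
VHL
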