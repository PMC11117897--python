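# ASD-associated gene panel used for genetic exclusion screening
# one HGNC symbol per line
ADNP
ALDH5A1
AMT
AP1S2
ARID1B
ARX
ATRX
BCKDK
BRAF
CACNA1C
CASK
CDKL5
CHD7
CHD8
CNTNAP2
CREBBP
CTNNB1
DHCR7
DYRK1A
EHMT1
FGD1
FMR1
FOLR1
FOXG1
FOXP1
FOXP2
GABRB3
SLC2A1
GRIN2B
HDAC8
HOXA1
HPRT1
KDM5C
KIRREL3
L1CAM
LAMC3
MBD5
MECP2
MED12
MEF2C
MID1
NHS
NIPBL
NLGN3
NLGN4X
NRXN1
NSD1
NTNG1
OPHN1
PAFAH1B1
PCDH19
PHF6
PNKP
PQBP1
PTCHD1
PTEN
PTPN11
RAB39B
RAD21
RAI1
RELN
SCN1A
SCN2A
SETBP1
SETD2
SHANK3
SLC9A6
SMC1A
SMC3
STXBP1
SYNE1
TBL1XR1
TBR1
TCF4
TMEM231
TMLHE
TSC1
TSC2
TUBA1A
UBE3A
UBE3C
VPS13B
ZEB2
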