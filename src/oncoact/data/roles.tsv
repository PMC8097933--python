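gene	role
EGFR	oncogene
ERBB2	oncogene
KDR	oncogene
IGF1R	oncogene
MET	oncogene
RET	oncogene
PIK3CA	oncogene
PIK3CB	oncogene
PIK3CG	oncogene
PIK3CD	oncogene
AKT1	oncogene
AKT2	oncogene
AKT3	oncogene
MTOR	oncogene
KRAS	oncogene
HRAS	oncogene
NRAS	oncogene
BRAF	oncogene
MAP2K1	oncogene
MAP2K2	oncogene
MAPK1	oncogene
CCND1	oncogene
CCNE1	oncogene
CDK4	oncogene
CDK6	oncogene
SMO	oncogene
STK36	oncogene
ARID1A	tumor_suppressor
ATM	tumor_suppressor
ATR	tumor_suppressor
BAP1	tumor_suppressor
BLM	tumor_suppressor
BRCA1	tumor_suppressor
BRCA2	tumor_suppressor
CHEK1	tumor_suppressor
CHEK2	tumor_suppressor
ERCC1	tumor_suppressor
MLH1	tumor_suppressor
MRE11A	tumor_suppressor
PALB2	tumor_suppressor
RAD50	tumor_suppressor
PTEN	tumor_suppressor
TSC1	tumor_suppressor
TSC2	tumor_suppressor
STK11	tumor_suppressor
NF1	tumor_suppressor
NF2	tumor_suppressor
FLCN	tumor_suppressor
FBXW7	tumor_suppressor
CDKN2A	tumor_suppressor
CDKN2B	tumor_suppressor
RB1	tumor_suppressor
PTCH1	tumor_suppressor
SUFU	tumor_suppressor
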