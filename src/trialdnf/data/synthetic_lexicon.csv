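term
KRAS G12C
BRAF V600E
EGFR exon 19 deletion
EGFR T790M
PIK3CA H1047R
IDH1 R132H
NRAS Q61K
AKT1 E17K
FGFR amplification
MET amplification
HER2 amplification
MYC amplification
CCND1 amplification
ALK fusion
ROS1 fusion
RET fusion
NTRK1 fusion
FGFR2 fusion
BRCA1 mutation
BRCA2 mutation
TP53 mutation
STK11 mutation
PTEN loss
CDKN2A deletion
ER+
PR+
HER2 +
PD-L1 positive
MSI-H
TMB-H
KRAS
BRAF
EGFR
ALK
HER2
FGFR
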