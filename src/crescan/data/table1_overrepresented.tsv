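# Published percent-of-genes columns for CREs listed at the over-represented
# tier (>=75% in the up- and/or down-regulated gene set). Blank = CRE absent
# from that set's listing. Variant sub-rows (MYB1-4/26, SEF1/3/4, SORLIP1/2/5)
# are collapsed into their CRE group, which carries one percent per set.
cre_id	percent_up	percent_down
ARR1_BINDING_SITE	100
DOF_BINDING_SITE	100
DRE_LIKE_MOTIF	100	96
E_BOX	100
GATA_BOX	100	94
GT1_BINDING_SITE	100
MYB_BINDING_SITE	100	92
SEF_BINDING_MOTIF	100
W_BOX	100	75
ROOTMOTIFTAPOX1	98
OSE1_2ROOTNODULE	97
CACTFTPPCA1	95
GTGA_MOTIF	95
I_BOX	95	75
POLLEN1_LELAT52	95
RAV1_BINDING_SITE	95	90
BIHD1	84
MYC_RECOGNITION_SITE	84	73
CCAAT_BOX_1	82
EEC_CONSENSUS_MOTIF	82
SORLIP	79	84
ACGT_BOX	75
LFY	70	75
T_BOX	69	75
ATB2_MOTIF	67	75
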