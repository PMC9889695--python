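# Published percent-of-genes columns for CREs listed at the moderately
# over-represented tier (50-74%). Blank = CRE absent from that set's listing
# (including cells the source marks as belonging to another tier).
cre_id	percent_up	percent_down
ABRE_LIKE_BINDING_SITE	74
RE_ALPHA	72
CURE	70
LFY_BINDING_SITE	70
PYRIMIDINE_BOX	69
GARE	67
SURE	67
PREAT	67
CARG_MOTIF	66
MARTBOX	64
ARF_ELEMENT	64	69
MINUS10_PEHVPSBD	59
AMYBOX1	57
L1_BOX	57	65
LTRE_PROMOTER_MOTIF	57
CPB_BINDING_MOTIF	56
BBF1_BINDING_MOTIF	56
TATCCAY_MOTIF	52
ASF1_BINDING_SITE	51
MYC_RECOGNITION_SITE		73
BOX_II_PROMOTER_MOTIF		71
CCA1_BINDING_SITE		57
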