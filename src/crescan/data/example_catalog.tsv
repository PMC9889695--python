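# Example CRE catalog (convenience fixture). Consensus sequences are widely
# cited forms for these CRE families from the plant cis-element literature;
# they are illustrative defaults, not authoritative database content.
cre_id	display_name	variants	tfs	tags
ARR1_BINDING_SITE	ARR1-binding site	NGATT	ARR1	growth,CK
DOF_BINDING_SITE	Dof-binding site	AAAG	Dof	light,growth,SA,GA
DRE_LIKE_MOTIF	DRE-like motif	RCCGAC	DPBF-1,DPBF-2	stress,ABA
E_BOX	E box	CANNTG	bHLH112	stress,ABA,JA,BR
GATA_BOX	GATA box	WGATAR	GATA factors	light,growth,CK,GA
GT1_BINDING_SITE	GT1-binding site	GRWAAW	GT-1	light,stress
MYB_BINDING_SITE	MYB-binding site	WAACCA,YAACKG	MYB1,MYB2,MYB3,MYB4,MYB26	stress,ABA,CK
SEF_BINDING_MOTIF	SEF-binding motif	RTTTTTR	SEF1,SEF3,SEF4	growth
W_BOX	W box	TTGACC,TTGACT	WRKY	stress,SA,JA,ABA,BR
I_BOX	I box	GATAAG	I-box binding factors	light
RAV1_BINDING_SITE	RAV1-binding site	CAACA	RAV1	stress,ABA,CK,BR
MYC_RECOGNITION_SITE	MYC-recognition site	CACATG	MYC2,ICE1	stress,JA,ABA
ACGT_BOX	ACGT box	ACGT	bZIP factors	stress,ABA,SA
CCAAT_BOX_1	CCAAT box 1	CCAAT		stress,growth
SORLIP	SORLIP motif	GCCAC	SORLIP1,SORLIP2,SORLIP5	light
L1_BOX	L1 box (HD-ZIP IV binding element)	TAAATGYA	GL2,ATML1,PDF2,HDG11,ATHB17	growth,stress,ABA
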