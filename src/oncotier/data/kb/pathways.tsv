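pathway	gene	role
PI3K_AKT_MTOR	EGFR	upstream
PI3K_AKT_MTOR	MET	upstream
PI3K_AKT_MTOR	PDGFRA	upstream
PI3K_AKT_MTOR	KIT	upstream
PI3K_AKT_MTOR	PIK3CA	downstream
PI3K_AKT_MTOR	PIK3R1	downstream
PI3K_AKT_MTOR	PTEN	downstream
PI3K_AKT_MTOR	TSC2	downstream
PI3K_AKT_MTOR	RPTOR	downstream
RTK_RAS_RAF	EGFR	upstream
RTK_RAS_RAF	MET	upstream
RTK_RAS_RAF	NF1	downstream
RTK_RAS_RAF	BRAF	downstream
CELL_CYCLE_CDK4_RB	CDKN2A	upstream
CELL_CYCLE_CDK4_RB	CDK4	downstream
CELL_CYCLE_CDK4_RB	RB1	downstream
P53_MDM2	TP53	upstream
P53_MDM2	MDM2	downstream
SMO_GLI	SMO	upstream
SMO_GLI	SUFU	downstream
SMO_GLI	GLI1	downstream
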