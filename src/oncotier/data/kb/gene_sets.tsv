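set_name	gene
actionable_genes	EGFR
actionable_genes	PTEN
actionable_genes	PIK3CA
actionable_genes	PIK3R1
actionable_genes	MET
actionable_genes	PDGFRA
actionable_genes	KIT
actionable_genes	KDR
actionable_genes	SMO
actionable_genes	NF1
actionable_genes	MGMT
actionable_genes	MDM2
actionable_genes	CDK4
actionable_genes	CDKN2A
actionable_genes	IDH1
actionable_genes	RPTOR
actionable_genes	TSC2
actionable_genes	TP53
actionable_genes	STAG2
actionable_genes	BRAF
actionable_genes	MYCN
actionable_genes	PALB2
actionable_genes	RB1
cancer_census	EGFR
cancer_census	PTEN
cancer_census	PIK3CA
cancer_census	PIK3R1
cancer_census	MET
cancer_census	PDGFRA
cancer_census	KIT
cancer_census	KDR
cancer_census	SMO
cancer_census	NF1
cancer_census	MGMT
cancer_census	MDM2
cancer_census	CDK4
cancer_census	CDKN2A
cancer_census	IDH1
cancer_census	RPTOR
cancer_census	TSC2
cancer_census	TP53
cancer_census	STAG2
cancer_census	BRAF
cancer_census	MYCN
cancer_census	PALB2
cancer_census	RB1
cancer_census	MSH2
cancer_census	MSH6
cancer_census	MLH1
cancer_census	PMS2
cancer_census	POLE
cancer_census	POLA1
cancer_census	TERT
cancer_census	ATRX
cancer_census	CIC
cancer_census	FUBP1
cancer_census	SMARCA4
cancer_census	SETD2
mmr_genes	MSH2
mmr_genes	MSH6
mmr_genes	MLH1
mmr_genes	PMS2
mmr_genes	POLE
promoter_genes	TERT
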