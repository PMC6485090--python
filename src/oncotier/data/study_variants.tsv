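sample	gene	variant_spec	finding_type
GBM1	PIK3R1	R562del	snv
GBM1	MET	R755fs	snv
GBM1	MET	exon 11 skipping	sv
GBM1	MET	focal gain	cnv_gain
GBM3	PIK3CA	V344G	snv
GBM4	EGFR	gain	cnv_gain
GBM4	PTEN	W111C	snv
GBM4	PTEN	whole arm loss	cnv_loss
GBM5	PDGFRA	gain	cnv_gain
GBM5	KIT	gain	cnv_gain
GBM5	KDR	gain	cnv_gain
GBM6	PIK3CA	G542K	snv
GBM6	PTEN	N59fs	snv
GBM6	EGFR	whole arm gain	cnv_gain
GBM7	SMO	R421*	snv
GBM7	NF1	Q270*	snv
GBM8	POLE	P1505S	snv
GBM8	MSH2	splice site donor c.366+1G>A	snv
GBM8	TMB_HIGH	High mutation burden	burden
GBM9	EGFR	gain	cnv_gain
GBM9	KDR	R1022*	snv
GBM9	PIK3R1	E443del	snv
GBM10	MGMT	loss	cnv_loss
GBM10	PTEN	R130*	snv
GBM10	PTEN	whole arm loss	cnv_loss
GBM10	NF1	E1722*	snv
GBM12	EGFR	A289V	snv
GBM12	EGFR	focal gain	cnv_gain
GBM12	PIK3R1	D560G	snv
GBM13	MDM2	focal gain	cnv_gain
GBM13	CDK4	focal gain	cnv_gain
GBM13	PTEN	R47S	snv
GBM14	EGFR	A289V	snv
GBM14	EGFR	focal gain	cnv_gain
GBM14	PIK3R1	W597G	snv
GBM14	PTEN	whole arm loss	cnv_loss
GBM14	PTEN	focal deletion	cnv_loss
GBM15	PIK3R1	T473P	snv
GBM15	EGFR	whole arm gain	cnv_gain
GBM15	CDKN2A	homozygous focal deletion	cnv_loss
GBM15	PTEN	whole arm loss	cnv_loss
GBM16	PTEN	Y16*	snv
GBM16	EGFR	focal gain	cnv_gain
GBM16	PDGFRA	focal gain	cnv_gain
GBM17	BRAF	V600E	snv
GBM17	EGFR	gain	cnv_gain
GBM21	EGFR	R222C	snv
GBM21	EGFR	focal gain	cnv_gain
GBM21	MET	P791L	snv
GBM21	MET	focal gain	cnv_gain
GBM21	PTEN	whole arm loss	cnv_loss
GBM21	CDKN2A	homozygous focal deletion	cnv_loss
GBM22	PTEN	V119F	snv
GBM22	PTEN	whole arm loss	cnv_loss
GBM22	STAG2	focal deletion	cnv_loss
GBM22	NF1	1283fs	snv
GBM22	NF1	focal loss	cnv_loss
GBM22	TP53	R158H	snv
GBM23	IDH1	R132H	snv
GBM23	RPTOR	A578G	snv
GBM24	PIK3CA	R93W	snv
GBM24	EGFR	whole arm amplification	cnv_gain
GBM24	MET	focal gain	cnv_gain
GBM24	PTEN	R335*	snv
GBM24	PTEN	T277I	snv
GBM24	PTEN	whole arm loss	cnv_loss
GBM24	CDKN2A	homozygous focal deletion	cnv_loss
GBM24	PALB2	whole arm loss	cnv_loss
GBM25	POLA1	G1178	snv
GBM25	MSH2	splice site donor c.366+1G>A	snv
GBM25	TP53	R175H	snv
GBM25	TP53	G245S	snv
GBM25	PDGFRA	Y375H	snv
GBM25	PDGFRA	focal gain	cnv_gain
GBM25	KIT	focal gain	cnv_gain
GBM25	KDR	focal gain	cnv_gain
GBM25	TMB_HIGH	High mutation burden	burden
GBM26	PIK3CA	R88Q	snv
GBM26	MDM2	focal gain	cnv_gain
GBM26	CDK4	focal gain	cnv_gain
GBM26	PTEN	whole arm loss	cnv_loss
GBM27	EGFR	vIII	sv
GBM27	EGFR	focal gain	cnv_gain
GBM27	CDKN2A	homozygous focal deletion	cnv_loss
GBM27	PTEN	whole arm loss	cnv_loss
GBM28	PIK3R1	Q579fs	snv
GBM28	PIK3CA	D939G	snv
GBM28	MET	focal gain	cnv_gain
GBM28	PDGFRA	focal gain	cnv_gain
GBM28	CDKN2A	homozygous focal deletion	cnv_loss
GBM28	PTEN	whole arm loss	cnv_loss
GBM29	EGFR	A289V	snv
GBM29	EGFR	focal gain	cnv_gain
GBM29	PTEN	R130*	snv
GBM29	PTEN	whole arm loss	cnv_loss
GBM29	CDKN2A	homozygous focal deletion	cnv_loss
GBM29	CDK4	focal gain	cnv_gain
GBM31	IDH1	R132H	snv
GBM31	TSC2	P1215fs	snv
GBM31	TP53	R175H	snv
GBM31	CDKN2A	homozygous focal deletion	cnv_loss
GBM32	PIK3R1	A483P	snv
GBM32	STAG2	focal deletion	cnv_loss
GBM32	PTEN	M198R	snv
GBM32	PTEN	whole arm loss	cnv_loss
GBM33	PTEN	Q97*	snv
GBM33	PTEN	whole arm loss	cnv_loss
GBM33	CDKN2A	focal loss	cnv_loss
GBM34	EGFR	gain	cnv_gain
GBM34	PTEN	whole arm loss	cnv_loss
GBM34	TP53	C242S	snv
GBM34	TP53	V143M	snv
GBM34	MYCN	gain	cnv_gain
GBM35	EGFR	focal gain	cnv_gain
GBM35	PIK3R1	L372dup	snv
GBM35	CDKN2A	homozygous loss	cnv_loss
GBM35	PTEN	whole arm loss	cnv_loss
GBM35	KIT	A207V	snv
GBM36	NF1	c.1062+1 splice site donor	snv
GBM36	TP53	T211I	snv
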