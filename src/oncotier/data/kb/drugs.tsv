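gene	variant_scope	variant_spec	drug	evidence_level	trial_ids	disease
EGFR	gain		Cetuximab	approved_other_disease	NCT01238237;NCT02573324	colorectal cancer
EGFR	gain		ABT-414	clinical_trial	NCT02573324;NCT02423525	glioblastoma
EGFR	gain		Afatanib	clinical_trial	NCT02423525	glioblastoma
EGFR	gain		ABBV-221	clinical_trial	NCT02365662	glioblastoma
EGFR	gain		Erlotinib	approved_other_disease		lung adenocarcinoma
EGFR	specific_variant	vIII	Rindopepimut	clinical_trial	NCT01480479	glioblastoma
EGFR	specific_variant	vIII	CAR-T	clinical_trial	NCT02664363	glioblastoma
EGFR	specific_variant	vIII	Afatanib	clinical_trial	NCT02423525	glioblastoma
PIK3CA	any_alteration		BKM120	clinical_trial	NCT01870726;NCT01349660	glioblastoma
PIK3R1	any_alteration		BKM120	clinical_trial	NCT01870726;NCT01349660	glioblastoma
MET	gain		INC280	clinical_trial	NCT02386826	glioblastoma
MET	gain		Crizotinib	clinical_trial	NCT02034981;NCT02540161	glioblastoma
MET	any_alteration		INC280	clinical_trial	NCT02386826	glioblastoma
PTEN	loss		Everolimus	clinical_trial	NCT01870726;NCT01390571	glioblastoma
PTEN	loss		Temsirolimus	clinical_trial	NCT02152982	glioblastoma
PTEN	any_alteration		Everolimus	clinical_trial	NCT01870726	glioblastoma
PDGFRA	gain		Nilotinib	clinical_trial	NCT01140568;NCT01871311	glioblastoma
PDGFRA	gain		Crenolanib	clinical_trial	NCT02626364	glioblastoma
PDGFRA	any_alteration		Nilotinib	clinical_trial	NCT01140568	glioblastoma
KIT	gain		Nilotinib	clinical_trial	NCT01140568	glioblastoma
KIT	any_alteration		Imatinib	approved_other_disease		gastrointestinal stromal tumor
KDR	gain		Nilotinib	clinical_trial	NCT01140568	glioblastoma
KDR	any_alteration		Bevacizumab	approved_in_disease		glioblastoma
SMO	any_alteration		Vismodegib	clinical_trial	NCT00980343	glioblastoma
NF1	any_alteration		MEK162	clinical_trial	NCT01885195	glioblastoma
MGMT	loss		Temozolomide	approved_in_disease		glioblastoma
MDM2	gain		RG7112	clinical_trial	NCT01877382	glioblastoma
MDM2	gain		RG7388	clinical_trial	NCT02143635	glioblastoma
MDM2	gain		AMG232	clinical_trial	NCT01723020	glioblastoma
CDK4	gain		Palbociclib	clinical_trial	NCT01227434	glioblastoma
CDK4	gain		Ribociclib	clinical_trial	NCT02345824	glioblastoma
CDKN2A	loss		Palbociclib	clinical_trial	NCT01390571	glioblastoma
CDKN2A	loss		Ribociclib	clinical_trial	NCT02152982	glioblastoma
IDH1	specific_variant	R132H	AG-120	clinical_trial	NCT02073994	glioblastoma
IDH1	specific_variant	R132H	AG-881	clinical_trial	NCT02481154	glioblastoma
IDH1	specific_variant	R132H	BAY-1436032	clinical_trial	NCT02746081	glioblastoma
RPTOR	any_alteration		Everolimus	clinical_trial	NCT01434602	glioblastoma
RPTOR	any_alteration		INK128	clinical_trial	NCT02142803	glioblastoma
TSC2	any_alteration		Everolimus	clinical_trial	NCT02142803	glioblastoma
TSC2	any_alteration		MLN0128	clinical_trial	NCT02142803	glioblastoma
TP53	any_alteration		Temsirolimus	clinical_trial	NCT00703625	glioblastoma
TP53	any_alteration		Docetaxel	clinical_trial	NCT00703625	glioblastoma
TP53	any_alteration		Paclitaxel	clinical_trial	NCT02379416	glioblastoma
STAG2	loss		Olaparib	clinical_trial	NCT01390571	glioblastoma
STAG2	loss		Veliparib	clinical_trial	NCT02152892	glioblastoma
PALB2	loss		Olaparib	clinical_trial	NCT01390571	glioblastoma
PALB2	loss		Veliparib	clinical_trial	NCT02152892	glioblastoma
BRAF	specific_variant	V600E	Vemurafanib	approved_other_disease	NCT02537600	melanoma
BRAF	specific_variant	V600E	Cobimetinib	approved_other_disease	NCT02537600	melanoma
BRAF	specific_variant	V600E	Dabrafenib	approved_other_disease		melanoma
BRAF	specific_variant	V600E	Trametinib	approved_other_disease		melanoma
MYCN	gain		CP-0610	clinical_trial	NCT02698176	glioblastoma
MYCN	gain		MK-8628	clinical_trial	NCT02630251	glioblastoma
MYCN	gain		GSK2820151	clinical_trial	NCT01877382	glioblastoma
TMB_HIGH	any_alteration		Pembrolizumab	clinical_trial	NCT02337686	glioblastoma
TMB_HIGH	any_alteration		Nivolumab	clinical_trial	NCT02017717	glioblastoma
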