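gene	variant_spec	disease	significance	source_id
IDH1	R132H	glioblastoma	clinically_significant	civic:IDH1-R132H-gbm
BRAF	V600E	glioblastoma	clinically_significant	civic:BRAF-V600E-gbm
BRAF	V600E	melanoma	clinically_significant	civic:BRAF-V600E-mel
TP53	R175H	breast cancer	clinically_significant	civic:TP53-R175H
TP53	R273C	breast cancer	clinically_significant	civic:TP53-R273C
PIK3CA	E542K	breast cancer	clinically_significant	civic:PIK3CA-E542K
EGFR	amplification	glioblastoma	clinically_significant	civic:EGFR-amp-gbm
EGFR	L858R	lung adenocarcinoma	clinically_significant	civic:EGFR-L858R
KRAS	G12D	colorectal cancer	resistance	civic:KRAS-G12D
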