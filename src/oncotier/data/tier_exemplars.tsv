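gene	variant_spec
IDH1	R132H
IDH1	R132H
BRAF	V600E
TP53	R175H
TP53	R273C
PIK3CA	E542K
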