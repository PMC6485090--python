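alias	canonical
ABT41	ABT-414
Afatnib	Afatanib
Afatinib	Afatanib
Vemurafenib	Vemurafanib
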