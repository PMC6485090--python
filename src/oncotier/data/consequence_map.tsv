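snpeff_term	consequence
missense_variant	missense
stop_gained	nonsense
stop_lost	nonsense
start_lost	nonsense
frameshift_variant	frameshift
inframe_insertion	inframe_indel
inframe_deletion	inframe_indel
disruptive_inframe_insertion	inframe_indel
disruptive_inframe_deletion	inframe_indel
splice_donor_variant	splice_site
splice_acceptor_variant	splice_site
splice_region_variant	splice_site
synonymous_variant	synonymous
stop_retained_variant	synonymous
upstream_gene_variant	promoter
5_prime_UTR_premature_start_codon_gain_variant	other
intron_variant	other
intergenic_region	other
3_prime_UTR_variant	other
5_prime_UTR_variant	other
downstream_gene_variant	other
non_coding_transcript_exon_variant	other
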