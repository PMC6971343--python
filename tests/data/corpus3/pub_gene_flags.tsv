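pub_id	gene_id	mutagen_or_nature_of_lesion	classical_allele_with_pheno	exp_go_bp_mf	expression_or_antibody	gene_source
pub1	g1	1	1	1	0	0
pub1	g2	0	0	0	0	0
pub2	g1	0	1	0	1	0
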