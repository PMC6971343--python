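gene_id	allele_id	is_classical	has_phenotype	source_pub
g1	wg[1]	1	1	pub1
g2	CG4711[KO]	0	0	pub1
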