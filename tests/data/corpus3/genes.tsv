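gene_id	symbol	name	is_named	is_protein_coding	page_views	n_publications	has_human_ortholog	ortholog_in_omim	has_nonarthropod_metazoan_ortholog	gene_group_summary	interactive_fly_summary
g1	wg	wingless	1	1	120	2	1	1	0	Wnt family ligand group.	Segment polarity signal.
g2	CG4711	CG4711	0	1	3	1	0	0	0		
g3	arm	armadillo	1	1	80	0	1	0	0		
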