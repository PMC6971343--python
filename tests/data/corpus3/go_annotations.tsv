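gene_id	term_id	aspect	is_root	evidence_class
g1	GO:0016055	BP	0	experimental
g1	GO:0008150	BP	1	non_experimental
g2	GO:0005737	CC	0	non_experimental
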