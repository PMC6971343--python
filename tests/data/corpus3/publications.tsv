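pub_id	year	n_linked_genes	author_ids
pub1	2014	2	a1;a2
pub2	2009	1	a2;a3
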