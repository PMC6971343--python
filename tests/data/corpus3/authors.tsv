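author_id	surname	known_email	excluded	exclusion_reason
a1	Smith		0	
a2	Jones	jones@uni.example.edu	0	
a3	Brown		1	retired
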