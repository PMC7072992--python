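gene	forward_primer	reverse_primer	role
RPL5b	CCTGGTGCCTTCACGTGTTA	GTAGCCGGGGAAACGTTTC	target
RPL24	CCGATACGCCAGGATAGACG	CCTTCTTGTGCTTGCGTCTG	target
eef1a1a	.	.	reference
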