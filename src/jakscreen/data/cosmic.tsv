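chrom	pos	ref	alt	cosmic_id
JAK2FRAG	450	A	G	COSM0001
JAK2FRAG	452	A	T	COSM0002
JAK2FRAG	761	G	A	COSM0003
JAK2FRAG	801	G	T	COSM0004
JAK2FRAG	1681	G	A	COSM0005
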