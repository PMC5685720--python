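chrom	pos	ref	alt	af_1000g_all	af_1000g_eur	af_esp_eur
JAK2FRAG	1101	C	T	0.12	0.1	0.08
JAK2FRAG	1106	A	G	0.3	0.28	0.22
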