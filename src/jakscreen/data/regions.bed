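JAK2FRAG	200	500	exon16
JAK2FRAG	700	850	exon20
JAK2FRAG	1000	1240	exon21
JAK2FRAG	1400	1700	exon23
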