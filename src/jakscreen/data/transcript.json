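{
  "gene": "JAK2L",
  "chrom": "JAK2FRAG",
  "strand": "+",
  "first_residue": 600,
  "exons": [
    {
      "start": 200,
      "end": 500,
      "label": "exon16"
    },
    {
      "start": 700,
      "end": 850,
      "label": "exon20"
    },
    {
      "start": 1000,
      "end": 1240,
      "label": "exon21"
    },
    {
      "start": 1400,
      "end": 1700,
      "label": "exon23"
    }
  ]
}
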