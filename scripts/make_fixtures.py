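"""Dev-time generator for the packaged reference + fixture tables (run from repo root)."""
import json
import numpy as np

rng = np.random.default_rng(20260905)
L = 2000
bases = np.array(list("ACGT"))
seq = list(rng.choice(bases, size=L))

EXONS = [(200, 500, "exon16"), (700, 850, "exon20"), (1000, 1240, "exon21"), (1400, 1700, "exon23")]
FIRST_RESIDUE = 600

# fill CDS with random non-stop codons
STOPS = {"TAA", "TAG", "TGA"}
codons = [a+b+c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a+b+c not in STOPS]
cds_positions = []
for s, e, _ in EXONS:
    cds_positions.extend(range(s, e))
assert len(cds_positions) % 3 == 0
for i in range(0, len(cds_positions), 3):
    cod = codons[rng.integers(len(codons))]
    for j in range(3):
        seq[cds_positions[i + j]] = cod[j]

def set_codon(residue, codon):
    idx = residue - FIRST_RESIDUE
    for j in range(3):
        seq[cds_positions[idx * 3 + j]] = codon[j]

set_codon(683, "AGA")  # R; A>G at first pos -> G (missense), A>T at third -> S
set_codon(720, "GAA")  # E; G>A at first pos -> K
set_codon(733, "CGG")  # R; G>T at middle  -> L (artifact plant)
set_codon(783, "ACT")  # T; C>T at middle  -> I (germline SNP plant)
set_codon(923, "CGT")  # R; G>A at middle  -> H

# repeat tract for indel-normalization tests (non-exonic)
for j, b in enumerate("TTACACACG"):
    seq[100 + j] = b

seq = "".join(seq)
with open("src/jakscreen/data/reference.fa", "w") as fh:
    fh.write(">JAK2FRAG synthetic hotspot fragment\n")
    for i in range(0, L, 60):
        fh.write(seq[i:i+60] + "\n")

with open("src/jakscreen/data/transcript.json", "w") as fh:
    json.dump({
        "gene": "JAK2L",
        "chrom": "JAK2FRAG",
        "strand": "+",
        "first_residue": FIRST_RESIDUE,
        "exons": [{"start": s, "end": e, "label": l} for s, e, l in EXONS],
    }, fh, indent=2)
    fh.write("\n")

with open("src/jakscreen/data/regions.bed", "w") as fh:
    for s, e, l in EXONS:
        fh.write(f"JAK2FRAG\t{s}\t{e}\t{l}\n")

# 1-based hotspot positions derived above
rows = [
    ("JAK2FRAG", 450, "A", "G", "COSM0001"),   # R683G-like
    ("JAK2FRAG", 452, "A", "T", "COSM0002"),   # R683S-like
    ("JAK2FRAG", 761, "G", "A", "COSM0003"),   # E720K-like
    ("JAK2FRAG", 801, "G", "T", "COSM0004"),   # R733L-like (run-artifact plant)
    ("JAK2FRAG", 1681, "G", "A", "COSM0005"),  # R923H-like
]
for chrom, pos, ref, alt, _ in rows:
    assert seq[pos-1] == ref, (pos, seq[pos-1], ref)
with open("src/jakscreen/data/cosmic.tsv", "w") as fh:
    fh.write("chrom\tpos\tref\talt\tcosmic_id\n")
    for r in rows:
        fh.write("\t".join(map(str, r)) + "\n")

pf = [
    ("JAK2FRAG", 1101, "C", "T", 0.12, 0.10, 0.08),        # T783I-like common SNP
    ("JAK2FRAG", 1106, seq[1105], "A" if seq[1105] != "A" else "G", 0.30, 0.28, 0.22),
]
with open("src/jakscreen/data/popfreq.tsv", "w") as fh:
    fh.write("chrom\tpos\tref\talt\taf_1000g_all\taf_1000g_eur\taf_esp_eur\n")
    for r in pf:
        fh.write("\t".join(map(str, r)) + "\n")

print("codon683:", seq[449:452], "codon720:", seq[760:763], "codon733:", seq[799:802],
      "codon783:", seq[1099:1102], "codon923:", seq[1679:1682], "snp2 ref:", seq[1105])
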