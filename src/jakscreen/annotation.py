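"""Coding-effect annotation and whitelist / population-frequency lookups.

The package ships a small synthetic reference fragment plus a hand-built
transcript model covering four hotspot exons; effects are classified by
translating the affected codons on the strand-corrected coding sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd
from Bio.Seq import Seq

from .errors import AnnotationError, ConfigurationError
from .variant_io import VariantKey, load_reference, normalize_variant

EFFECTS = ("missense", "nonsense", "synonymous", "frameshift", "inframe_indel", "noncoding")

#: effects counted as "amino-acid changing" by the filter cascade
AA_CHANGING = frozenset({"missense", "nonsense", "frameshift", "inframe_indel"})


@dataclass
class TranscriptModel:
    """Minimal transcript: ordered coding exons with a continuous frame.

    ``first_residue`` maps the first codon of the concatenated CDS to a
    protein residue number, so fixture variants can mimic well-known
    hotspot residues.  Exons are stored as 0-based half-open genomic
    intervals in genomic order; on the minus strand the CDS runs through
    them in reverse with complemented bases.
    """

    gene: str
    chrom: str
    strand: str
    first_residue: int
    exons: list[tuple[int, int, str]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConfigurationError(f"strand must be '+' or '-', got {self.strand!r}")
        if sum(e - s for s, e, _ in self.exons) % 3 != 0:
            raise ConfigurationError("transcript exon lengths do not form whole codons")

    def cds_positions(self) -> list[int]:
        """Genomic 0-based positions in CDS (5'→3' of the coding strand) order."""
        pos: list[int] = []
        for start, end, _ in self.exons:
            pos.extend(range(start, end))
        if self.strand == "-":
            pos.reverse()
        return pos

    def cds_sequence(self, reference: Mapping[str, str]) -> str:
        seq = reference[self.chrom]
        bases = [seq[p] for p in self.cds_positions()]
        if self.strand == "-":
            bases = [str(Seq(b).complement()) for b in bases]
        return "".join(bases)

    def cds_index(self, pos0: int) -> int | None:
        """CDS offset of a genomic 0-based position, or None if intronic."""
        running = 0
        total = sum(e - s for s, e, _ in self.exons)
        for start, end, _ in self.exons:
            if start <= pos0 < end:
                idx = running + (pos0 - start)
                return total - 1 - idx if self.strand == "-" else idx
            running += end - start
        return None

    def residue_number(self, cds_index: int) -> int:
        return self.first_residue + cds_index // 3


def load_transcript(path) -> TranscriptModel:
    with open(path) as fh:
        obj = json.load(fh)
    return TranscriptModel(
        gene=obj["gene"],
        chrom=obj["chrom"],
        strand=obj["strand"],
        first_residue=int(obj["first_residue"]),
        exons=[(int(e["start"]), int(e["end"]), e["label"]) for e in obj["exons"]],
    )


def _codon_at(cds: str, codon_idx: int) -> str:
    return cds[codon_idx * 3 : codon_idx * 3 + 3]


def annotate_effect(
    key: VariantKey,
    model: TranscriptModel,
    reference: Mapping[str, str],
) -> str:
    """Classify a variant's coding effect against the transcript model.

    Returns one of :data:`EFFECTS`.  Substitutions are translated codon
    by codon; length-changing variants inside an exon are ``frameshift``
    when the length difference is not a multiple of 3, else
    ``inframe_indel``.  Variants not touching any exon are ``noncoding``.
    """
    if key.chrom not in reference:
        raise AnnotationError(f"chromosome {key.chrom!r} not in packaged reference")
    seq = reference[key.chrom]
    if key.pos - 1 + len(key.ref) > len(seq):
        raise AnnotationError(f"variant {key} outside packaged reference")
    if key.chrom != model.chrom:
        return "noncoding"

    start0 = key.pos - 1
    if key.is_indel:
        # changed interval: for ins/del the bases after the shared anchor
        changed = range(start0 + 1, start0 + max(len(key.ref), 1))
        anchor_in = model.cds_index(start0) is not None
        touched = anchor_in or any(model.cds_index(p) is not None for p in changed)
        if len(key.ref) == 1 and len(key.alt) > 1:  # insertion: between anchor and next
            touched = anchor_in or model.cds_index(start0 + 1) is not None
        if not touched:
            return "noncoding"
        return "frameshift" if (len(key.alt) - len(key.ref)) % 3 != 0 else "inframe_indel"

    # same-length substitution (SNV or MNV): substitute in CDS and translate
    cds = model.cds_sequence(reference)
    cds_alt = list(cds)
    any_coding = False
    for offset in range(len(key.ref)):
        idx = model.cds_index(start0 + offset)
        if idx is None:
            continue
        any_coding = True
        base = key.alt[offset]
        if model.strand == "-":
            base = str(Seq(base).complement())
        cds_alt[idx] = base
    if not any_coding:
        return "noncoding"
    codon_idxs = sorted(
        {
            model.cds_index(start0 + o) // 3
            for o in range(len(key.ref))
            if model.cds_index(start0 + o) is not None
        }
    )
    cds_alt = "".join(cds_alt)
    effect = "synonymous"
    for ci in codon_idxs:
        aa_ref = str(Seq(_codon_at(cds, ci)).translate())
        aa_alt = str(Seq(_codon_at(cds_alt, ci)).translate())
        if aa_alt == aa_ref:
            continue
        if aa_alt == "*":
            return "nonsense"
        effect = "missense"
    return effect


# ---------------------------------------------------------------------------
# Whitelist and population-frequency fixtures


def load_cosmic(path, reference: Mapping[str, str]) -> dict[VariantKey, str]:
    """Load a COSMIC-like whitelist TSV (chrom pos ref alt cosmic_id)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    table: dict[VariantKey, str] = {}
    for row in df.itertuples():
        key = normalize_variant(row.chrom, int(row.pos), row.ref, row.alt, reference)
        table[key] = str(row.cosmic_id)
    return table


def lookup_cosmic(key: VariantKey, cosmic_table: Mapping[VariantKey, str]) -> bool:
    return key in cosmic_table


def load_popfreq(
    path, reference: Mapping[str, str]
) -> dict[VariantKey, tuple[float, float, float]]:
    """Load population allele frequencies (three databases) keyed by variant."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    table: dict[VariantKey, tuple[float, float, float]] = {}
    for row in df.itertuples():
        key = normalize_variant(row.chrom, int(row.pos), row.ref, row.alt, reference)
        afs = (float(row.af_1000g_all), float(row.af_1000g_eur), float(row.af_esp_eur))
        for af in afs:
            if not 0.0 <= af <= 1.0:
                raise ConfigurationError(f"allele frequency {af} outside [0,1] for {key}")
        table[key] = afs
    return table


def lookup_population_frequency(
    key: VariantKey,
    freq_table: Mapping[VariantKey, tuple[float, float, float]],
) -> tuple[float, float, float]:
    """Frequencies for a key; absence is the value (0, 0, 0), not an error."""
    return freq_table.get(key, (0.0, 0.0, 0.0))


# ---------------------------------------------------------------------------
# Packaged fixture access


def _data_path(name: str):
    return resources.files("jakscreen").joinpath("data", name)


def packaged_reference() -> dict[str, str]:
    return load_reference(str(_data_path("reference.fa")))


def packaged_transcript() -> TranscriptModel:
    return load_transcript(str(_data_path("transcript.json")))


def packaged_cosmic(reference: Mapping[str, str] | None = None) -> dict[VariantKey, str]:
    return load_cosmic(str(_data_path("cosmic.tsv")), reference or packaged_reference())


def packaged_popfreq(
    reference: Mapping[str, str] | None = None,
) -> dict[VariantKey, tuple[float, float, float]]:
    return load_popfreq(str(_data_path("popfreq.tsv")), reference or packaged_reference())


def packaged_regions_path() -> str:
    return str(_data_path("regions.bed"))
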