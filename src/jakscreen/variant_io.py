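"""Caller VCF ingestion, variant normalization, and per-sample merging.

Four caller dialects (labelled ``A``-``D``) convey read depth and
alt-supporting reads through different VCF fields:

========  =================================  =================================
caller    depth                              alt reads
========  =================================  =================================
A         FORMAT ``DP``                      FORMAT ``AD`` (ref,alt1,... list)
B         FORMAT ``DP``                      FORMAT ``AD`` (alt only), ref in
                                             FORMAT ``RD``
C         INFO ``DP4`` (sum of all four)     INFO ``DP4`` (fwd+rev alt fields)
D         FORMAT ``AD`` (ref,alt,... list;   FORMAT ``AD``
          depth from FORMAT ``DP`` when
          present, else sum of ``AD``)
========  =================================  =================================

All variants are normalized to a canonical :class:`VariantKey` (shared
suffix trimmed, shared prefix trimmed to the mandatory anchor base,
indels left-shifted) so the same event reported differently by two
callers merges into one record.  Leading ``chr`` prefixes are stripped
from chromosome names on ingestion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

from .errors import BedFormatError, ConfigurationError, IntegrityError, VcfFormatError

CALLERS = ("A", "B", "C", "D")


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True, order=True)
class VariantKey:
    """Canonical identity of a variant: chrom, 1-based pos, ref, alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", _norm_chrom(self.chrom))
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if not self.ref or not self.alt:
            raise IntegrityError(f"empty allele in variant {self}")
        if self.ref == self.alt:
            raise IntegrityError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise IntegrityError(f"position must be 1-based positive, got {self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class CallerCall:
    """One caller's report of one variant in one sample."""

    key: VariantKey
    caller: str
    depth: int
    alt_reads: int
    raw_pos: int
    missing_counts: bool = False

    def __post_init__(self) -> None:
        if self.caller not in CALLERS:
            raise ConfigurationError(f"unknown caller dialect {self.caller!r}")
        if not (0 <= self.alt_reads <= self.depth):
            raise IntegrityError(
                f"alt_reads {self.alt_reads} outside [0, depth={self.depth}] at {self.key}"
            )


@dataclass
class MergedVariant:
    """Per-sample consensus record aggregating evidence across callers.

    ``agg_depth``/``agg_alt`` are medians across the reporting callers
    (even count: mean of the middle two, rounded half up).
    """

    key: VariantKey
    sample_id: str
    evidence: dict[str, tuple[int, int]]

    @property
    def n_callers(self) -> int:
        return len(self.evidence)

    @property
    def agg_depth(self) -> int:
        return _median_int([d for d, _ in self.evidence.values()])

    @property
    def agg_alt(self) -> int:
        return _median_int([a for _, a in self.evidence.values()])

    @property
    def vaf(self) -> float:
        d = self.agg_depth
        return self.agg_alt / d if d > 0 else 0.0


def _median_int(values: Sequence[int]) -> int:
    """Median with the even-count mean rounded half up to an integer."""
    vs = sorted(values)
    n = len(vs)
    if n == 0:
        raise IntegrityError("median of empty evidence")
    if n % 2 == 1:
        return int(vs[n // 2])
    mid = (vs[n // 2 - 1] + vs[n // 2]) / 2.0
    return int(math.floor(mid + 0.5))


# ---------------------------------------------------------------------------
# Reference FASTA


def load_reference(fasta_path) -> dict[str, str]:
    """Load a (small) FASTA into a chrom -> uppercase sequence dict."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[_norm_chrom(rec.id)] = str(rec.seq).upper()
    return seqs


# ---------------------------------------------------------------------------
# Normalization


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Mapping[str, str],
) -> VariantKey:
    """Canonicalize a variant: trim shared suffix/prefix, left-align indels.

    ``pos`` is 1-based.  Raises :class:`IntegrityError` when ``ref``
    disagrees with the reference sequence at ``pos``.
    """
    chrom = _norm_chrom(chrom)
    ref = ref.upper()
    alt = alt.upper()
    if chrom not in reference:
        raise IntegrityError(f"chromosome {chrom!r} absent from reference")
    seq = reference[chrom]
    if seq[pos - 1 : pos - 1 + len(ref)] != ref:
        raise IntegrityError(
            f"REF {ref!r} does not match reference at {chrom}:{pos} "
            f"({seq[pos - 1 : pos - 1 + len(ref)]!r})"
        )
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    raise IntegrityError(
                        f"cannot left-extend variant at {chrom}:1 during normalization"
                    )
                pos -= 1
                base = seq[pos - 1]
                ref, alt = base + ref, base + alt
            continue
        if len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
            continue
        break
    return VariantKey(chrom, pos, ref, alt)


def normalize_key(key: VariantKey, reference: Mapping[str, str]) -> VariantKey:
    return normalize_variant(key.chrom, key.pos, key.ref, key.alt, reference)


# ---------------------------------------------------------------------------
# Targeted regions (BED)


@dataclass
class TargetRegions:
    """Targeted intervals as (chrom, 0-based start, exclusive end, label)."""

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = _merge_intervals(self.intervals)

    def label_at(self, key: VariantKey) -> str | None:
        """Label of the region containing the variant's anchor position."""
        p0 = key.pos - 1  # 0-based anchor
        for chrom, start, end, label in self.intervals:
            if chrom == key.chrom and start <= p0 < end:
                return label
        return None

    def __contains__(self, key: VariantKey) -> bool:
        return self.label_at(key) is not None

    def __iter__(self):
        return iter(self.intervals)


def _merge_intervals(
    intervals: Iterable[tuple[str, int, int, str]],
) -> list[tuple[str, int, int, str]]:
    out: list[tuple[str, int, int, str]] = []
    for chrom, start, end, label in sorted(intervals):
        if start >= end:
            raise BedFormatError(f"interval start {start} >= end {end} on {chrom}")
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            pc, ps, pe, pl = out.pop()
            out.append((pc, ps, max(pe, end), pl if pl == label else f"{pl}+{label}"))
        else:
            out.append((_norm_chrom(chrom), start, end, label))
    return out


def read_regions(bed_path) -> TargetRegions:
    """Read a 0-based half-open BED (3 or 4 columns) into TargetRegions."""
    df = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "label"],
        dtype={"chrom": str, "label": str},
    )
    if df[["chrom", "start", "end"]].isna().any().any():
        raise BedFormatError(f"malformed BED at {bed_path}")
    intervals = [
        (row.chrom, int(row.start), int(row.end), row.label if isinstance(row.label, str) else f"region{i}")
        for i, row in enumerate(df.itertuples())
    ]
    return TargetRegions(intervals)


def in_region(key: VariantKey, regions: TargetRegions) -> bool:
    """Membership of the variant's anchor base in the targeted regions.

    Intervals are 0-based half-open; the 1-based position ``pos`` is
    inside ``[start, end)`` iff ``start < pos <= end``.
    """
    return key in regions


# ---------------------------------------------------------------------------
# VCF reading


def _dialect_counts(rec, alt_index: int, caller: str) -> tuple[int, int, bool]:
    """Return (depth, alt_reads, missing) for one alt of one record."""
    try:
        if caller == "C":
            dp4 = rec.info.get("DP4")
            if dp4 is None:
                return 0, 0, True
            dp4 = [int(x) for x in dp4]
            return sum(dp4), dp4[2] + dp4[3], False
        sample = rec.samples[0]
        ad = sample.get("AD")
        if caller == "B":
            rd = sample.get("RD")
            dp = sample.get("DP")
            if ad is None or rd is None:
                return 0, 0, True
            alt_reads = int(ad[alt_index] if isinstance(ad, (tuple, list)) else ad)
            depth = int(dp) if dp is not None else int(rd) + alt_reads
            return depth, alt_reads, False
        # A and D: AD is (ref, alt1, alt2, ...)
        if ad is None:
            return 0, 0, True
        ad = [int(x) for x in ad]
        alt_reads = ad[alt_index + 1]
        dp = sample.get("DP")
        depth = int(dp) if dp is not None else sum(ad)
        return depth, alt_reads, False
    except (KeyError, IndexError, TypeError, ValueError):
        return 0, 0, True


def read_caller_vcf(
    path,
    caller: str,
    reference: Mapping[str, str] | None = None,
) -> list[CallerCall]:
    """Read one caller's VCF into normalized :class:`CallerCall` records.

    Multi-allelic records are split into one call per alt.  Records with
    missing count fields come back with depth 0 / alt 0 and
    ``missing_counts=True``.  When ``reference`` is given, keys are
    normalized (left-aligned, minimal).
    """
    if caller not in CALLERS:
        raise ConfigurationError(f"unknown caller dialect {caller!r}")
    calls: list[CallerCall] = []
    verbosity = pysam.set_verbosity(0)  # silence htslib header-sanity chatter
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    finally:
        pysam.set_verbosity(verbosity)
    with vf:
        record_no = 0
        it = iter(vf)
        while True:
            try:
                rec = next(it, None)
            except (OSError, ValueError) as exc:
                raise VcfFormatError(
                    f"malformed VCF record #{record_no + 1} in {path}: {exc}"
                ) from exc
            if rec is None:
                break
            record_no += 1
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                if alt in (".", "*", "<NON_REF>"):
                    continue
                depth, alt_reads, missing = _dialect_counts(rec, i, caller)
                if alt_reads > depth:
                    raise VcfFormatError(
                        f"alt reads {alt_reads} exceed depth {depth} at record "
                        f"#{record_no} in {path}"
                    )
                if reference is not None:
                    key = normalize_variant(rec.chrom, rec.pos, rec.ref, alt, reference)
                else:
                    key = VariantKey(rec.chrom, rec.pos, rec.ref, alt)
                calls.append(
                    CallerCall(
                        key=key,
                        caller=caller,
                        depth=depth,
                        alt_reads=alt_reads,
                        raw_pos=rec.pos,
                        missing_counts=missing,
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# Merging


def merge_callers(calls: Iterable[CallerCall], sample_id: str) -> list[MergedVariant]:
    """Group one sample's calls by variant key and aggregate caller evidence.

    Depth and alt reads are aggregated as medians across reporting
    callers.  Output is sorted by key, so the merge is invariant to
    input order.  Duplicate (caller, key) pairs are an integrity error.
    """
    grouped: dict[VariantKey, dict[str, tuple[int, int]]] = {}
    for call in calls:
        ev = grouped.setdefault(call.key, {})
        if call.caller in ev:
            raise IntegrityError(
                f"duplicate call from caller {call.caller} for {call.key} "
                f"in sample {sample_id}"
            )
        ev[call.caller] = (call.depth, call.alt_reads)
    return [
        MergedVariant(key=key, sample_id=sample_id, evidence=grouped[key])
        for key in sorted(grouped)
    ]
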