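"""Synthetic study generator: samples, runs, truth variants, caller
callsets, clinical follow-up, expression, and assay plates.

Everything is driven by one integer seed through hierarchically split
`numpy` SeedSequences (one stream per purpose per sample), so output is
bit-identical for a fixed config regardless of evaluation order.

Modelling choices (documented, since only medians are anchored):

* per-exon depths are negative binomial with mean at the configured
  median and a dispersion parameter (overdispersed counts);
* caller false negatives follow a logistic in log10(VAF) per caller, so
  low-frequency variants are missed more often;
* germline SNP carriers draw VAF from a tight Beta centred at 0.5
  (heterozygous expectation);
* run-restricted artifacts only ever appear in samples of their run.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .annotation import packaged_reference, packaged_regions_path
from .errors import ConfigurationError
from .variant_io import (
    CALLERS,
    CallerCall,
    TargetRegions,
    VariantKey,
    read_regions,
)

# VAF distributions: ("fixed", v) | ("uniform", lo, hi) | ("beta", mean, concentration)
VafDist = tuple


def _draw_vaf(dist: VafDist, rng: np.random.Generator) -> float:
    kind = dist[0]
    if kind == "fixed":
        return float(dist[1])
    if kind == "uniform":
        return float(rng.uniform(dist[1], dist[2]))
    if kind == "beta":
        mean, conc = float(dist[1]), float(dist[2])
        return float(rng.beta(mean * conc, (1 - mean) * conc))
    raise ConfigurationError(f"unknown VAF distribution {dist!r}")


@dataclass
class TruthVariantSpec:
    """A planted true variant: who carries it and at what frequency."""

    key: VariantKey
    vaf: VafDist
    carrier_fraction: float | None = None
    carriers: list[str] | None = None
    origin: str = "somatic"

    def __post_init__(self) -> None:
        if (self.carrier_fraction is None) == (self.carriers is None):
            raise ConfigurationError(
                f"truth_variants[{self.key}]: give exactly one of carrier_fraction/carriers"
            )
        if self.carrier_fraction is not None and not 0 <= self.carrier_fraction <= 1:
            raise ConfigurationError(
                f"truth_variants[{self.key}]: carrier_fraction outside [0,1]"
            )


@dataclass
class ArtifactSpec:
    """A sequencing artifact confined to one run."""

    key: VariantKey
    run_id: str
    n_carriers: int
    vaf: VafDist = ("uniform", 0.025, 0.06)


@dataclass
class CallerProfile:
    """Noise behaviour of one caller.

    ``fn_midpoint_vaf`` is the VAF at which the caller misses half the
    variants (0 disables false negatives); ``fp_rate`` is the chance of
    one spurious call per targeted region per sample.
    """

    fp_rate: float = 0.0
    fn_midpoint_vaf: float = 0.0
    fn_slope: float = 4.0
    depth_jitter: float = 0.0
    alt_jitter: float = 0.0

    def miss_probability(self, vaf: float) -> float:
        if self.fn_midpoint_vaf <= 0 or vaf <= 0:
            return 0.0 if vaf > 0 else 1.0
        x = self.fn_slope * (math.log10(vaf) - math.log10(self.fn_midpoint_vaf))
        return 1.0 / (1.0 + math.exp(x))


@dataclass
class SampleRecord:
    sample_id: str
    subtype: str
    run_id: str
    exon_depths: dict[str, int]


@dataclass
class TruthRecord:
    sample_id: str
    key: VariantKey
    vaf: float
    origin: str  # somatic | germline | artifact


@dataclass
class SimulationConfig:
    """Full description of the synthetic study."""

    n_samples: int
    subtype_proportions: dict[str, float]
    runs: list[tuple[str, int]]
    exon_depth_medians: dict[str, int]
    depth_dispersion: float = 20.0
    truth_variants: list[TruthVariantSpec] = field(default_factory=list)
    germline_variants: list[VariantKey] = field(default_factory=list)
    germline_snp_rate: float = 0.0
    artifact_spec: list[ArtifactSpec] = field(default_factory=list)
    caller_profiles: dict[str, CallerProfile] = field(default_factory=dict)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 0:
            raise ConfigurationError("n_samples must be >= 0")
        if self.n_samples > 0:
            total = sum(self.subtype_proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"subtype_proportions must sum to 1 (got {total})"
                )
            if sum(n for _, n in self.runs) != self.n_samples:
                raise ConfigurationError("runs sizes must sum to n_samples")
        if not 0 <= self.germline_snp_rate <= 1:
            raise ConfigurationError("germline_snp_rate must be in [0,1]")
        if self.depth_dispersion <= 0:
            raise ConfigurationError("depth_dispersion must be positive")
        for caller, profile in self.caller_profiles.items():
            if caller not in CALLERS:
                raise ConfigurationError(f"caller_profiles: unknown caller {caller!r}")
            for name in ("fp_rate", "depth_jitter", "alt_jitter"):
                v = getattr(profile, name)
                if not 0 <= v <= 1:
                    raise ConfigurationError(
                        f"caller_profiles[{caller}].{name} must be in [0,1]"
                    )
        run_ids = {rid for rid, _ in self.runs}
        for art in self.artifact_spec:
            if art.run_id not in run_ids:
                raise ConfigurationError(
                    f"artifact_spec[{art.key}]: unknown run {art.run_id!r}"
                )


@dataclass
class ClinicalEntry:
    """One sample's simulated clinical follow-up row."""

    sample_id: str
    group: str
    mrd_level: float | None
    relapsed: bool
    time_years: float
    event_type: int


@dataclass
class ExpressionEntry:
    sample_id: str
    probe_intensity: float
    ct_target: float
    ct_reference: float


@dataclass
class PlateEntry:
    """Flat plate well row; vehicle wells carry well_type='vehicle'."""

    sample_id: str
    drug: str
    condition: str
    well_type: str  # dosed | vehicle
    concentration: float
    replicate: int
    signal: float


@dataclass
class CohortBundle:
    samples: list[SampleRecord]
    truth: list[TruthRecord]
    clinical: list[ClinicalEntry]
    expression: list[ExpressionEntry]
    plates: list[PlateEntry]

    def truth_by_sample(self) -> dict[str, list[TruthRecord]]:
        out: dict[str, list[TruthRecord]] = {s.sample_id: [] for s in self.samples}
        for rec in self.truth:
            out[rec.sample_id].append(rec)
        return out


def _rng(seed: int, domain: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, domain, index)))


def _subtype_counts(proportions: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n samples across subtypes."""
    items = sorted(proportions.items())
    raw = [(name, p * n) for name, p in items]
    counts = {name: int(math.floor(x)) for name, x in raw}
    short = n - sum(counts.values())
    for name, _ in sorted(raw, key=lambda kv: kv[1] - math.floor(kv[1]), reverse=True)[:short]:
        counts[name] += 1
    return counts


def simulate_cohort(
    config: SimulationConfig,
    regions: TargetRegions | None = None,
) -> CohortBundle:
    """Generate the full synthetic study for a validated config."""
    config.validate()
    if config.n_samples == 0:
        return CohortBundle([], [], [], [], [])
    regions = regions or read_regions(packaged_regions_path())
    seed = config.rng_seed
    rng0 = _rng(seed, 0)

    # samples: ids, subtypes (shuffled largest-remainder), sequential runs
    ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    subtype_pool: list[str] = []
    for name, count in _subtype_counts(config.subtype_proportions, config.n_samples).items():
        subtype_pool.extend([name] * count)
    subtypes = [subtype_pool[j] for j in rng0.permutation(config.n_samples)]
    run_of: list[str] = []
    for run_id, size in config.runs:
        run_of.extend([run_id] * size)

    samples = []
    for i, sid in enumerate(ids):
        rng_i = _rng(seed, 1, i)
        depths = {}
        for exon, mu in sorted(config.exon_depth_medians.items()):
            r = config.depth_dispersion
            depths[exon] = int(rng_i.negative_binomial(r, r / (r + mu)))
        samples.append(
            SampleRecord(sample_id=sid, subtype=subtypes[i], run_id=run_of[i], exon_depths=depths)
        )

    # truth variants
    truth: list[TruthRecord] = []
    for spec in config.truth_variants:
        if spec.carriers is not None:
            carriers = list(spec.carriers)
        else:
            k = int(round(spec.carrier_fraction * config.n_samples))
            carriers = [ids[j] for j in rng0.choice(config.n_samples, size=k, replace=False)]
        for sid in carriers:
            truth.append(TruthRecord(sid, spec.key, _draw_vaf(spec.vaf, rng0), spec.origin))
    for key in config.germline_variants:
        mask = rng0.uniform(size=config.n_samples) < config.germline_snp_rate
        for i in np.flatnonzero(mask):
            vaf = float(rng0.beta(60, 60))  # tight around heterozygous 0.5
            truth.append(TruthRecord(ids[i], key, vaf, "germline"))
    for art in config.artifact_spec:
        run_samples = [s.sample_id for s in samples if s.run_id == art.run_id]
        if art.n_carriers > len(run_samples):
            raise ConfigurationError(
                f"artifact_spec[{art.key}]: {art.n_carriers} carriers exceed run size"
            )
        chosen = rng0.choice(len(run_samples), size=art.n_carriers, replace=False)
        for j in chosen:
            truth.append(
                TruthRecord(run_samples[j], art.key, _draw_vaf(art.vaf, rng0), "artifact")
            )

    somatic_carriers = {t.sample_id for t in truth if t.origin == "somatic"}
    clinical = _simulate_clinical(ids, somatic_carriers, seed)
    expression = _simulate_expression(ids, somatic_carriers, seed)
    plates = _simulate_plates(ids, somatic_carriers, seed)
    return CohortBundle(samples, truth, clinical, expression, plates)


def _simulate_clinical(
    ids: list[str], mutated: set[str], seed: int
) -> list[ClinicalEntry]:
    """Stylized follow-up: mutated cases relapse more and carry higher MRD."""
    out = []
    for i, sid in enumerate(ids):
        rng = _rng(seed, 3, i)
        group = "mutated" if sid in mutated else "wildtype"
        relapse_rate = 0.16 if group == "mutated" else 0.05
        t_relapse = rng.exponential(1.0 / relapse_rate)
        t_death = rng.exponential(1.0 / 0.02)
        t_censor = rng.uniform(5.0, 10.0)
        time = min(t_relapse, t_death, t_censor)
        if time == t_relapse:
            event = 1
        elif time == t_death:
            event = 2
        else:
            event = 0
        relapsed = event == 1
        if rng.uniform() < 0.2:
            mrd = None
        elif relapsed:
            mrd = 10 ** rng.uniform(-3.0, -1.5) if rng.uniform() < 0.85 else 10 ** rng.uniform(-5.0, -3.2)
        else:
            mrd = 10 ** rng.uniform(-5.5, -3.1) if rng.uniform() < 0.9 else 10 ** rng.uniform(-3.0, -2.0)
        out.append(ClinicalEntry(sid, group, mrd, relapsed, float(time), event))
    return out


def _simulate_expression(
    ids: list[str], mutated: set[str], seed: int
) -> list[ExpressionEntry]:
    """Receptor overexpression co-occurs with mutation in most carriers."""
    out = []
    for i, sid in enumerate(ids):
        rng = _rng(seed, 4, i)
        high = (sid in mutated and rng.uniform() < 0.85) or rng.uniform() < 0.07
        intensity = float(rng.normal(9.5, 0.6) if high else rng.normal(6.5, 0.8))
        rel = 10 ** rng.uniform(1.2, 2.3) if high else 10 ** rng.uniform(-0.5, 0.9)
        ct_ref = float(rng.normal(20.0, 0.3))
        ct_target = ct_ref - math.log2(rel / 100.0)
        out.append(ExpressionEntry(sid, intensity, float(ct_target), ct_ref))
    return out


_CONCENTRATIONS = (0.05, 0.15, 0.75, 1.5, 3.0, 6.0)


def _simulate_plates(ids: list[str], mutated: set[str], seed: int) -> list[PlateEntry]:
    """Duplicate-well viability plates for a small ex vivo panel.

    Mutated samples follow a more sensitive logistic dose-response than
    wildtype; TSLP deepens the response of mutated samples only.
    """
    mut_panel = sorted(mutated)[:6]
    wt_panel = [sid for sid in ids if sid not in mutated][:6]
    out = []
    for sid in mut_panel + wt_panel:
        i = ids.index(sid)
        rng = _rng(seed, 5, i)
        is_mut = sid in mutated
        for drug in ("momelotinib", "ruxolitinib"):
            for condition in ("none", "TSLP"):
                if is_mut and condition == "TSLP":
                    ic50, bottom = 0.5, 15.0
                elif is_mut:
                    ic50, bottom = 2.0, 45.0
                else:
                    ic50, bottom = 8.0, 65.0
                vehicle_base = float(rng.uniform(1.0, 1.4))
                for rep in (1, 2):
                    out.append(
                        PlateEntry(sid, drug, condition, "vehicle", 0.0, rep,
                                   vehicle_base * float(rng.normal(1.0, 0.03)))
                    )
                for conc in _CONCENTRATIONS:
                    v = bottom + (100.0 - bottom) / (1.0 + (conc / ic50) ** 1.3)
                    for rep in (1, 2):
                        signal = vehicle_base * v / 100.0 * float(rng.normal(1.0, 0.04))
                        out.append(
                            PlateEntry(sid, drug, condition, "dosed", conc, rep, max(signal, 0.0))
                        )
    return out


# ---------------------------------------------------------------------------
# Caller emission


def emit_caller_callsets(
    bundle: CohortBundle,
    config: SimulationConfig,
    regions: TargetRegions | None = None,
    reference: Mapping[str, str] | None = None,
) -> dict[str, dict[str, list[CallerCall]]]:
    """Turn per-sample truth into noisy per-caller callsets.

    For each truth variant one binomial alt-read count is drawn from the
    sample's exon depth and true VAF (shared across callers, as all
    callers see the same reads), then each caller applies its own miss
    probability, jitter, and false-positive injection.
    """
    config.validate()
    regions = regions or read_regions(packaged_regions_path())
    reference = reference or packaged_reference()
    seed = config.rng_seed
    idx = {s.sample_id: i for i, s in enumerate(bundle.samples)}
    by_sample = bundle.truth_by_sample()
    callsets: dict[str, dict[str, list[CallerCall]]] = {}
    for sample in bundle.samples:
        rng = _rng(seed, 2, idx[sample.sample_id])
        per_caller: dict[str, list[CallerCall]] = {c: [] for c in CALLERS}
        for rec in sorted(by_sample[sample.sample_id], key=lambda r: r.key):
            exon = regions.label_at(rec.key)
            if exon is None or exon not in sample.exon_depths:
                continue
            depth = sample.exon_depths[exon]
            true_alt = int(rng.binomial(depth, rec.vaf)) if depth > 0 else 0
            for caller in CALLERS:
                profile = config.caller_profiles.get(caller, CallerProfile())
                missed = rng.uniform() < profile.miss_probability(rec.vaf)
                if missed or true_alt == 0:
                    continue
                d = depth
                a = true_alt
                if profile.depth_jitter > 0:
                    d = max(0, int(round(depth * (1 + profile.depth_jitter * rng.uniform(-1, 1)))))
                if profile.alt_jitter > 0:
                    a = int(round(true_alt * (1 + profile.alt_jitter * rng.uniform(-1, 1))))
                a = min(max(a, 0), d)
                if a == 0:
                    continue
                per_caller[caller].append(
                    CallerCall(rec.key, caller, d, a, raw_pos=rec.key.pos)
                )
        # caller-specific false positives, one chance per region per caller
        for caller in CALLERS:
            profile = config.caller_profiles.get(caller, CallerProfile())
            if profile.fp_rate <= 0:
                continue
            seen = {c.key for c in per_caller[caller]}
            for chrom, start, end, label in regions:
                if rng.uniform() >= profile.fp_rate:
                    continue
                pos0 = int(rng.integers(start, end))
                ref_base = reference[chrom][pos0]
                alt_base = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                key = VariantKey(chrom, pos0 + 1, ref_base, alt_base)
                if key in seen:
                    continue
                depth = sample.exon_depths.get(label, 0)
                if depth == 0:
                    continue
                alt = max(1, int(rng.binomial(depth, rng.uniform(0.002, 0.02))))
                per_caller[caller].append(CallerCall(key, caller, depth, alt, raw_pos=key.pos))
        callsets[sample.sample_id] = per_caller
    return callsets


# ---------------------------------------------------------------------------
# Fixture writing (all plain text)

_VCF_HEADERS = {
    "A": [
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ],
    "B": [
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=RD,Number=1,Type=Integer,Description="Reference depth">',
        '##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Variant depth">',
    ],
    "C": [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw depth">',
        '##INFO=<ID=DP4,Number=4,Type=Integer,Description="Ref fwd, ref rev, alt fwd, alt rev">',
    ],
    "D": [
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ],
}


def _vcf_record(call: CallerCall, caller: str) -> str:
    k = call.key
    fixed = f"{k.chrom}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t.\tPASS"
    d, a = call.depth, call.alt_reads
    if caller == "A":
        return f"{fixed}\t.\tDP:AD\t{d}:{d - a},{a}"
    if caller == "B":
        return f"{fixed}\t.\tDP:RD:AD\t{d}:{d - a}:{a}"
    if caller == "C":
        rf, af = (d - a) // 2, a // 2
        info = f"DP={d};DP4={rf},{d - a - rf},{af},{a - af}"
        return f"{fixed}\t{info}"
    if caller == "D":
        return f"{fixed}\t.\tAD:DP\t{d - a},{a}:{d}"
    raise ConfigurationError(f"unknown caller {caller!r}")


def write_caller_vcf(path, calls: Iterable[CallerCall], caller: str,
                     contigs: Mapping[str, int]) -> None:
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length={n}>" for c, n in sorted(contigs.items())]
    lines += _VCF_HEADERS[caller]
    if caller == "C":
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    else:
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE")
    for call in sorted(calls, key=lambda c: c.key):
        lines.append(_vcf_record(call, caller))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_fixture(
    bundle: CohortBundle,
    callsets: Mapping[str, Mapping[str, list[CallerCall]]],
    directory,
    reference: Mapping[str, str] | None = None,
    regions_path: str | None = None,
) -> None:
    """Write the whole study as a plain-text file tree.

    Layout: ``vcf/<sample>.<caller>.vcf`` per sample per caller, plus
    ``regions.bed``, ``samples.tsv``, ``truth.tsv``, ``clinical.tsv``,
    ``expression.tsv`` and ``plates.tsv``.
    """
    reference = reference or packaged_reference()
    directory = str(directory)
    vcf_dir = os.path.join(directory, "vcf")
    try:
        os.makedirs(vcf_dir, exist_ok=True)
    except OSError as exc:
        raise ConfigurationError(f"cannot create fixture directory {directory}: {exc}") from exc
    contigs = {c: len(s) for c, s in reference.items()}
    for sid, per_caller in callsets.items():
        for caller, calls in per_caller.items():
            write_caller_vcf(
                os.path.join(vcf_dir, f"{sid}.{caller}.vcf"), calls, caller, contigs
            )
    with open(regions_path or packaged_regions_path()) as src, open(
        os.path.join(directory, "regions.bed"), "w"
    ) as dst:
        dst.write(src.read())

    exons = sorted({e for s in bundle.samples for e in s.exon_depths})
    with open(os.path.join(directory, "samples.tsv"), "w") as fh:
        fh.write("sample_id\tsubtype\trun_id\t" + "\t".join(f"depth_{e}" for e in exons) + "\n")
        for s in bundle.samples:
            depths = "\t".join(str(s.exon_depths.get(e, 0)) for e in exons)
            fh.write(f"{s.sample_id}\t{s.subtype}\t{s.run_id}\t{depths}\n")
    with open(os.path.join(directory, "truth.tsv"), "w") as fh:
        fh.write("sample_id\tchrom\tpos\tref\talt\tvaf\torigin\n")
        for t in bundle.truth:
            k = t.key
            fh.write(f"{t.sample_id}\t{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\t{t.vaf:.6f}\t{t.origin}\n")
    with open(os.path.join(directory, "clinical.tsv"), "w") as fh:
        fh.write("sample_id\tgroup\tmrd_level\trelapsed\ttime_years\tevent_type\n")
        for c in bundle.clinical:
            mrd = "" if c.mrd_level is None else f"{c.mrd_level:.3e}"
            fh.write(
                f"{c.sample_id}\t{c.group}\t{mrd}\t{int(c.relapsed)}\t"
                f"{c.time_years:.6f}\t{c.event_type}\n"
            )
    with open(os.path.join(directory, "expression.tsv"), "w") as fh:
        fh.write("sample_id\tprobe_intensity\tct_target\tct_reference\n")
        for e in bundle.expression:
            fh.write(
                f"{e.sample_id}\t{e.probe_intensity:.4f}\t{e.ct_target:.4f}\t{e.ct_reference:.4f}\n"
            )
    with open(os.path.join(directory, "plates.tsv"), "w") as fh:
        fh.write("sample_id\tdrug\tcondition\twell_type\tconcentration\treplicate\tsignal\n")
        for p in bundle.plates:
            fh.write(
                f"{p.sample_id}\t{p.drug}\t{p.condition}\t{p.well_type}\t"
                f"{p.concentration:g}\t{p.replicate}\t{p.signal:.6f}\n"
            )


# ---------------------------------------------------------------------------
# Default study configuration


#: subtype composition of the emulated 461-sample screening cohort
DEFAULT_SUBTYPE_COUNTS = {
    "BCR-ABL1": 26,
    "BCR-ABL1-like": 79,
    "B-other": 67,
    "ETV6-RUNX1": 124,
    "high-hyperdiploid": 124,
    "KMT2A-AFF1": 15,
    "TCF3-PBX1": 26,
}

#: per-exon median target depths for the default simulation
DEFAULT_EXON_DEPTHS = {"exon16": 673, "exon20": 577, "exon21": 711, "exon23": 944}


def default_config(
    n_samples: int = 461,
    seed: int = 0,
    noiseless: bool = False,
) -> SimulationConfig:
    """A ready-to-run study config mirroring the screening design.

    Hotspot truth variants sit on the packaged reference fragment; the
    germline plant and the run-restricted artifact exercise the
    cohort-level rules.  ``noiseless=True`` disables all caller noise.
    """
    total = sum(DEFAULT_SUBTYPE_COUNTS.values())
    proportions = {k: v / total for k, v in DEFAULT_SUBTYPE_COUNTS.items()}
    n_run1 = n_samples // 2
    runs = [("run1", n_run1), ("run2", n_samples - n_run1)]
    if noiseless:
        profiles = {c: CallerProfile() for c in CALLERS}
    else:
        profiles = {
            "A": CallerProfile(fp_rate=0.002, fn_midpoint_vaf=0.004, depth_jitter=0.05, alt_jitter=0.05),
            "B": CallerProfile(fp_rate=0.004, fn_midpoint_vaf=0.008, depth_jitter=0.08, alt_jitter=0.08),
            "C": CallerProfile(fp_rate=0.002, fn_midpoint_vaf=0.01, depth_jitter=0.05, alt_jitter=0.05),
            "D": CallerProfile(fp_rate=0.001, fn_midpoint_vaf=0.005, depth_jitter=0.04, alt_jitter=0.04),
        }
    return SimulationConfig(
        n_samples=n_samples,
        subtype_proportions=proportions,
        runs=runs,
        exon_depth_medians=dict(DEFAULT_EXON_DEPTHS),
        depth_dispersion=20.0,
        truth_variants=[
            TruthVariantSpec(VariantKey("JAK2FRAG", 450, "A", "G"), ("uniform", 0.05, 0.56),
                             carrier_fraction=0.022),
            TruthVariantSpec(VariantKey("JAK2FRAG", 761, "G", "A"), ("uniform", 0.03, 0.30),
                             carrier_fraction=0.009),
            TruthVariantSpec(VariantKey("JAK2FRAG", 1681, "G", "A"), ("fixed", 0.50),
                             carrier_fraction=0.004),
        ],
        germline_variants=[VariantKey("JAK2FRAG", 1101, "C", "T")],
        germline_snp_rate=0.30,
        artifact_spec=[ArtifactSpec(VariantKey("JAK2FRAG", 801, "G", "T"), "run1",
                                    max(2, n_samples // 25))],
        caller_profiles=profiles,
        rng_seed=seed,
    )


def noiseless_config(config: SimulationConfig) -> SimulationConfig:
    """Copy of a config with every caller noise channel switched off."""
    return replace(config, caller_profiles={c: CallerProfile() for c in CALLERS})
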