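"""End-to-end pipeline: simulate -> filter -> detect-limit -> stats -> assay.

Every stage writes plain TSV/JSON artifacts into the output directory;
``run_pipeline`` chains them and records a manifest (config hash, seed,
library versions) so re-runs with the same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .annotation import (
    load_cosmic,
    load_popfreq,
    load_transcript,
    packaged_cosmic,
    packaged_popfreq,
    packaged_reference,
    packaged_regions_path,
    packaged_transcript,
)
from .assay_response import compare_groups, significance_annotation, summarize_dose_response
from .clinical_stats import (
    classify_crlf2,
    cumulative_incidence,
    gray_test,
    mrd_relapse_association,
    relative_expression,
)
from .consensus_filter import (
    RULES,
    CohortRow,
    CohortVariantTable,
    FilterOutcome,
    FilterThresholds,
    filter_cohort,
)
from .detection_limit import cohort_detection_summary
from .errors import ConfigurationError, JakscreenError
from .synthetic_cohort import default_config, emit_caller_callsets, simulate_cohort, write_fixture
from .tables import (
    depth_triples,
    read_clinical_tsv,
    read_expression_tsv,
    read_plates_tsv,
    read_samples_tsv,
)
from .variant_io import CALLERS, load_reference, merge_callers, read_caller_vcf, read_regions


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults are the published thresholds."""

    out_dir: str = "jakscreen_out"
    fixture_dir: str | None = None  # None -> simulate into out_dir/fixture
    n_samples: int = 461
    seed: int = 0
    noiseless: bool = False
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    detection_vaf: float = 0.05
    mrd_threshold: float = 1e-3
    expression_percentile: float = 90.0
    equal_variance_ttest: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = FilterThresholds(**raw.pop("thresholds", {}))
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(thresholds=thresholds, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# Stages


def simulate_stage(config: PipelineConfig, directory: str) -> None:
    sim = default_config(n_samples=config.n_samples, seed=config.seed,
                         noiseless=config.noiseless)
    bundle = simulate_cohort(sim)
    callsets = emit_caller_callsets(bundle, sim)
    write_fixture(bundle, callsets, directory)


def build_cohort_table(
    vcf_dir: str,
    samples_df: pd.DataFrame,
    reference,
) -> CohortVariantTable:
    """Read every per-sample per-caller VCF and merge into a cohort table."""
    rows: list[CohortRow] = []
    run_sizes: dict[str, int] = {}
    for srow in samples_df.itertuples():
        run_sizes[srow.run_id] = run_sizes.get(srow.run_id, 0) + 1
        calls = []
        for caller in CALLERS:
            path = os.path.join(vcf_dir, f"{srow.sample_id}.{caller}.vcf")
            if os.path.exists(path):
                calls.extend(read_caller_vcf(path, caller, reference))
        for mv in merge_callers(calls, srow.sample_id):
            rows.append(CohortRow(sample_id=srow.sample_id, run_id=srow.run_id, variant=mv))
    return CohortVariantTable(rows=rows, run_sizes=run_sizes)


def filter_stage(
    vcf_dir: str,
    bed_path: str,
    samples_path: str,
    out_dir: str,
    thresholds: FilterThresholds | None = None,
    cosmic_path: str | None = None,
    popfreq_path: str | None = None,
    transcript_path: str | None = None,
    reference_path: str | None = None,
) -> FilterOutcome:
    """Run the cascade over a fixture tree and write the audit artifacts."""
    reference = load_reference(reference_path) if reference_path else packaged_reference()
    regions = read_regions(bed_path)
    cosmic = load_cosmic(cosmic_path, reference) if cosmic_path else packaged_cosmic(reference)
    freqs = load_popfreq(popfreq_path, reference) if popfreq_path else packaged_popfreq(reference)
    model = load_transcript(transcript_path) if transcript_path else packaged_transcript()
    samples_df = read_samples_tsv(samples_path)
    table = build_cohort_table(vcf_dir, samples_df, reference)
    outcome = filter_cohort(table, cosmic, freqs, model, regions, reference, thresholds)
    os.makedirs(out_dir, exist_ok=True)
    _write_audit(outcome, out_dir)
    return outcome


def _write_audit(outcome: FilterOutcome, out_dir: str) -> None:
    with open(os.path.join(out_dir, "audit.tsv"), "w") as fh:
        fh.write("sample_id\tchrom\tpos\tref\talt\tfinal\t" + "\t".join(RULES) + "\n")
        for d in outcome.decisions:
            k = d.key
            verdicts = "\t".join(d.verdicts[r] for r in RULES)
            fh.write(f"{d.sample_id}\t{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\t{d.final}\t{verdicts}\n")
    with open(os.path.join(out_dir, "rule_summary.tsv"), "w") as fh:
        fh.write("rule\tn_excluding\n")
        for rule in RULES:
            fh.write(f"{rule}\t{outcome.rule_exclusions[rule]}\n")
    with open(os.path.join(out_dir, "sample_status.tsv"), "w") as fh:
        fh.write("sample_id\tmutated\n")
        for sid in sorted(outcome.sample_status):
            fh.write(f"{sid}\t{int(outcome.sample_status[sid])}\n")
    with open(os.path.join(out_dir, "kept.vcf"), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Carrier sample">\n')
        fh.write('##INFO=<ID=NCALLERS,Number=1,Type=Integer,Description="Reporting callers">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Aggregated depth">\n')
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in sorted(outcome.kept.rows, key=lambda r: (r.variant.key, r.sample_id)):
            mv = row.variant
            k = mv.key
            fh.write(
                f"{k.chrom}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t.\tPASS\t"
                f"SAMPLE={mv.sample_id};NCALLERS={mv.n_callers};DP={mv.agg_depth};"
                f"VAF={mv.vaf:.4f}\n"
            )


def detection_stage(samples_path: str, vaf: float, out_path: str | None = None) -> str:
    """Per-exon and overall detectable fractions at the given VAF, as TSV."""
    summary = cohort_detection_summary(depth_triples(read_samples_tsv(samples_path)), vaf)
    lines = ["aggregate\tfraction_detectable"]
    lines.append(f"sample_exon_pairs\t{summary.pair_fraction:.4f}")
    lines.append(f"samples_all_exons\t{summary.sample_fraction:.4f}")
    for exon, frac in summary.per_exon.items():
        lines.append(f"exon:{exon}\t{frac:.4f}")
    text = "\n".join(lines) + "\n"
    if out_path:
        with open(out_path, "w") as fh:
            fh.write(text)
    return text


def stats_stage(
    clinical_path: str,
    expression_path: str,
    out_dir: str,
    percentile: float = 90.0,
    mutated_samples: set[str] | None = None,
) -> dict:
    """Outcome and expression statistics for the cohort.

    The MRD association is computed among mutated samples when a mutated
    set is supplied (mirroring the per-mutation analysis), else over all
    samples with MRD data.
    """
    clinical, outcomes = read_clinical_tsv(clinical_path)
    expression = read_expression_tsv(expression_path)
    os.makedirs(out_dir, exist_ok=True)

    mrd_records = clinical
    if mutated_samples is not None:
        mrd_records = [c for c in clinical if c.sample_id in mutated_samples]
    result: dict = {}
    try:
        table, p = mrd_relapse_association(mrd_records)
        result["mrd_relapse"] = {"table": table.tolist(), "fisher_p": p}
    except ConfigurationError as exc:
        result["mrd_relapse"] = {"error": str(exc)}

    if len({o.group for o in outcomes}) >= 2:
        stat, df, p_gray = gray_test(outcomes)
        result["gray_test"] = {"statistic": stat, "df": df, "p": p_gray}
    else:
        result["gray_test"] = {"error": "fewer than two outcome groups"}

    cir_rows = []
    for group in sorted({o.group for o in outcomes}):
        ci = cumulative_incidence([o for o in outcomes if o.group == group])
        for t, c1, c2, s in zip(ci.times, ci.cif[1], ci.cif[2], ci.survival):
            cir_rows.append((group, t, c1, c2, s))
    with open(os.path.join(out_dir, "cir.tsv"), "w") as fh:
        fh.write("group\ttime\tcir_event\tcir_competing\tsurvival\n")
        for group, t, c1, c2, s in cir_rows:
            fh.write(f"{group}\t{t:.6f}\t{c1:.6f}\t{c2:.6f}\t{s:.6f}\n")

    intensities = [e.probe_intensity for e in expression if e.probe_intensity is not None]
    cls = classify_crlf2(intensities, percentile)
    result["crlf2"] = {
        "threshold": cls.threshold,
        "n_high": cls.labels.count("high"),
        "n": len(cls.labels),
    }
    with open(os.path.join(out_dir, "expression_classified.tsv"), "w") as fh:
        fh.write("sample_id\tprobe_intensity\tcrlf2_label\trelative_expression_pct\n")
        idx = 0
        for e in expression:
            label = ""
            if e.probe_intensity is not None:
                label = cls.labels[idx]
                idx += 1
            rel = relative_expression(e.ct_target, e.ct_reference)
            fh.write(f"{e.sample_id}\t{e.probe_intensity}\t{label}\t{rel:.4f}\n")

    with open(os.path.join(out_dir, "stats.json"), "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
    return result


def assay_stage(
    plates_path: str,
    out_dir: str,
    group_of: dict[str, str] | None = None,
    equal_var: bool = True,
) -> None:
    """Summarize dose-response per (drug, condition, group) and compare groups."""
    plates = read_plates_tsv(plates_path)
    os.makedirs(out_dir, exist_ok=True)
    if group_of is None:
        group_of = {}
    keyed: dict[tuple[str, str, str], list] = {}
    for plate in plates:
        group = group_of.get(plate.sample_id, "all")
        keyed.setdefault((plate.drug, plate.condition, group), []).append(plate)
    with open(os.path.join(out_dir, "dose_response.tsv"), "w") as fh:
        fh.write("drug\tcondition\tgroup\tconcentration\tmean_viability\tsem\tn\n")
        for (drug, condition, group), ps in sorted(keyed.items()):
            for conc, mean, sem, n in summarize_dose_response(ps).points:
                sem_s = "" if np.isnan(sem) else f"{sem:.4f}"
                fh.write(f"{drug}\t{condition}\t{group}\t{conc:g}\t{mean:.4f}\t{sem_s}\t{n}\n")
    with open(os.path.join(out_dir, "comparisons.tsv"), "w") as fh:
        fh.write("drug\tcondition\tgroup_a\tgroup_b\tconcentration\tp\tannotation\n")
        combos = sorted({(d, c) for d, c, _ in keyed})
        for drug, condition in combos:
            groups = sorted({g for d, c, g in keyed if d == drug and c == condition})
            for i, ga in enumerate(groups):
                for gb in groups[i + 1 :]:
                    pa, pb = keyed[(drug, condition, ga)], keyed[(drug, condition, gb)]
                    concs = sorted(
                        {c for p in pa for c, _, _ in p.wells}
                        & {c for p in pb for c, _, _ in p.wells}
                    )
                    for conc in concs:
                        try:
                            p = compare_groups(pa, pb, conc, equal_var=equal_var)
                        except ConfigurationError:
                            continue
                        fh.write(
                            f"{drug}\t{condition}\t{ga}\t{gb}\t{conc:g}\t{p:.6g}\t"
                            f"{significance_annotation(p)}\n"
                        )


# ---------------------------------------------------------------------------
# Orchestration


def run_pipeline(config: PipelineConfig) -> str:
    """Execute every stage; returns the artifact directory.

    Any stage failure is re-raised with the stage name prepended.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    fixture = config.fixture_dir or os.path.join(out, "fixture")

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except JakscreenError as exc:
            raise JakscreenError(f"stage {name!r} failed: {exc}") from exc

    if config.fixture_dir is None:
        _stage("simulate", simulate_stage, config, fixture)
    outcome = _stage(
        "filter",
        filter_stage,
        os.path.join(fixture, "vcf"),
        os.path.join(fixture, "regions.bed"),
        os.path.join(fixture, "samples.tsv"),
        os.path.join(out, "filter"),
        config.thresholds,
    )
    _stage(
        "detect-limit",
        detection_stage,
        os.path.join(fixture, "samples.tsv"),
        config.detection_vaf,
        os.path.join(out, "detection.tsv"),
    )
    mutated = {sid for sid, flag in outcome.sample_status.items() if flag}
    _stage(
        "stats",
        stats_stage,
        os.path.join(fixture, "clinical.tsv"),
        os.path.join(fixture, "expression.tsv"),
        os.path.join(out, "stats"),
        config.expression_percentile,
        mutated or None,
    )
    samples_df = read_samples_tsv(os.path.join(fixture, "samples.tsv"))
    group_of = {
        row.sample_id: ("mutated" if row.sample_id in mutated else "wildtype")
        for row in samples_df.itertuples()
    }
    _stage(
        "assay",
        assay_stage,
        os.path.join(fixture, "plates.tsv"),
        os.path.join(out, "assay"),
        group_of,
        config.equal_variance_ttest,
    )
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "jakscreen": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "stage_counts": {
            "variant_rows": len(outcome.decisions),
            "kept_rows": len(outcome.kept.rows),
            "mutated_samples": len(mutated),
        },
        "inputs": sorted(
            os.path.relpath(p, fixture)
            for p in glob.glob(os.path.join(fixture, "**", "*"), recursive=True)
            if os.path.isfile(p)
        ),
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
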