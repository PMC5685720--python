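"""The consensus filter cascade with a complete per-rule audit trail.

Ten rules are evaluated for every merged variant occurrence, in a fixed
documented order; all rules are always evaluated (no short-circuit) so
the audit can attribute exclusions per rule.  A row is kept iff no rule
failed.

Rule boundary semantics (exactly as configured by default):

* ``DEPTH``        fails iff aggregated depth < 100 (100 passes)
* ``ALTREADS``     fails iff aggregated alt reads < 10 (10 passes)
* ``VAFPRESENCE``  key retained iff max VAF across the cohort > 0.02 (strict)
* ``GERMLINE``     flagged iff carriers >= 10 and mean VAF > 0.40 and
  median VAF > 0.40 (strict on both VAF conditions)
* ``SNP``          flagged iff mean of the three population AFs >= 0.05
  (inclusive; alternative "each >= threshold" mode available)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .annotation import (
    AA_CHANGING,
    TranscriptModel,
    annotate_effect,
    lookup_cosmic,
    lookup_population_frequency,
)
from .errors import ConfigurationError
from .variant_io import MergedVariant, TargetRegions, VariantKey, in_region

RULES = (
    "REGION",
    "MULTICALLER",
    "DEPTH",
    "ALTREADS",
    "VAFPRESENCE",
    "RUNBALANCE",
    "COSMIC",
    "AACHANGE",
    "SNP",
    "GERMLINE",
)

PASS, FAIL, NOT_EVALUATED = "pass", "fail", "not_evaluated"


@dataclass
class FilterThresholds:
    """All cascade thresholds; defaults are the published values."""

    min_depth: int = 100
    min_alt: int = 10
    min_callers: int = 2
    vaf_presence: float = 0.02
    snp_af: float = 0.05
    snp_mode: str = "mean"  # "mean" of the three AFs, or "each"
    germline_min_carriers: int = 10
    germline_vaf: float = 0.40
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_depth", "min_alt", "min_callers"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("vaf_presence", "snp_af", "germline_vaf", "alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.snp_mode not in ("mean", "each"):
            raise ConfigurationError(f"snp_mode must be 'mean' or 'each', got {self.snp_mode!r}")


@dataclass
class FilterDecision:
    """Per-variant, per-rule verdicts; kept iff no rule failed."""

    sample_id: str
    key: VariantKey
    verdicts: dict[str, str]

    @property
    def fail_reasons(self) -> list[str]:
        return [r for r in RULES if self.verdicts.get(r) == FAIL]

    @property
    def final(self) -> str:
        return "excluded" if self.fail_reasons else "kept"


@dataclass
class CohortRow:
    sample_id: str
    run_id: str
    variant: MergedVariant


@dataclass
class KeyAnnotation:
    """Cohort-level summary of one variant key."""

    n_carriers: int
    mean_vaf: float
    median_vaf: float
    max_vaf: float
    run_carriers: dict[str, int]


@dataclass
class CohortVariantTable:
    """All merged variant occurrences across the cohort, plus run structure.

    ``run_sizes`` counts every sequenced sample per run (not just
    carriers); the run-balance expectation needs the full denominators.
    """

    rows: list[CohortRow]
    run_sizes: dict[str, int]

    @property
    def n_samples(self) -> int:
        return sum(self.run_sizes.values())

    def key_annotations(self) -> dict[VariantKey, KeyAnnotation]:
        by_key: dict[VariantKey, list[CohortRow]] = {}
        for row in self.rows:
            by_key.setdefault(row.variant.key, []).append(row)
        out: dict[VariantKey, KeyAnnotation] = {}
        for key, rows in by_key.items():
            vafs = np.array([r.variant.vaf for r in rows], dtype=float)
            run_carriers: dict[str, int] = {run: 0 for run in self.run_sizes}
            for r in rows:
                run_carriers[r.run_id] = run_carriers.get(r.run_id, 0) + 1
            out[key] = KeyAnnotation(
                n_carriers=len(rows),
                mean_vaf=float(vafs.mean()),
                median_vaf=float(np.median(vafs)),
                max_vaf=float(vafs.max()),
                run_carriers=run_carriers,
            )
        return out


# ---------------------------------------------------------------------------
# Individual rules


def apply_site_filters(
    mv: MergedVariant,
    regions: TargetRegions,
    thresholds: FilterThresholds | None = None,
) -> dict[str, str]:
    """Per-occurrence rules: REGION, MULTICALLER, DEPTH, ALTREADS."""
    t = thresholds or FilterThresholds()
    return {
        "REGION": PASS if in_region(mv.key, regions) else FAIL,
        "MULTICALLER": PASS if mv.n_callers >= t.min_callers else FAIL,
        "DEPTH": PASS if mv.agg_depth >= t.min_depth else FAIL,
        "ALTREADS": PASS if mv.agg_alt >= t.min_alt else FAIL,
    }


def cohort_vaf_presence(
    table: CohortVariantTable,
    threshold: float = 0.02,
) -> set[VariantKey]:
    """Keys seen at least once with VAF strictly above the threshold."""
    return {
        key for key, ann in table.key_annotations().items() if ann.max_vaf > threshold
    }


@dataclass
class RunBalanceResult:
    chi2: float
    p: float
    passed: bool
    evaluated: bool = True


def run_balance_test(
    key: VariantKey,
    table: CohortVariantTable,
    alpha: float = 0.05,
) -> RunBalanceResult:
    """Pearson chi-square of carrier counts against run-size expectations.

    Expected carriers per run = total carriers x run size / cohort size;
    runs with expected count 0 are excluded from the sum; df = runs - 1.
    Degenerate inputs (single run, or <= 1 carrier) cannot be assessed
    and pass with ``evaluated=False``.
    """
    ann = table.key_annotations().get(key)
    if ann is None:
        return RunBalanceResult(0.0, 1.0, True, evaluated=False)
    runs = [r for r in table.run_sizes if table.run_sizes[r] > 0]
    if len(runs) < 2 or ann.n_carriers <= 1:
        return RunBalanceResult(0.0, 1.0, True, evaluated=False)
    n = table.n_samples
    total = ann.n_carriers
    chi2 = 0.0
    for run in runs:
        expected = total * table.run_sizes[run] / n
        if expected == 0:
            continue
        observed = ann.run_carriers.get(run, 0)
        chi2 += (observed - expected) ** 2 / expected
    df = len(runs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return RunBalanceResult(float(chi2), p, p >= alpha)


def germline_flag(
    table: CohortVariantTable,
    min_carriers: int = 10,
    vaf_threshold: float = 0.40,
) -> set[VariantKey]:
    """Keys carried by many samples at near-heterozygous VAF.

    Flagged iff carriers >= ``min_carriers`` and both mean and median
    VAF strictly exceed ``vaf_threshold``.
    """
    return {
        key
        for key, ann in table.key_annotations().items()
        if ann.n_carriers >= min_carriers
        and ann.mean_vaf > vaf_threshold
        and ann.median_vaf > vaf_threshold
    }


def snp_flag(
    key: VariantKey,
    freqs: Mapping[VariantKey, tuple[float, float, float]],
    threshold: float = 0.05,
    mode: str = "mean",
) -> bool:
    """Known-SNP rule on the three population allele frequencies.

    ``mean`` mode flags when the arithmetic mean of the three AFs is
    >= threshold (absent key -> all zero); ``each`` mode requires every
    AF to reach the threshold.
    """
    afs = lookup_population_frequency(key, freqs)
    if mode == "mean":
        # inclusive boundary with a float guard so e.g. mean(0.06,0.05,0.04)
        # counts as exactly the threshold
        return sum(afs) / 3.0 >= threshold - 1e-12
    if mode == "each":
        return all(af >= threshold for af in afs)
    raise ConfigurationError(f"unknown snp mode {mode!r}")


# ---------------------------------------------------------------------------
# Full cascade


@dataclass
class FilterOutcome:
    """Kept rows plus the complete audit."""

    kept: CohortVariantTable
    decisions: list[FilterDecision]
    rule_exclusions: dict[str, int]
    sample_status: dict[str, bool] = field(default_factory=dict)

    @property
    def kept_keys(self) -> set[VariantKey]:
        return {row.variant.key for row in self.kept.rows}


def filter_cohort(
    table: CohortVariantTable,
    cosmic: Mapping[VariantKey, str],
    freqs: Mapping[VariantKey, tuple[float, float, float]],
    model: TranscriptModel,
    regions: TargetRegions,
    reference: Mapping[str, str],
    thresholds: FilterThresholds | None = None,
) -> FilterOutcome:
    """Run the full ten-rule cascade over the cohort table.

    Every rule is evaluated for every row (audit completeness); cohort-
    level rules (VAFPRESENCE, RUNBALANCE, GERMLINE) are computed once per
    key and applied to each occurrence.
    """
    t = thresholds or FilterThresholds()
    keys = {row.variant.key for row in table.rows}
    vaf_present = cohort_vaf_presence(table, t.vaf_presence)
    germline = germline_flag(table, t.germline_min_carriers, t.germline_vaf)
    balance = {key: run_balance_test(key, table, t.alpha) for key in keys}
    effects = {key: annotate_effect(key, model, reference) for key in keys}

    decisions: list[FilterDecision] = []
    kept_rows: list[CohortRow] = []
    rule_exclusions = {rule: 0 for rule in RULES}
    sample_status: dict[str, bool] = {}
    for row in table.rows:
        mv = row.variant
        key = mv.key
        verdicts = dict.fromkeys(RULES, NOT_EVALUATED)
        verdicts.update(apply_site_filters(mv, regions, t))
        verdicts["VAFPRESENCE"] = PASS if key in vaf_present else FAIL
        b = balance[key]
        verdicts["RUNBALANCE"] = (
            NOT_EVALUATED if not b.evaluated else (PASS if b.passed else FAIL)
        )
        verdicts["COSMIC"] = PASS if lookup_cosmic(key, cosmic) else FAIL
        verdicts["AACHANGE"] = PASS if effects[key] in AA_CHANGING else FAIL
        verdicts["SNP"] = FAIL if snp_flag(key, freqs, t.snp_af, t.snp_mode) else PASS
        verdicts["GERMLINE"] = FAIL if key in germline else PASS
        decision = FilterDecision(sample_id=mv.sample_id, key=key, verdicts=verdicts)
        decisions.append(decision)
        for rule in decision.fail_reasons:
            rule_exclusions[rule] += 1
        sample_status.setdefault(mv.sample_id, False)
        if decision.final == "kept":
            kept_rows.append(row)
            sample_status[mv.sample_id] = True
    kept = CohortVariantTable(rows=kept_rows, run_sizes=dict(table.run_sizes))
    return FilterOutcome(
        kept=kept,
        decisions=decisions,
        rule_exclusions=rule_exclusions,
        sample_status=sample_status,
    )
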