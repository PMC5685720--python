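"""Filter cascade: per-rule boundaries, cohort rules, audit, oracle equivalence."""

import numpy as np
import pytest
from scipy import stats

from jakscreen.annotation import AA_CHANGING, annotate_effect
from jakscreen.consensus_filter import (
    RULES,
    CohortVariantTable,
    FilterThresholds,
    apply_site_filters,
    cohort_vaf_presence,
    filter_cohort,
    germline_flag,
    run_balance_test,
    snp_flag,
)
from jakscreen.variant_io import VariantKey, in_region

from .conftest import make_merged, make_table, random_cohort_table

HOTSPOT = VariantKey("JAK2FRAG", 450, "A", "G")  # in cosmic, missense, in exon16
NON_COSMIC = VariantKey("JAK2FRAG", 300, "A", "G")  # position only; built per-test
SNP_KEY = VariantKey("JAK2FRAG", 1101, "C", "T")  # in packaged popfreq


def brute_force_kept(table, cosmic, freqs, model, regions, reference, t=None):
    """Independent re-statement of all ten predicates as one comprehension.

    Deliberately avoids the cascade machinery: plain loops and direct
    arithmetic over the table rows.
    """
    t = t or FilterThresholds()
    rows = table.rows
    # cohort aggregates, recomputed from scratch
    vafs_of = {}
    runs_of = {}
    for r in rows:
        vafs_of.setdefault(r.variant.key, []).append(r.variant.vaf)
        runs_of.setdefault(r.variant.key, []).append(r.run_id)

    def vaf_presence(key):
        return max(vafs_of[key]) > t.vaf_presence

    def not_germline(key):
        v = vafs_of[key]
        return not (
            len(v) >= t.germline_min_carriers
            and np.mean(v) > t.germline_vaf
            and np.median(v) > t.germline_vaf
        )

    def balanced(key):
        carriers = runs_of[key]
        run_ids = [rid for rid in table.run_sizes if table.run_sizes[rid] > 0]
        if len(run_ids) < 2 or len(carriers) <= 1:
            return True
        n = sum(table.run_sizes.values())
        chi2 = 0.0
        for rid in run_ids:
            exp = len(carriers) * table.run_sizes[rid] / n
            if exp > 0:
                chi2 += (carriers.count(rid) - exp) ** 2 / exp
        return stats.chi2.sf(chi2, len(run_ids) - 1) >= t.alpha

    def not_snp(key):
        afs = freqs.get(key, (0.0, 0.0, 0.0))
        return sum(afs) / 3 < t.snp_af

    return {
        (r.sample_id, r.variant.key)
        for r in rows
        if in_region(r.variant.key, regions)
        and r.variant.n_callers >= t.min_callers
        and r.variant.agg_depth >= t.min_depth
        and r.variant.agg_alt >= t.min_alt
        and vaf_presence(r.variant.key)
        and balanced(r.variant.key)
        and r.variant.key in cosmic
        and annotate_effect(r.variant.key, model, reference) in AA_CHANGING
        and not_snp(r.variant.key)
        and not_germline(r.variant.key)
    }


class TestSiteFilters:
    @pytest.mark.parametrize("depth,verdict", [(99, "fail"), (100, "pass")])
    def test_depth_boundary(self, regions, depth, verdict):
        mv = make_merged(HOTSPOT, depth=depth, alt=min(50, depth))
        assert apply_site_filters(mv, regions)["DEPTH"] == verdict

    @pytest.mark.parametrize("alt,verdict", [(9, "fail"), (10, "pass")])
    def test_altreads_boundary(self, regions, alt, verdict):
        mv = make_merged(HOTSPOT, depth=600, alt=alt)
        assert apply_site_filters(mv, regions)["ALTREADS"] == verdict

    @pytest.mark.parametrize("nc,verdict", [(1, "fail"), (2, "pass")])
    def test_multicaller_boundary(self, regions, nc, verdict):
        mv = make_merged(HOTSPOT, n_callers=nc)
        assert apply_site_filters(mv, regions)["MULTICALLER"] == verdict

    def test_region_rule(self, regions, reference):
        base = reference["JAK2FRAG"][59]
        off = VariantKey("JAK2FRAG", 60, base, "A" if base != "A" else "C")
        assert apply_site_filters(make_merged(off), regions)["REGION"] == "fail"
        assert apply_site_filters(make_merged(HOTSPOT), regions)["REGION"] == "pass"


class TestVafPresence:
    def test_exactly_two_percent_excluded(self):
        table = make_table([("S1", "run1", HOTSPOT, 1000, 20, 3)], {"run1": 5})
        assert HOTSPOT not in cohort_vaf_presence(table)  # 0.020 is not > 0.02

    def test_cohort_level_rescue(self):
        table = make_table(
            [
                ("S1", "run1", HOTSPOT, 1000, 10, 3),  # VAF 0.01
                ("S2", "run1", HOTSPOT, 1000, 30, 3),  # VAF 0.03
            ],
            {"run1": 5},
        )
        assert HOTSPOT in cohort_vaf_presence(table)

    def test_no_carrier_above_threshold(self):
        table = make_table(
            [("S1", "run1", HOTSPOT, 1000, 10, 3), ("S2", "run1", HOTSPOT, 1000, 15, 3)],
            {"run1": 5},
        )
        assert cohort_vaf_presence(table) == set()


class TestRunBalance:
    def _table(self, carriers_run1, carriers_run2, run_size=50):
        entries = []
        for i in range(carriers_run1):
            entries.append((f"A{i}", "run1", HOTSPOT, 600, 60, 3))
        for i in range(carriers_run2):
            entries.append((f"B{i}", "run2", HOTSPOT, 600, 60, 3))
        return make_table(entries, {"run1": run_size, "run2": run_size})

    def test_perfect_balance(self):
        res = run_balance_test(HOTSPOT, self._table(5, 5))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.passed

    def test_hand_computed_imbalance(self):
        # carriers 10 vs 0 in equal runs: chi2 = 25/5 + 25/5 = 10, df=1
        res = run_balance_test(HOTSPOT, self._table(10, 0))
        assert res.chi2 == pytest.approx(10.0)
        assert res.p == pytest.approx(float(stats.chi2.sf(10.0, 1)), rel=1e-12)
        assert res.p == pytest.approx(0.001565, abs=2e-5)
        assert not res.passed

    def test_single_carrier_degenerate_passes(self):
        res = run_balance_test(HOTSPOT, self._table(1, 0))
        assert res.passed and not res.evaluated

    def test_single_run_not_evaluated(self):
        table = make_table([("S1", "run1", HOTSPOT, 600, 60, 3)], {"run1": 10})
        res = run_balance_test(HOTSPOT, table)
        assert res.passed and not res.evaluated


class TestGermlineFlag:
    def _table(self, vafs):
        entries = [
            (f"S{i}", "run1", SNP_KEY, 1000, int(round(v * 1000)), 3)
            for i, v in enumerate(vafs)
        ]
        return make_table(entries, {"run1": max(len(vafs), 20)})

    def test_flagged_at_thresholds(self):
        vafs = [0.45] * 5 + [0.37] * 5  # n=10, mean 0.41, median 0.41
        assert SNP_KEY in germline_flag(self._table(vafs))

    def test_not_flagged_below_carrier_count(self):
        assert SNP_KEY not in germline_flag(self._table([0.5] * 9))

    def test_not_flagged_when_median_fails(self):
        # 12 carriers, mean 0.55 but median 0.39
        vafs = [0.39] * 7 + [0.774] * 5
        table = self._table(vafs)
        ann = table.key_annotations()[SNP_KEY]
        assert ann.mean_vaf > 0.40 and ann.median_vaf < 0.40
        assert SNP_KEY not in germline_flag(table)


class TestSnpFlag:
    def test_mean_boundary_inclusive(self):
        freqs = {SNP_KEY: (0.06, 0.05, 0.04)}  # mean exactly 0.05
        assert snp_flag(SNP_KEY, freqs)

    def test_novel_variant_not_flagged(self):
        assert not snp_flag(HOTSPOT, {})

    def test_clearly_common(self):
        assert snp_flag(SNP_KEY, {SNP_KEY: (0.10, 0.10, 0.10)})

    def test_each_mode(self):
        freqs = {SNP_KEY: (0.20, 0.04, 0.20)}  # mean >= 0.05 but one af below
        assert snp_flag(SNP_KEY, freqs, mode="mean")
        assert not snp_flag(SNP_KEY, freqs, mode="each")


class TestFilterCohort:
    def test_single_rule_failure_reported(self, cosmic, popfreq, model, regions, reference):
        seq = reference["JAK2FRAG"]
        non_cosmic = VariantKey("JAK2FRAG", 300, seq[299], "T" if seq[299] != "T" else "G")
        table = make_table([("S1", "run1", non_cosmic, 600, 60, 3)], {"run1": 10})
        out = filter_cohort(table, cosmic, popfreq, model, regions, reference)
        (decision,) = out.decisions
        assert decision.final == "excluded"
        assert decision.fail_reasons == ["COSMIC"]

    def test_empty_table(self, cosmic, popfreq, model, regions, reference):
        table = CohortVariantTable(rows=[], run_sizes={"run1": 5})
        out = filter_cohort(table, cosmic, popfreq, model, regions, reference)
        assert out.decisions == [] and out.kept.rows == []

    def test_audit_completeness(self, cosmic, popfreq, model, regions, reference):
        rng = np.random.default_rng(5)
        table = random_cohort_table(rng, reference, cosmic, popfreq, regions)
        out = filter_cohort(table, cosmic, popfreq, model, regions, reference)
        assert len(out.decisions) == len(table.rows)
        kept = sum(d.final == "kept" for d in out.decisions)
        assert kept == len(out.kept.rows)
        for d in out.decisions:  # every rule has a verdict entry
            assert set(d.verdicts) == set(RULES)

    def test_row_order_invariance(self, cosmic, popfreq, model, regions, reference):
        rng = np.random.default_rng(11)
        table = random_cohort_table(rng, reference, cosmic, popfreq, regions)
        shuffled = CohortVariantTable(
            rows=[table.rows[i] for i in rng.permutation(len(table.rows))],
            run_sizes=dict(table.run_sizes),
        )
        a = filter_cohort(table, cosmic, popfreq, model, regions, reference)
        b = filter_cohort(shuffled, cosmic, popfreq, model, regions, reference)
        key = lambda d: (d.sample_id, d.key)
        va = {key(d): d.verdicts for d in a.decisions}
        vb = {key(d): d.verdicts for d in b.decisions}
        assert va == vb

    def test_depth_threshold_monotonicity(self, cosmic, popfreq, model, regions, reference):
        rng = np.random.default_rng(23)
        table = random_cohort_table(rng, reference, cosmic, popfreq, regions)
        kept_sets = []
        for min_depth in (50, 100, 400, 800):
            out = filter_cohort(
                table, cosmic, popfreq, model, regions, reference,
                FilterThresholds(min_depth=min_depth),
            )
            kept_sets.append({(r.sample_id, r.variant.key) for r in out.kept.rows})
        for lower, higher in zip(kept_sets, kept_sets[1:]):
            assert higher <= lower

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_random_cohorts(
        self, seed, cosmic, popfreq, model, regions, reference
    ):
        rng = np.random.default_rng(1000 + seed)
        table = random_cohort_table(rng, reference, cosmic, popfreq, regions)
        out = filter_cohort(table, cosmic, popfreq, model, regions, reference)
        mine = {(r.sample_id, r.variant.key) for r in out.kept.rows}
        oracle = brute_force_kept(table, cosmic, popfreq, model, regions, reference)
        assert mine == oracle
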