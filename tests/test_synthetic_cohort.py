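"""Synthetic study generator: determinism, distributional targets, emission
noise models, and fixture round-trips."""

import dataclasses
import os

import numpy as np
import pytest

from jakscreen.errors import ConfigurationError
from jakscreen.synthetic_cohort import (
    ArtifactSpec,
    CallerProfile,
    CohortBundle,
    SampleRecord,
    SimulationConfig,
    TruthRecord,
    TruthVariantSpec,
    default_config,
    emit_caller_callsets,
    simulate_cohort,
    write_fixture,
)
from jakscreen.variant_io import CALLERS, VariantKey, merge_callers, read_caller_vcf

HOTSPOT = VariantKey("JAK2FRAG", 450, "A", "G")
ARTIFACT = VariantKey("JAK2FRAG", 801, "G", "T")


def small_config(seed=7, n=20, **kwargs):
    base = dict(
        n_samples=n,
        subtype_proportions={"B-other": 0.5, "ETV6-RUNX1": 0.5},
        runs=[("run1", n // 2), ("run2", n - n // 2)],
        exon_depth_medians={"exon16": 673, "exon20": 577, "exon21": 711, "exon23": 944},
        truth_variants=[
            TruthVariantSpec(HOTSPOT, ("uniform", 0.1, 0.5), carrier_fraction=0.2)
        ],
        rng_seed=seed,
    )
    base.update(kwargs)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_bad_proportions_named(self):
        cfg = small_config()
        cfg.subtype_proportions = {"a": 0.5, "b": 0.4}
        with pytest.raises(ConfigurationError, match="subtype_proportions"):
            cfg.validate()

    def test_run_sizes_must_sum(self):
        cfg = small_config()
        cfg.runs = [("run1", 3)]
        with pytest.raises(ConfigurationError, match="runs"):
            cfg.validate()

    def test_rate_bounds(self):
        cfg = small_config(germline_snp_rate=1.5)
        with pytest.raises(ConfigurationError, match="germline_snp_rate"):
            cfg.validate()

    def test_caller_profile_rate_bounds(self):
        cfg = small_config(caller_profiles={"A": CallerProfile(fp_rate=2.0)})
        with pytest.raises(ConfigurationError, match="fp_rate"):
            cfg.validate()

    def test_truth_spec_needs_exactly_one_carrier_definition(self):
        with pytest.raises(ConfigurationError):
            TruthVariantSpec(HOTSPOT, ("fixed", 0.5))


class TestSimulateCohort:
    def test_empty_cohort(self):
        cfg = small_config(n=0)
        cfg.runs = []
        cfg.subtype_proportions = {}
        bundle = simulate_cohort(cfg)
        assert bundle.samples == [] and bundle.truth == [] and bundle.clinical == []

    def test_determinism_bit_identical(self):
        a = simulate_cohort(small_config(seed=7))
        b = simulate_cohort(small_config(seed=7))
        assert dataclasses.asdict(CohortBundle(**vars(a))) == dataclasses.asdict(
            CohortBundle(**vars(b))
        )

    def test_different_seed_differs(self):
        a = simulate_cohort(small_config(seed=7))
        b = simulate_cohort(small_config(seed=8))
        assert [s.exon_depths for s in a.samples] != [s.exon_depths for s in b.samples]

    def test_exon23_median_depth_within_ten_percent(self):
        bundle = simulate_cohort(default_config(n_samples=461, seed=1))
        depths = [s.exon_depths["exon23"] for s in bundle.samples]
        assert 850 <= np.median(depths) <= 1039

    def test_run_structure(self):
        bundle = simulate_cohort(small_config(n=20))
        runs = [s.run_id for s in bundle.samples]
        assert runs.count("run1") == 10 and runs.count("run2") == 10

    def test_subtype_apportionment(self):
        bundle = simulate_cohort(small_config(n=20))
        subtypes = [s.subtype for s in bundle.samples]
        assert subtypes.count("B-other") == 10

    def test_carrier_count_as_configured(self):
        bundle = simulate_cohort(small_config(n=20))  # fraction 0.2 -> 4 carriers
        carriers = [t for t in bundle.truth if t.key == HOTSPOT]
        assert len(carriers) == 4
        assert all(0.1 <= t.vaf <= 0.5 for t in carriers)

    def test_explicit_carrier_list(self):
        cfg = small_config(
            truth_variants=[
                TruthVariantSpec(HOTSPOT, ("fixed", 0.3), carriers=["S0001", "S0003"])
            ]
        )
        bundle = simulate_cohort(cfg)
        assert {t.sample_id for t in bundle.truth if t.key == HOTSPOT} == {"S0001", "S0003"}

    def test_germline_vaf_near_half(self):
        cfg = small_config(
            n=200,
            runs=[("run1", 100), ("run2", 100)],
            germline_variants=[VariantKey("JAK2FRAG", 1101, "C", "T")],
            germline_snp_rate=0.5,
        )
        bundle = simulate_cohort(cfg)
        gl = [t for t in bundle.truth if t.origin == "germline"]
        assert len(gl) >= 60  # ~100 expected
        vafs = np.array([t.vaf for t in gl])
        assert abs(vafs.mean() - 0.5) < 0.03
        assert np.all((vafs > 0.3) & (vafs < 0.7))

    def test_artifact_confined_to_run(self):
        cfg = small_config(artifact_spec=[ArtifactSpec(ARTIFACT, "run1", 5)])
        bundle = simulate_cohort(cfg)
        run_of = {s.sample_id: s.run_id for s in bundle.samples}
        art = [t for t in bundle.truth if t.origin == "artifact"]
        assert len(art) == 5
        assert all(run_of[t.sample_id] == "run1" for t in art)

    def test_referenced_samples_exist_and_vafs_valid(self):
        bundle = simulate_cohort(default_config(n_samples=60, seed=2))
        ids = {s.sample_id for s in bundle.samples}
        assert {t.sample_id for t in bundle.truth} <= ids
        assert {c.sample_id for c in bundle.clinical} <= ids
        assert {e.sample_id for e in bundle.expression} <= ids
        assert all(0 < t.vaf <= 1 for t in bundle.truth)


class TestEmission:
    def test_noiseless_callsets_equal_truth(self):
        cfg = small_config()
        bundle = simulate_cohort(cfg)
        callsets = emit_caller_callsets(bundle, cfg)
        truth = bundle.truth_by_sample()
        for sid, per_caller in callsets.items():
            expected_keys = {t.key for t in truth[sid]}
            for caller in CALLERS:
                assert {c.key for c in per_caller[caller]} == expected_keys
            # identical counts across callers in the noiseless limit
            snapshots = {
                caller: sorted((c.key, c.depth, c.alt_reads) for c in per_caller[caller])
                for caller in CALLERS
            }
            assert len(set(map(tuple, snapshots.values()))) == 1

    def test_binomial_alt_counts(self):
        # 1000 carriers at depth 600, VAF 0.5: mean alt in 300 +/- 3*sd/sqrt(n)
        samples = [
            SampleRecord(f"S{i:04d}", "B-other", "run1", {"exon16": 600})
            for i in range(1000)
        ]
        truth = [TruthRecord(s.sample_id, HOTSPOT, 0.5, "somatic") for s in samples]
        bundle = CohortBundle(samples, truth, [], [], [])
        cfg = small_config(n=1000, runs=[("run1", 1000)])
        callsets = emit_caller_callsets(bundle, cfg)
        alts = [callsets[s.sample_id]["A"][0].alt_reads for s in samples]
        assert 290 <= np.mean(alts) <= 310

    def test_vaf_converges_at_extreme_depth(self):
        samples = [SampleRecord("S0001", "B-other", "run1", {"exon16": 100_000})]
        truth = [TruthRecord("S0001", HOTSPOT, 0.2, "somatic")]
        bundle = CohortBundle(samples, truth, [], [], [])
        cfg = small_config(n=1, runs=[("run1", 1)])
        call = emit_caller_callsets(bundle, cfg)["S0001"]["A"][0]
        assert abs(call.alt_reads / call.depth - 0.2) < 0.01 * 0.2 + 0.005

    def test_fn_rate_suppresses_low_vaf(self):
        profile = CallerProfile(fn_midpoint_vaf=0.05, fn_slope=3.0)
        assert profile.miss_probability(0.05) == pytest.approx(0.5)
        assert profile.miss_probability(0.5) < 0.05
        assert profile.miss_probability(0.005) > 0.9

    def test_false_positives_injected(self):
        cfg = small_config(caller_profiles={"B": CallerProfile(fp_rate=1.0)})
        bundle = simulate_cohort(cfg)
        callsets = emit_caller_callsets(bundle, cfg)
        truth = bundle.truth_by_sample()
        extra = 0
        for sid, per_caller in callsets.items():
            truth_keys = {t.key for t in truth[sid]}
            extra += sum(1 for c in per_caller["B"] if c.key not in truth_keys)
            assert all(c.key in truth_keys for c in per_caller["A"])
        assert extra >= len(bundle.samples)  # ~4 regions x fp_rate 1 per sample

    def test_jitter_changes_counts_but_stays_bounded(self):
        cfg = small_config(
            caller_profiles={"D": CallerProfile(depth_jitter=0.2, alt_jitter=0.2)}
        )
        bundle = simulate_cohort(cfg)
        callsets = emit_caller_callsets(bundle, cfg)
        for per_caller in callsets.values():
            for c in per_caller["D"]:
                assert 0 <= c.alt_reads <= c.depth


class TestWriteFixture:
    def test_vcf_count(self, tmp_path):
        cfg = small_config(n=10, runs=[("run1", 5), ("run2", 5)])
        bundle = simulate_cohort(cfg)
        callsets = emit_caller_callsets(bundle, cfg)
        write_fixture(bundle, callsets, tmp_path)
        vcfs = [f for f in os.listdir(tmp_path / "vcf") if f.endswith(".vcf")]
        assert len(vcfs) == 40  # 10 samples x 4 callers

    def test_empty_bundle_writes_headers(self, tmp_path):
        bundle = CohortBundle([], [], [], [], [])
        write_fixture(bundle, {}, tmp_path)
        for name in ("samples.tsv", "truth.tsv", "clinical.tsv", "expression.tsv", "plates.tsv"):
            lines = (tmp_path / name).read_text().splitlines()
            assert len(lines) == 1 and "\t" in lines[0]

    def test_round_trip_preserves_every_call(self, tmp_path, reference):
        cfg = default_config(n_samples=8, seed=5)
        cfg.runs = [("run1", 4), ("run2", 4)]
        bundle = simulate_cohort(cfg)
        callsets = emit_caller_callsets(bundle, cfg)
        write_fixture(bundle, callsets, tmp_path)
        for sid, per_caller in callsets.items():
            for caller, calls in per_caller.items():
                path = tmp_path / "vcf" / f"{sid}.{caller}.vcf"
                back = read_caller_vcf(path, caller, reference)
                assert sorted((c.key, c.depth, c.alt_reads) for c in back) == sorted(
                    (c.key, c.depth, c.alt_reads) for c in calls
                )

    def test_merge_after_round_trip(self, tmp_path, reference):
        cfg = small_config(n=4, runs=[("run1", 2), ("run2", 2)])
        bundle = simulate_cohort(cfg)
        callsets = emit_caller_callsets(bundle, cfg)
        write_fixture(bundle, callsets, tmp_path)
        truth = bundle.truth_by_sample()
        for sid, per_caller in callsets.items():
            calls = []
            for caller in CALLERS:
                calls.extend(read_caller_vcf(tmp_path / "vcf" / f"{sid}.{caller}.vcf", caller, reference))
            merged = merge_callers(calls, sid)
            assert {m.key for m in merged} == {t.key for t in truth[sid]}
            for m in merged:
                assert m.n_callers == 4
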