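# jakscreen

Consensus filtering of multi-caller targeted-amplicon variant calls, with
detection-limit modelling and the downstream clinical/assay statistics of a
hotspot screening study — plus a synthetic-cohort generator so the whole
pipeline is testable without any external data.

## What it does

- **`synthetic_cohort`** — simulates a full study: samples assigned to
  sequencing runs and cytogenetic subtypes, per-exon depths (negative
  binomial around configurable medians), planted somatic/germline/artifact
  variants, noisy per-caller callsets, clinical follow-up, expression
  tables, and viability plates. Deterministic per seed.
- **`variant_io`** — reads four caller VCF dialects, normalizes variants
  (suffix/prefix trimming, indel left-alignment), reads targeted-region
  BED (0-based half-open), and merges per-caller evidence per sample
  (median depth/alt across callers).
- **`annotation`** — classifies coding effects against a packaged ~2 kb
  synthetic reference fragment and a hand-built 4-exon transcript model;
  looks up a COSMIC-like whitelist and population allele frequencies.
- **`consensus_filter`** — the ten-rule cascade (REGION, MULTICALLER,
  DEPTH ≥ 100, ALTREADS ≥ 10, cohort VAF presence > 2%, run-balance
  chi-square, COSMIC membership, amino-acid change, SNP mean AF ≥ 5%,
  germline ≥ 10 carriers with mean & median VAF > 40%), with a complete
  per-variant per-rule audit trail; all rules are evaluated, no
  short-circuiting.
- **`detection_limit`** — deterministic detectability (depth ≥ 100 and
  expected alt reads ≥ 10) plus the exact binomial detection probability,
  aggregated per exon and cohort-wide.
- **`clinical_stats`** — 90th-percentile expression classification,
  comparative-Ct relative expression (2^−ΔCt × 100%), two-sided Fisher
  exact test by hypergeometric enumeration, Aalen–Johansen cumulative
  incidence under competing risks, and Gray's K-sample test (ρ = 0).
- **`assay_response`** — viability normalization against vehicle wells,
  replicate-collapsed dose-response summaries (mean ± SEM), pooled
  independent-samples t-tests between genotype groups.

## Caller VCF dialects

| caller | depth                  | alt reads                     |
|--------|------------------------|-------------------------------|
| A      | FORMAT `DP`            | FORMAT `AD` (ref,alt list)    |
| B      | FORMAT `DP`            | FORMAT `AD` (alt), `RD` (ref) |
| C      | INFO `DP4` (sum)       | INFO `DP4` (alt fwd+rev)      |
| D      | FORMAT `DP` / sum `AD` | FORMAT `AD` (ref,alt list)    |

## CLI

```bash
jakscreen simulate --n 461 --seed 1 --out fixture/
jakscreen filter --vcf-dir fixture/vcf --bed fixture/regions.bed \
    --samples fixture/samples.tsv --out filtered/
jakscreen detect-limit --depths fixture/samples.tsv --vaf 0.05
jakscreen stats --clinical fixture/clinical.tsv \
    --expression fixture/expression.tsv --out stats/
jakscreen assay --plates fixture/plates.tsv --out assay/
jakscreen run-all --n 461 --seed 1 --out study_out/   # all stages + manifest
```

`run-all` also accepts `--config config.yaml` (flags override file values);
the output directory contains a `manifest.json` with the config hash, seed
and library versions, so re-runs with the same seed are byte-identical.

## Packaged fixtures

`src/jakscreen/data/` ships a synthetic reference fragment (`JAK2FRAG`,
2 kb), a 4-exon transcript model whose codon numbering mimics the hotspot
residues (e.g. the codon-683 analog at 1-based position 450–452),
targeted-region BED, and COSMIC-like/population-frequency TSV fixtures.
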