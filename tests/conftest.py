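"""Shared fixtures: packaged reference data and small cohort builders."""

from __future__ import annotations

import numpy as np
import pytest

from jakscreen.annotation import (
    packaged_cosmic,
    packaged_popfreq,
    packaged_reference,
    packaged_regions_path,
    packaged_transcript,
)
from jakscreen.consensus_filter import CohortRow, CohortVariantTable
from jakscreen.variant_io import MergedVariant, VariantKey, read_regions


@pytest.fixture(scope="session")
def reference():
    return packaged_reference()


@pytest.fixture(scope="session")
def model():
    return packaged_transcript()


@pytest.fixture(scope="session")
def regions():
    return read_regions(packaged_regions_path())


@pytest.fixture(scope="session")
def cosmic(reference):
    return packaged_cosmic(reference)


@pytest.fixture(scope="session")
def popfreq(reference):
    return packaged_popfreq(reference)


def make_merged(
    key: VariantKey,
    sample_id: str = "S0001",
    depth: int = 600,
    alt: int = 60,
    n_callers: int = 3,
) -> MergedVariant:
    """A merged variant with identical evidence from n callers."""
    callers = ["A", "B", "C", "D"][:n_callers]
    return MergedVariant(
        key=key, sample_id=sample_id, evidence={c: (depth, alt) for c in callers}
    )


def make_table(
    entries: list[tuple[str, str, VariantKey, int, int, int]],
    run_sizes: dict[str, int],
) -> CohortVariantTable:
    """Cohort table from (sample, run, key, depth, alt, n_callers) tuples."""
    rows = [
        CohortRow(sample_id=sid, run_id=run, variant=make_merged(key, sid, d, a, nc))
        for sid, run, key, d, a, nc in entries
    ]
    return CohortVariantTable(rows=rows, run_sizes=run_sizes)


def random_cohort_table(
    rng: np.random.Generator,
    reference,
    cosmic,
    popfreq,
    regions,
    max_samples: int = 20,
    max_variants: int = 30,
) -> CohortVariantTable:
    """A random small cohort over a pool of keys that exercises every rule."""
    # pool: hotspots (in cosmic), the SNP plant, off-target, non-cosmic in-region
    pool = [
        VariantKey("JAK2FRAG", 450, "A", "G"),
        VariantKey("JAK2FRAG", 452, "A", "T"),
        VariantKey("JAK2FRAG", 761, "G", "A"),
        VariantKey("JAK2FRAG", 801, "G", "T"),
        VariantKey("JAK2FRAG", 1681, "G", "A"),
        VariantKey("JAK2FRAG", 1101, "C", "T"),  # popfreq SNP
        VariantKey("JAK2FRAG", 60, reference["JAK2FRAG"][59], "A" if reference["JAK2FRAG"][59] != "A" else "C"),  # off-target
        VariantKey("JAK2FRAG", 300, reference["JAK2FRAG"][299], "T" if reference["JAK2FRAG"][299] != "T" else "G"),  # in-region, non-cosmic
    ]
    n_samples = int(rng.integers(4, max_samples + 1))
    n1 = n_samples // 2
    run_sizes = {"run1": n1, "run2": n_samples - n1}
    samples = [(f"S{i:03d}", "run1" if i < n1 else "run2") for i in range(n_samples)]
    n_rows = int(rng.integers(1, max_variants + 1))
    rows: list[CohortRow] = []
    seen: set[tuple[str, VariantKey]] = set()
    for _ in range(n_rows):
        sid, run = samples[int(rng.integers(n_samples))]
        key = pool[int(rng.integers(len(pool)))]
        if (sid, key) in seen:
            continue
        seen.add((sid, key))
        depth = int(rng.integers(50, 1200))
        alt = int(rng.integers(0, depth + 1)) if rng.uniform() < 0.3 else int(
            rng.integers(0, max(2, int(depth * 0.6)))
        )
        nc = int(rng.integers(1, 5))
        rows.append(
            CohortRow(sample_id=sid, run_id=run, variant=make_merged(key, sid, depth, alt, nc))
        )
    return CohortVariantTable(rows=rows, run_sizes=run_sizes)
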