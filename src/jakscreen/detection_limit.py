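"""Detectability of a given VAF under the cascade's read-count thresholds.

The deterministic criterion is tied to the cascade itself: a variant at
frequency ``vaf`` in a sample sequenced to ``depth`` is called detectable
when the depth threshold is met and the *expected* number of
alt-supporting reads reaches the alt-read threshold.  An exact binomial
detection probability is provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .errors import ConfigurationError


def detectable(
    depth: int,
    vaf: float,
    min_depth: int = 100,
    alt_threshold: int = 10,
) -> bool:
    """Deterministic criterion: depth >= 100 and vaf * depth >= 10."""
    if depth < 0 or not 0.0 <= vaf <= 1.0:
        raise ConfigurationError(f"invalid depth/vaf ({depth}, {vaf})")
    return depth >= min_depth and vaf * depth >= alt_threshold


def detection_probability(
    depth: int,
    vaf: float,
    alt_threshold: int = 10,
    min_depth: int = 100,
) -> float:
    """P(alt reads >= threshold) for alt ~ Binomial(depth, vaf).

    Returns 0 when the depth threshold itself is not met.  The tail is
    an exact binomial survival sum (no normal approximation).
    """
    if depth < 0 or not 0.0 <= vaf <= 1.0:
        raise ConfigurationError(f"invalid depth/vaf ({depth}, {vaf})")
    if depth < min_depth:
        return 0.0
    return float(stats.binom.sf(alt_threshold - 1, depth, vaf))


@dataclass
class DetectionProfile:
    """Per-sample per-exon detectability over a VAF grid."""

    sample_id: str
    exon: str
    depth: int
    vaf_grid: list[float]
    detectable_deterministic: dict[float, bool]
    detection_probability: dict[float, float]


def detection_profile(
    sample_id: str,
    exon: str,
    depth: int,
    vaf_grid: Sequence[float] = (0.01, 0.02, 0.05, 0.10, 0.20, 0.50),
) -> DetectionProfile:
    grid = sorted(vaf_grid)
    return DetectionProfile(
        sample_id=sample_id,
        exon=exon,
        depth=depth,
        vaf_grid=grid,
        detectable_deterministic={v: detectable(depth, v) for v in grid},
        detection_probability={v: detection_probability(depth, v) for v in grid},
    )


@dataclass
class DetectionSummary:
    """Cohort detectability of one VAF, aggregated two ways.

    ``pair_fraction`` averages over (sample, exon) pairs;
    ``sample_fraction`` counts a sample only when every profiled exon is
    detectable (both aggregations reported because the choice matters).
    """

    vaf: float
    pair_fraction: float
    per_exon: dict[str, float]
    sample_fraction: float


def cohort_detection_summary(
    profiles: Iterable[tuple[str, str, int]],
    vaf: float,
    min_depth: int = 100,
    alt_threshold: int = 10,
) -> DetectionSummary:
    """Fraction of (sample, exon) depths at which ``vaf`` is detectable.

    ``profiles`` is an iterable of (sample_id, exon, depth) triples, one
    per sample per targeted exon.
    """
    triples = list(profiles)
    if not triples:
        raise ConfigurationError("cohort_detection_summary: empty depth input")
    flags = [
        (s, e, detectable(d, vaf, min_depth, alt_threshold)) for s, e, d in triples
    ]
    pair_fraction = sum(f for _, _, f in flags) / len(flags)
    exons: dict[str, list[bool]] = {}
    samples: dict[str, list[bool]] = {}
    for s, e, f in flags:
        exons.setdefault(e, []).append(f)
        samples.setdefault(s, []).append(f)
    per_exon = {e: sum(fs) / len(fs) for e, fs in sorted(exons.items())}
    sample_fraction = sum(all(fs) for fs in samples.values()) / len(samples)
    return DetectionSummary(
        vaf=vaf,
        pair_fraction=pair_fraction,
        per_exon=per_exon,
        sample_fraction=sample_fraction,
    )
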