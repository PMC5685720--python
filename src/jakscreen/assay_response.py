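"""Viability normalization against vehicle controls and group comparison.

Replicate wells collapse to a sample-level mean per concentration before
any group statistic, so a heavily replicated sample cannot dominate the
group mean or the t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError

DRUGS = ("momelotinib", "ruxolitinib")
CONDITIONS = ("none", "TSLP")


@dataclass
class AssayPlate:
    """One sample's plate for one drug: dosed wells plus vehicle wells."""

    sample_id: str
    drug: str
    condition: str
    wells: list[tuple[float, int, float]]  # (concentration uM, replicate, signal)
    vehicle_wells: list[float]

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise ConfigurationError(f"unknown drug {self.drug!r}")
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if not self.vehicle_wells:
            raise ConfigurationError(f"plate {self.sample_id}/{self.drug}: no vehicle wells")
        if any(conc < 0 for conc, _, _ in self.wells):
            raise ConfigurationError(f"plate {self.sample_id}/{self.drug}: negative concentration")


@dataclass
class DoseResponse:
    """Group summary per concentration: mean viability %, SEM, n samples."""

    points: list[tuple[float, float, float, int]]  # (conc, mean, sem, n); sem NaN if n < 2


def normalize_viability(plate: AssayPlate) -> list[tuple[float, int, float]]:
    """Per-well viability % relative to the mean vehicle signal."""
    vehicle_mean = float(np.mean(plate.vehicle_wells))
    if vehicle_mean <= 0:
        raise ConfigurationError(
            f"plate {plate.sample_id}/{plate.drug}: vehicle mean {vehicle_mean} <= 0"
        )
    return [
        (conc, rep, 100.0 * signal / vehicle_mean) for conc, rep, signal in plate.wells
    ]


def sample_level_means(plate: AssayPlate) -> dict[float, float]:
    """Mean viability per concentration after collapsing replicates."""
    by_conc: dict[float, list[float]] = {}
    for conc, _, viability in normalize_viability(plate):
        by_conc.setdefault(conc, []).append(viability)
    return {conc: float(np.mean(vs)) for conc, vs in by_conc.items()}


def summarize_dose_response(plates: Iterable[AssayPlate]) -> DoseResponse:
    """Group mean +/- SEM over sample-level means per concentration.

    A concentration measured in a single sample reports n=1 with SEM
    missing (NaN).
    """
    plates = list(plates)
    if not plates:
        raise ConfigurationError("summarize_dose_response: no plates")
    by_conc: dict[float, list[float]] = {}
    for plate in plates:
        for conc, mean in sample_level_means(plate).items():
            by_conc.setdefault(conc, []).append(mean)
    points = []
    for conc in sorted(by_conc):
        vals = np.asarray(by_conc[conc], dtype=float)
        n = len(vals)
        sem = float(np.std(vals, ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
        points.append((conc, float(vals.mean()), sem, n))
    return DoseResponse(points=points)


def compare_groups(
    group_a: Iterable[AssayPlate] | Sequence[float],
    group_b: Iterable[AssayPlate] | Sequence[float],
    concentration: float | None = None,
    equal_var: bool = True,
) -> float:
    """Two-sided independent-samples t-test on sample-level viabilities.

    Inputs are either plates (sample-level means extracted at
    ``concentration``) or raw per-sample viability values.  Pooled
    (equal-variance) form by default; Welch via ``equal_var=False``.
    """

    def _values(group) -> list[float]:
        group = list(group)
        if group and isinstance(group[0], AssayPlate):
            if concentration is None:
                raise ConfigurationError("compare_groups: concentration required for plates")
            vals = []
            for plate in group:
                means = sample_level_means(plate)
                if concentration in means:
                    vals.append(means[concentration])
            return vals
        return [float(v) for v in group]

    a, b = _values(group_a), _values(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("compare_groups: need >= 2 sample-level values per group")
    result = stats.ttest_ind(a, b, equal_var=equal_var)
    p = float(result.pvalue)
    return 1.0 if math.isnan(p) else p


def significance_annotation(p: float) -> str:
    """Conventional star annotation at the 0.05 and 0.01 levels."""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""
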