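"""Readers for the plain-text study tables written by the fixture writer."""

from __future__ import annotations

import math

import pandas as pd

from .assay_response import AssayPlate
from .clinical_stats import ClinicalRecord, ExpressionRecord, OutcomeRecord
from .errors import ConfigurationError


def read_clinical_tsv(path) -> tuple[list[ClinicalRecord], list[OutcomeRecord]]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    clinical, outcomes = [], []
    for row in df.itertuples():
        mrd = None if pd.isna(row.mrd_level) else float(row.mrd_level)
        clinical.append(
            ClinicalRecord(sample_id=row.sample_id, mrd_level=mrd, relapsed=bool(row.relapsed))
        )
        outcomes.append(
            OutcomeRecord(
                sample_id=row.sample_id,
                group=row.group,
                time=float(row.time_years),
                event_type=int(row.event_type),
            )
        )
    return clinical, outcomes


def read_expression_tsv(path) -> list[ExpressionRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})

    def _opt(v) -> float | None:
        return None if pd.isna(v) else float(v)

    return [
        ExpressionRecord(
            sample_id=row.sample_id,
            probe_intensity=_opt(row.probe_intensity),
            ct_target=_opt(row.ct_target),
            ct_reference=_opt(row.ct_reference),
        )
        for row in df.itertuples()
    ]


def read_plates_tsv(path) -> list[AssayPlate]:
    """Rebuild AssayPlate objects from the flat well table."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "drug": str})
    plates = []
    grouped = df.groupby(["sample_id", "drug", "condition"], sort=True)
    for (sid, drug, condition), sub in grouped:
        vehicle = [float(s) for s in sub.loc[sub.well_type == "vehicle", "signal"]]
        dosed = sub[sub.well_type == "dosed"]
        wells = [
            (float(r.concentration), int(r.replicate), float(r.signal))
            for r in dosed.itertuples()
        ]
        if not vehicle:
            raise ConfigurationError(f"plate {sid}/{drug}/{condition}: no vehicle wells")
        plates.append(
            AssayPlate(sample_id=sid, drug=drug, condition=condition,
                       wells=wells, vehicle_wells=vehicle)
        )
    return plates


def read_samples_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subtype": str, "run_id": str})
    if "sample_id" not in df.columns:
        raise ConfigurationError(f"samples table {path} lacks a sample_id column")
    return df


def depth_triples(samples_df: pd.DataFrame) -> list[tuple[str, str, int]]:
    """(sample, exon, depth) triples from a samples table's depth_* columns."""
    exon_cols = [c for c in samples_df.columns if c.startswith("depth_")]
    if not exon_cols:
        raise ConfigurationError("samples table has no depth_* columns")
    triples = []
    for row in samples_df.itertuples():
        for col in exon_cols:
            value = getattr(row, col)
            if not (isinstance(value, float) and math.isnan(value)):
                triples.append((row.sample_id, col.removeprefix("depth_"), int(value)))
    return triples
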