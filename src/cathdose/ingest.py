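"""Read per-event exposure tables and aggregate them into procedures.

The input is the tabular analogue of a DICOM Radiation Dose Structured
Report export from a dose-management system: one row per irradiation event,
carrying dose, geometry and patient columns.  Column headers vary by vendor
and version, so the reader takes a configurable column map and a unit
dialect; everything downstream sees canonical names and units
(DAP cGy·cm², kerma mGy, seconds).
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import units
from .records import (
    IrradiationEvent,
    PatientInfo,
    ProcedureSummary,
    ValidationReport,
    IRRADIATION_TYPES,
    PLANES,
    PROCEDURE_TYPES,
)

#: canonical event-table columns
REQUIRED_COLUMNS = (
    "procedure_id", "plane", "irradiation_type",
    "dap", "air_kerma_irp", "duration", "frame_count",
)
OPTIONAL_COLUMNS = (
    "patient_id", "age", "sex", "height", "weight_kg", "procedure_type",
    "primary_angle", "secondary_angle",
    "source_isocenter_dist", "source_detector_dist",
    "kvp", "filtration_cu",
)
GEOMETRY_COLUMNS = (
    "primary_angle", "secondary_angle",
    "source_isocenter_dist", "source_detector_dist",
)

#: export header names with units spelled out
EXPORT_HEADERS = {
    "total_dap": "total_dap[cGy.cm2]",
    "dap_frontal": "dap_frontal[cGy.cm2]",
    "dap_lateral": "dap_lateral[cGy.cm2]",
    "dap_fluoro": "dap_fluoro[cGy.cm2]",
    "dap_cine": "dap_cine[cGy.cm2]",
    "total_kerma_irp": "total_kerma_irp[mGy]",
    "fluoro_time": "fluoro_time[s]",
    "height": "height[cm]",
    "weight_kg": "weight[kg]",
    "age": "age[y]",
}


def load_column_map(path) -> dict:
    """Load a {source header -> canonical name} map from YAML or JSON."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def read_event_table(
    path,
    dap_dialect: str = "cGy.cm2",
    kerma_dialect: str = "mGy",
    column_map: Optional[dict] = None,
) -> pd.DataFrame:
    """Read an event table (CSV or XLSX) into canonical columns and units.

    Parameters
    ----------
    path : path-like
        CSV or XLSX file, one row per irradiation event.
    dap_dialect, kerma_dialect : str
        Units of the source's DAP / kerma columns (see :mod:`cathdose.units`).
    column_map : dict, optional
        ``{source header: canonical name}``; applied before validation.

    Returns
    -------
    DataFrame with canonical columns, row order preserved.  Missing optional
    columns are absent; missing required columns raise ``ValueError``.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing required column(s): {missing}")

    df = df.copy()
    for col in ("dap", "air_kerma_irp", "duration", "frame_count"):
        df[col] = pd.to_numeric(df[col])
        if (df[col] < 0).any():
            bad = int(df.index[df[col] < 0][0])
            raise ValueError(f"negative {col} at row {bad}")
    df["dap"] = df["dap"].map(lambda v: units.dap_to_canonical(v, dap_dialect))
    df["air_kerma_irp"] = df["air_kerma_irp"].map(
        lambda v: units.kerma_to_canonical(v, kerma_dialect))
    df["frame_count"] = df["frame_count"].astype(int)
    return df


def events_from_frame(df: pd.DataFrame) -> list[IrradiationEvent]:
    """Turn canonical event rows into validated :class:`IrradiationEvent`s."""
    events = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in GEOMETRY_COLUMNS + ("kvp", "filtration_cu"):
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = float(row[col])
        events.append(IrradiationEvent(
            procedure_id=str(row["procedure_id"]),
            plane=row["plane"],
            irradiation_type=row["irradiation_type"],
            dap=float(row["dap"]),
            air_kerma_irp=float(row["air_kerma_irp"]),
            duration=float(row["duration"]),
            frame_count=int(row["frame_count"]),
            **kwargs,
        ))
    return events


def validate_events(df: pd.DataFrame) -> tuple[pd.DataFrame, ValidationReport]:
    """Screen events; drop what cannot be analysed, flag what cannot be simulated.

    Rotational-angiography events are excluded outright (their reports lack
    the information needed for simulation); events whose values violate the
    basic invariants are excluded as ``invalid``.  Events merely lacking
    C-arm geometry stay in the table — they still count for DRL statistics —
    but are flagged ``incomplete_geometry`` so the simulation-job builder can
    skip them.
    """
    exclusions: list[tuple[int, str]] = []
    flags: list[tuple[int, str]] = []
    keep = np.ones(len(df), dtype=bool)

    for pos, (idx, row) in enumerate(df.iterrows()):
        if row["irradiation_type"] == "rotational":
            exclusions.append((idx, "rotational"))
            keep[pos] = False
            continue
        if (row["irradiation_type"] not in IRRADIATION_TYPES
                or row["plane"] not in PLANES
                or min(row["dap"], row["air_kerma_irp"],
                       row["duration"], row["frame_count"]) < 0):
            exclusions.append((idx, "invalid"))
            keep[pos] = False
            continue
        have = [c for c in GEOMETRY_COLUMNS
                if c in df.columns and pd.notna(row[c])]
        if len(have) < len(GEOMETRY_COLUMNS):
            flags.append((idx, "incomplete_geometry"))

    kept = df.loc[keep].copy()
    report = ValidationReport(
        n_events_in=len(df), n_events_kept=len(kept), exclusions=exclusions)
    report.flags = flags
    return kept, report


def canonical_procedure_type(label, vocabulary: Sequence[str] = PROCEDURE_TYPES) -> str:
    """Map a free-string label onto the configured vocabulary."""
    if label in vocabulary:
        return label
    warnings.warn(f"unknown procedure type {label!r}; mapped to 'other'",
                  stacklevel=2)
    return "other"


def aggregate_procedure(
    events: Iterable[IrradiationEvent],
    patient: PatientInfo,
    type_label: str = "other",
) -> ProcedureSummary:
    """Sum one procedure's events into a :class:`ProcedureSummary`.

    All events must share a ``procedure_id``; the fluoroscopy time is the sum
    of fluoroscopy-event durations and the frame count the sum of cinegraphy
    frames.  A procedure is *biplane* when any lateral-plane event exists.
    """
    events = list(events)
    ids = {e.procedure_id for e in events}
    if len(ids) > 1:
        raise ValueError(f"mixed procedure_ids in one aggregation: {sorted(ids)}")
    pid = ids.pop() if ids else patient.patient_id

    fluoro = [e for e in events if e.irradiation_type == "fluoroscopy"]
    cine = [e for e in events if e.irradiation_type == "cinegraphy"]
    return ProcedureSummary(
        procedure_id=pid,
        patient=patient,
        procedure_type=canonical_procedure_type(type_label),
        total_dap=sum(e.dap for e in events),
        dap_frontal=sum(e.dap for e in events if e.plane == "frontal"),
        dap_lateral=sum(e.dap for e in events if e.plane == "lateral"),
        dap_fluoro=sum(e.dap for e in fluoro),
        dap_cine=sum(e.dap for e in events if e.irradiation_type != "fluoroscopy"),
        total_kerma_irp=sum(e.air_kerma_irp for e in events),
        fluoro_time=sum(e.duration for e in fluoro),
        cine_frames=sum(e.frame_count for e in cine),
        is_biplane=any(e.plane == "lateral" for e in events),
    )


def aggregate_cohort(events: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a validated multi-procedure event table to one row per procedure.

    Patient columns (age, sex, height, weight_kg, procedure_type, patient_id)
    are taken from the first event of each procedure when present.
    """
    if len(events) == 0:
        return pd.DataFrame(columns=["procedure_id"])
    g = events.groupby("procedure_id", sort=True)
    is_fluoro = events["irradiation_type"] == "fluoroscopy"
    is_cine = events["irradiation_type"] == "cinegraphy"
    is_lat = events["plane"] == "lateral"

    out = pd.DataFrame({
        "total_dap": g["dap"].sum(),
        "dap_frontal": events.loc[~is_lat].groupby("procedure_id")["dap"].sum(),
        "dap_lateral": events.loc[is_lat].groupby("procedure_id")["dap"].sum(),
        "dap_fluoro": events.loc[is_fluoro].groupby("procedure_id")["dap"].sum(),
        "dap_cine": events.loc[~is_fluoro].groupby("procedure_id")["dap"].sum(),
        "total_kerma_irp": g["air_kerma_irp"].sum(),
        "fluoro_time": events.loc[is_fluoro].groupby("procedure_id")["duration"].sum(),
        "cine_frames": events.loc[is_cine].groupby("procedure_id")["frame_count"].sum(),
        "is_biplane": g.apply(
            lambda sub: bool((sub["plane"] == "lateral").any()),
            include_groups=False),
        "n_events": g.size(),
    })
    for col in ("dap_frontal", "dap_lateral", "dap_fluoro", "dap_cine",
                "fluoro_time", "cine_frames"):
        out[col] = out[col].fillna(0.0)
    out["cine_frames"] = out["cine_frames"].astype(int)

    for col in ("patient_id", "age", "sex", "height", "weight_kg",
                "procedure_type"):
        if col in events.columns:
            out[col] = g[col].first()
    return out.reset_index()


def write_procedure_table(summaries: pd.DataFrame, path) -> None:
    """Write the per-procedure table as CSV with units spelled in the headers."""
    summaries.rename(columns=EXPORT_HEADERS).to_csv(path, index=False)
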