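"""Diagnostic reference level (DRL) statistics.

A DRL here is the 75th percentile of a cohort's distribution of a dose
quantity — DAP itself, DAP normalized to body weight (DAP_BW), or DAP
normalized to the product of body weight and fluoroscopy time (DAP_BWxFT).
Tables can be built per procedure type, per weight group (the paediatric
weight bands of the European guidance: <5, 5-<15, 15-<30, 30-<50, 50-<80,
>=80 kg) or pooled; groups with fewer than 20 procedures are flagged as
small samples.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .records import ProcedureSummary

WEIGHT_EDGES = (0.0, 5.0, 15.0, 30.0, 50.0, 80.0, math.inf)
WEIGHT_LABELS = ("<5", "5-<15", "15-<30", "30-<50", "50-<80", ">=80")

#: quantities summarized in DRL tables (canonical column -> report label)
DRL_QUANTITIES = {
    "total_dap": "DAP[cGy.cm2]",
    "total_kerma_irp": "Kerma[mGy]",
    "fluoro_time": "FT[s]",
    "cine_frames": "Frames",
    "dap_bw": "DAP_BW[cGy.cm2/kg]",
    "dap_bwxft": "DAP_BWxFT[cGy.cm2/kg/min]",
}

SMALL_SAMPLE_N = 20   # "at least 20 cases per procedure type" guidance


@dataclass(frozen=True)
class NormalizedDose:
    """Weight- (and time-) normalized DAP of one procedure."""

    dap_bw: float                    # cGy·cm²/kg
    dap_bwxft: Optional[float]       # cGy·cm²/kg/min; None when FT = 0


@dataclass
class AlertResult:
    """Outcome of comparing one procedure against a DRL table."""

    procedure_id: str
    parameter: str
    value: float
    threshold: float
    exceeded: bool
    causes: list = field(default_factory=list)   # secondary parameters above P75


def normalize(summary: Union[ProcedureSummary, dict]) -> NormalizedDose:
    """DAP_BW and DAP_BWxFT of one procedure.

    DAP_BW = total DAP / body weight (cGy·cm²/kg); DAP_BWxFT additionally
    divides by the fluoroscopy time in minutes and is undefined (None) for
    cine-only procedures with zero fluoroscopy time.
    """
    if isinstance(summary, ProcedureSummary):
        dap, weight, ft = summary.total_dap, summary.patient.weight_kg, summary.fluoro_time
    else:
        dap, weight, ft = summary["total_dap"], summary["weight_kg"], summary["fluoro_time"]
    if weight <= 0:
        raise ValueError("weight must be > 0 to normalize DAP")
    dap_bw = dap / weight
    dap_bwxft = dap / (weight * ft / 60.0) if ft > 0 else None
    return NormalizedDose(dap_bw=dap_bw, dap_bwxft=dap_bwxft)


def add_normalized(summaries: pd.DataFrame) -> pd.DataFrame:
    """Append dap_bw / dap_bwxft / weight_group columns to a cohort table."""
    df = summaries.copy()
    df["dap_bw"] = df["total_dap"] / df["weight_kg"]
    ft_min = df["fluoro_time"] / 60.0
    df["dap_bwxft"] = np.where(
        df["fluoro_time"] > 0,
        df["total_dap"] / (df["weight_kg"] * ft_min.replace(0, np.nan)),
        np.nan,
    )
    df["weight_group"] = df["weight_kg"].map(weight_group)
    return df


def weight_group(weight_kg: float) -> str:
    """Half-open weight banding: 15.0 kg falls in '15-<30'."""
    if weight_kg <= 0 or not math.isfinite(weight_kg):
        raise ValueError("weight must be positive and finite")
    for lo, hi, label in zip(WEIGHT_EDGES[:-1], WEIGHT_EDGES[1:], WEIGHT_LABELS):
        if lo <= weight_kg < hi:
            return label
    return WEIGHT_LABELS[-1]


def percentile(values: Sequence[float], p: float, method: str = "linear") -> float:
    """Percentile by linear interpolation between order statistics.

    The default places the p-quantile at rank h = (n-1)p + 1 and
    interpolates linearly — the usual statistics-package convention.  The
    method tag is recorded in every emitted table because P75 values at
    small n shift between conventions.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("percentile of an empty list is undefined")
    return float(np.quantile(arr, p, method=method))


def _stratum(df: pd.DataFrame) -> pd.Series:
    return np.where(df["procedure_type"] == "Diagnostic",
                    "Diagnostic", "Interventional")


def build_drl_table(
    summaries: pd.DataFrame,
    grouping: str = "pooled",
    percentile_method: str = "linear",
) -> pd.DataFrame:
    """P25/median/P75 DRL table for each group of a cohort.

    Parameters
    ----------
    summaries : DataFrame
        Per-procedure cohort table (``add_normalized`` is applied if needed).
    grouping : {"pooled", "by_procedure_type", "by_weight_group"}
    percentile_method : str
        numpy quantile method; recorded in the output.

    Returns a long-format table with one row per (group, quantity), columns
    ``group, quantity, n, p25, median, p75, small_sample, method``.  The
    DAP_BWxFT rows use only procedures with nonzero fluoroscopy time.
    """
    if len(summaries) == 0:
        raise ValueError("empty cohort")
    df = summaries if "dap_bw" in summaries.columns else add_normalized(summaries)

    if grouping == "pooled":
        keys = pd.Series(["All"] * len(df), index=df.index)
    elif grouping == "by_procedure_type":
        keys = df["procedure_type"]
    elif grouping == "by_weight_group":
        keys = df["weight_group"]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rows = []
    for group, sub in df.groupby(keys, sort=True):
        for col, label in DRL_QUANTITIES.items():
            if col not in sub.columns:
                continue
            vals = sub[col].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            rows.append({
                "group": group,
                "quantity": label,
                "n": int(vals.size),
                "p25": percentile(vals, 0.25, percentile_method),
                "median": percentile(vals, 0.50, percentile_method),
                "p75": percentile(vals, 0.75, percentile_method),
                "small_sample": vals.size < SMALL_SAMPLE_N,
                "method": percentile_method,
            })
    return pd.DataFrame(rows)


def summarize_cohort(summaries: pd.DataFrame) -> pd.DataFrame:
    """Cohort descriptive statistics per stratum (Diagnostic / Interventional / All).

    Reports the median per-procedure fluoroscopy share of total DAP, the
    biplane usage fraction, and the min/max of DAP and DAP_BW.
    """
    df = summaries if "dap_bw" in summaries.columns else add_normalized(summaries)
    df = df.assign(_stratum=_stratum(df))
    frac = df["dap_fluoro"] / df["total_dap"].replace(0, np.nan)
    df = df.assign(_fluoro_frac=frac)

    def one(sub, name):
        return {
            "stratum": name,
            "n": len(sub),
            "median_fluoro_dap_fraction": float(sub["_fluoro_frac"].median()),
            "biplane_fraction": float(sub["is_biplane"].mean()),
            "dap_min": float(sub["total_dap"].min()),
            "dap_max": float(sub["total_dap"].max()),
            "dap_bw_min": float(sub["dap_bw"].min()),
            "dap_bw_max": float(sub["dap_bw"].max()),
        }

    rows = [one(df, "All")]
    for name, sub in df.groupby("_stratum", sort=True):
        rows.append(one(sub, name))
    return pd.DataFrame(rows)


def check_alert(
    summary: Union[ProcedureSummary, dict, pd.Series],
    table: pd.DataFrame,
    primary: str = "dap_bwxft",
    group: Optional[str] = None,
) -> AlertResult:
    """Compare one procedure's primary DRL parameter against a DRL table.

    Exceedance is strict (a value equal to the DRL does not alert).  When
    the primary parameter is DAP_BWxFT but the procedure has no fluoroscopy
    time, the comparison falls back to DAP_BW.  Secondary parameters
    (fluoroscopy time, frame count, kerma) above their own P75 are listed as
    candidate causes.
    """
    if isinstance(summary, ProcedureSummary):
        row = summary.to_row()
    elif isinstance(summary, pd.Series):
        row = summary.to_dict()
    else:
        row = dict(summary)
    norm = normalize(row)
    row.setdefault("dap_bw", norm.dap_bw)
    row.setdefault("dap_bwxft", norm.dap_bwxft)

    parameter = primary
    if parameter == "dap_bwxft" and (row["dap_bwxft"] is None
                                     or (isinstance(row["dap_bwxft"], float)
                                         and math.isnan(row["dap_bwxft"]))):
        parameter = "dap_bw"

    def threshold_for(quantity_col: str) -> Optional[float]:
        label = DRL_QUANTITIES[quantity_col]
        cand = table[table["quantity"] == label]
        if group is not None and (cand["group"] == group).any():
            cand = cand[cand["group"] == group]
        elif (cand["group"] == "All").any():
            cand = cand[cand["group"] == "All"]
        elif group is not None:
            raise KeyError(f"group {group!r} not in table and no pooled row")
        if len(cand) == 0:
            return None
        return float(cand["p75"].iloc[0])

    thr = threshold_for(parameter)
    if thr is None:
        raise KeyError(f"DRL table has no row for {parameter!r}")
    value = float(row[parameter])
    exceeded = value > thr

    causes = []
    for col, cause in (("fluoro_time", "fluoro_time>P75"),
                       ("cine_frames", "frames>P75"),
                       ("total_kerma_irp", "kerma>P75")):
        t = threshold_for(col)
        if t is not None and float(row.get(col, 0.0)) > t:
            causes.append(cause)

    return AlertResult(
        procedure_id=str(row.get("procedure_id", "?")),
        parameter=parameter, value=value, threshold=thr,
        exceeded=exceeded, causes=causes if exceeded else [],
    )
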