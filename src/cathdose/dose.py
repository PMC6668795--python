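"""Conversion-factor organ/effective dose engine.

Organ doses (mGy) and effective doses (mSv) are estimated from
weight-normalized DAP via regression-slope conversion factors:

    dose = CF(target, weight group, plane) x DAP_BW     [DAP_BW in Gy·cm²/kg]

The shipped default table carries the published slopes per weight band and
per C-arm plane (frontal, lateral, and a combined total/biplane factor for
systems that report a single cumulative DAP).  New tables can be derived
from any cohort that carries reference doses, e.g. Monte Carlo output or
the synthetic generator's ground truth.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .drl import WEIGHT_LABELS, weight_group
from .records import ProcedureSummary
from .stats import fit_linear

PLANE_ALIASES = {"total": "total", "biplane": "total",
                 "frontal": "frontal", "lateral": "lateral"}

#: ICRP tissue weighting factors, keyed by the organ names used here.
TISSUE_WEIGHTS = {
    "ICRP103": {
        "active bone marrow": 0.12, "colon": 0.12, "lungs": 0.12,
        "stomach": 0.12, "breasts": 0.12, "remainder": 0.12,
        "gonads": 0.08,
        "urinary bladder": 0.04, "oesophagus": 0.04, "liver": 0.04,
        "thyroid": 0.04,
        "bone surface": 0.01, "brain": 0.01, "salivary glands": 0.01,
        "skin": 0.01,
    },
    "ICRP60": {
        "gonads": 0.20,
        "active bone marrow": 0.12, "colon": 0.12, "lungs": 0.12,
        "stomach": 0.12,
        "urinary bladder": 0.05, "breasts": 0.05, "liver": 0.05,
        "oesophagus": 0.05, "thyroid": 0.05, "remainder": 0.05,
        "skin": 0.01, "bone surface": 0.01,
    },
}

#: organ-name aliases mapping dose targets onto weighting-scheme tissues
ORGAN_TO_TISSUE = {"ovaries": "gonads",
                   "remainder male": "remainder",
                   "remainder female": "remainder"}


@dataclass(frozen=True)
class EffectiveDoseResult:
    ed: float                 # mSv
    weighting: str            # ICRP103 | ICRP60
    provenance: str           # cf_total | cf_per_plane | from_organ_doses


class ConversionFactorTable:
    """Slope table mapping DAP_BW to organ dose (mGy) or effective dose (mSv).

    Rows are keyed by (target, plane, weight_group); ``plane`` is canonical
    ``total`` (= biplane), ``frontal`` or ``lateral``; ``weight_group`` is a
    weight band label or ``"All"``.  ED rows also carry the weighting scheme.
    """

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        df["plane"] = df["plane"].map(
            lambda p: PLANE_ALIASES.get(str(p).lower()))
        if df["plane"].isna().any():
            raise ValueError("unknown plane name in conversion-factor table")
        if (pd.to_numeric(df["slope"]) <= 0).any():
            raise ValueError("conversion-factor slopes must be positive")
        df["weighting"] = df.get("weighting", "").fillna("")
        self.frame = df
        # dict index: (target, plane, group, weighting) -> slope
        self._index = {
            (t, p, g, w): float(s)
            for t, p, g, w, s in zip(df["target"], df["plane"],
                                     df["weight_group"], df["weighting"],
                                     df["slope"])
        }

    @classmethod
    def default(cls) -> "ConversionFactorTable":
        """The table shipped with the package."""
        with resources.files("cathdose.data").joinpath(
                "conversion_factors.csv").open() as fh:
            return cls(pd.read_csv(fh, keep_default_na=False,
                                   na_values=[""]))

    @classmethod
    def from_csv(cls, path) -> "ConversionFactorTable":
        return cls(pd.read_csv(Path(path), keep_default_na=False,
                               na_values=[""]))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def organs(self) -> list[str]:
        return sorted(set(self.frame["target"]) - {"ED"})

    def lookup(
        self,
        target: str,
        weight_kg: Optional[float] = None,
        plane: str = "total",
        weighting: str = "ICRP103",
        group: Optional[str] = None,
    ) -> float:
        """Slope for a target/plane, selected by patient weight.

        Either ``weight_kg`` (mapped through the weight bands) or an explicit
        ``group`` (including ``"All"``) must be given; the pooled ``All`` row
        is used only on explicit request.
        """
        if group is None:
            if weight_kg is None:
                raise ValueError("give either weight_kg or group")
            group = weight_group(weight_kg)
        plane_c = PLANE_ALIASES.get(plane.lower())
        key = (target, plane_c, group, weighting if target == "ED" else "")
        try:
            return self._index[key]
        except KeyError:
            avail = sorted({(t, p) for t, p, _, _ in self._index})
            raise KeyError(
                f"no conversion factor for (target={target!r}, plane={plane!r}, "
                f"group={group!r}); available (target, plane) keys: {avail}"
            ) from None


def _row(summary: Union[ProcedureSummary, dict, pd.Series]) -> dict:
    if isinstance(summary, ProcedureSummary):
        return summary.to_row()
    if isinstance(summary, pd.Series):
        return summary.to_dict()
    return dict(summary)


def _dap_bw_gy(row: dict, which: str) -> float:
    """Plane DAP normalized to weight, on the Gy·cm²/kg scale CFs expect."""
    w = row["weight_kg"]
    if w <= 0:
        raise ValueError("weight must be > 0")
    return row[which] / w / 100.0   # cGy·cm² -> Gy·cm²


def estimate_organ_doses(
    summary,
    table: Optional[ConversionFactorTable] = None,
    mode: str = "total",
    organs: Optional[list[str]] = None,
) -> dict[str, float]:
    """Per-organ dose (mGy) of one procedure from its DAP.

    ``mode="total"`` applies the combined biplane factor to the cumulative
    DAP; ``mode="per_plane"`` applies the frontal and lateral factors to the
    per-plane DAP shares and sums them (the more accurate option on a
    biplane system).
    """
    table = table or ConversionFactorTable.default()
    row = _row(summary)
    organs = organs if organs is not None else table.organs
    out = {}
    for organ in organs:
        if mode == "total":
            cf = table.lookup(organ, row["weight_kg"], plane="total")
            out[organ] = cf * _dap_bw_gy(row, "total_dap")
        elif mode == "per_plane":
            cf_f = table.lookup(organ, row["weight_kg"], plane="frontal")
            cf_l = table.lookup(organ, row["weight_kg"], plane="lateral")
            out[organ] = (cf_f * _dap_bw_gy(row, "dap_frontal")
                          + cf_l * _dap_bw_gy(row, "dap_lateral"))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def estimate_effective_dose(
    summary,
    table: Optional[ConversionFactorTable] = None,
    mode: str = "total",
    weighting: str = "ICRP103",
) -> EffectiveDoseResult:
    """Effective dose (mSv) of one procedure via the ED conversion factor."""
    table = table or ConversionFactorTable.default()
    row = _row(summary)
    if mode == "total":
        cf = table.lookup("ED", row["weight_kg"], plane="total",
                          weighting=weighting)
        ed = cf * _dap_bw_gy(row, "total_dap")
        prov = "cf_total"
    elif mode == "per_plane":
        cf_f = table.lookup("ED", row["weight_kg"], plane="frontal",
                            weighting=weighting)
        cf_l = table.lookup("ED", row["weight_kg"], plane="lateral",
                            weighting=weighting)
        ed = (cf_f * _dap_bw_gy(row, "dap_frontal")
              + cf_l * _dap_bw_gy(row, "dap_lateral"))
        prov = "cf_per_plane"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return EffectiveDoseResult(ed=ed, weighting=weighting, provenance=prov)


def effective_dose_from_organ_doses(
    organ_doses: dict[str, float],
    weighting: Union[str, dict] = "ICRP103",
) -> EffectiveDoseResult:
    """Tissue-weighted sum ED = sum_T w_T H_T (mSv, doses in mGy).

    Tissues absent from ``organ_doses`` count as zero (with a warning);
    organ names are aliased onto weighting-scheme tissues (ovaries->gonads,
    sex-specific remainder->remainder).  The weights must sum to one.
    """
    if isinstance(weighting, str):
        name, weights = weighting, TISSUE_WEIGHTS[weighting]
    else:
        name, weights = "custom", dict(weighting)
    if not math.isclose(sum(weights.values()), 1.0, abs_tol=1e-9):
        raise ValueError("tissue weights must sum to 1")

    doses: dict[str, float] = {}
    for organ, d in organ_doses.items():
        tissue = ORGAN_TO_TISSUE.get(organ, organ)
        if tissue in weights:
            doses[tissue] = doses.get(tissue, 0.0) + float(d)
    missing = sorted(set(weights) - set(doses))
    if missing:
        warnings.warn(f"tissues with no dose, treated as 0: {missing}",
                      stacklevel=2)
    ed = sum(weights[t] * doses.get(t, 0.0) for t in weights)
    return EffectiveDoseResult(ed=ed, weighting=name,
                               provenance="from_organ_doses")


def ref_column(target: str) -> str:
    """Reference-dose column name for a target ('ED' -> 'ed', organs 'od_*')."""
    if target == "ED":
        return "ed"
    return "od_" + target.replace(" ", "_")


def derive_cf_table(
    cohort: pd.DataFrame,
    targets: Optional[list[str]] = None,
    plane: str = "total",
    weighting: str = "ICRP103",
    through_origin: bool = False,
) -> ConversionFactorTable:
    """Fit conversion factors from a dose-labelled cohort.

    For every target and weight band (plus pooled ``All``), regresses the
    reference dose column (``od_<organ>`` or ``ed``) on the matching plane's
    DAP_BW (Gy·cm²/kg) and stores slope, 95% CI and n.  The fit is
    variance-weighted (weights 1/x²) because dose scatter about the
    conversion line is multiplicative, so the response variance grows with
    DAP_BW; an unweighted slope would be dominated by the few highest-dose
    procedures and its interval would be unreliable.  Lateral fits use only
    procedures with nonzero lateral DAP; bands with fewer than 3 procedures
    are left out.
    """
    plane_c = PLANE_ALIASES.get(plane.lower())
    if plane_c is None:
        raise ValueError(f"unknown plane {plane!r}")
    df = cohort.copy()
    dap_col = {"total": "total_dap", "frontal": "dap_frontal",
               "lateral": "dap_lateral"}[plane_c]
    df = df[df[dap_col] > 0]   # zero-DAP rows carry no slope information
    x_all = (df[dap_col] / df["weight_kg"] / 100.0).to_numpy(dtype=float)
    groups = df["weight_kg"].map(weight_group)

    if targets is None:
        targets = [c.removeprefix("od_").replace("_", " ")
                   for c in df.columns if c.startswith("od_")]
        if "ed" in df.columns:
            targets.append("ED")

    rows = []
    for target in targets:
        col = ref_column(target)
        if col not in df.columns:
            raise KeyError(f"cohort lacks reference column {col!r}")
        y_all = df[col].to_numpy(dtype=float)
        for label in list(WEIGHT_LABELS) + ["All"]:
            mask = np.ones(len(df), bool) if label == "All" \
                else (groups == label).to_numpy()
            if mask.sum() < 3 or np.ptp(x_all[mask]) == 0:
                continue
            fit = fit_linear(x_all[mask], y_all[mask],
                             through_origin=through_origin,
                             weights=1.0 / x_all[mask] ** 2)
            rows.append({
                "target": target, "plane": plane_c, "weight_group": label,
                "weighting": weighting if target == "ED" else "",
                "slope": fit.slope, "ci_low": fit.slope_ci_low,
                "ci_high": fit.slope_ci_high, "n": fit.n,
            })
    columns = ["target", "plane", "weight_group", "weighting",
               "slope", "ci_low", "ci_high", "n"]
    return ConversionFactorTable(pd.DataFrame(rows, columns=columns))
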