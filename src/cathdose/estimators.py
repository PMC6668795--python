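"""scikit-learn-style estimators over the DRL and dose-conversion core.

These wrap the module-level functions so the statistical steps compose with
sklearn pipelines and model selection:

* :class:`DRLEstimator` — ``fit`` learns P75 reference levels from a cohort,
  ``predict`` flags procedures exceeding them.
* :class:`ConversionFactorRegressor` — ``fit`` derives conversion-factor
  slopes from a dose-labelled cohort, ``predict`` estimates doses.
* :class:`CFDoseEstimator` — applies a fixed (published or previously
  fitted) conversion-factor table; ``fit`` only validates.

All take a per-procedure cohort ``DataFrame`` as ``X``.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import dose as dose_mod
from . import drl as drl_mod
from .dose import ConversionFactorTable


def _check_cohort(X, columns=("total_dap", "weight_kg")) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a per-procedure cohort DataFrame")
    missing = [c for c in columns if c not in X.columns]
    if missing:
        raise ValueError(f"cohort missing column(s): {missing}")
    if len(X) == 0:
        raise ValueError("empty cohort")
    return X


class DRLEstimator(BaseEstimator):
    """Learn 75th-percentile reference levels and flag exceedances.

    Parameters
    ----------
    grouping : {"pooled", "by_procedure_type", "by_weight_group"}
        How the DRL table is stratified.
    primary : {"dap_bwxft", "dap_bw"}
        Primary DRL parameter compared on ``predict`` (DAP_BWxFT falls back
        to DAP_BW for cine-only procedures).
    percentile_method : str
        numpy quantile convention; recorded in the fitted table.

    Attributes
    ----------
    table_ : DataFrame
        Long-format DRL table (group, quantity, n, p25, median, p75).
    cohort_stats_ : DataFrame
        Fluoroscopy-DAP-fraction and biplane-usage summaries per stratum.
    """

    def __init__(self, grouping: str = "pooled", primary: str = "dap_bwxft",
                 percentile_method: str = "linear"):
        self.grouping = grouping
        self.primary = primary
        self.percentile_method = percentile_method

    def fit(self, X, y=None):
        X = _check_cohort(X, ("total_dap", "weight_kg", "fluoro_time",
                              "procedure_type"))
        df = drl_mod.add_normalized(X)
        self.table_ = drl_mod.build_drl_table(
            df, grouping=self.grouping,
            percentile_method=self.percentile_method)
        self.cohort_stats_ = drl_mod.summarize_cohort(df)
        self.n_features_in_ = X.shape[1]
        return self

    def _group_of(self, row) -> Optional[str]:
        if self.grouping == "by_procedure_type":
            return row["procedure_type"]
        if self.grouping == "by_weight_group":
            return drl_mod.weight_group(row["weight_kg"])
        return None

    def alerts(self, X) -> list:
        """Detailed :class:`~cathdose.drl.AlertResult` per procedure."""
        check_is_fitted(self, "table_")
        X = _check_cohort(X, ("total_dap", "weight_kg", "fluoro_time"))
        df = drl_mod.add_normalized(X)
        return [
            drl_mod.check_alert(row, self.table_, primary=self.primary,
                                group=self._group_of(row))
            for _, row in df.iterrows()
        ]

    def predict(self, X) -> np.ndarray:
        """Boolean array: does each procedure exceed its reference level."""
        return np.array([a.exceeded for a in self.alerts(X)], dtype=bool)


class ConversionFactorRegressor(BaseEstimator, RegressorMixin):
    """Derive DAP_BW-to-dose conversion factors by weight-group regression.

    ``fit(X)`` expects a cohort with reference dose columns (``od_<organ>``
    / ``ed``); the fitted ``cf_table_`` holds a slope with 95% CI per
    (target, weight band).  ``predict(X)`` returns the dose for
    ``predict_target`` via the fitted slopes.
    """

    def __init__(self, targets=None, plane: str = "total",
                 through_origin: bool = False, predict_target: str = "ED"):
        self.targets = targets
        self.plane = plane
        self.through_origin = through_origin
        self.predict_target = predict_target

    def fit(self, X, y=None):
        X = _check_cohort(X)
        self.cf_table_ = dose_mod.derive_cf_table(
            X, targets=self.targets, plane=self.plane,
            through_origin=self.through_origin)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "cf_table_")
        X = _check_cohort(X)
        mode = "total" if self.plane in ("total", "biplane") else self.plane
        out = []
        for _, row in X.iterrows():
            if self.predict_target == "ED":
                # frontal/lateral tables carry a single-plane ED slope
                cf = self.cf_table_.lookup("ED", row["weight_kg"],
                                           plane=self.plane)
                dap_col = {"total": "total_dap", "frontal": "dap_frontal",
                           "lateral": "dap_lateral"}[mode]
                out.append(cf * row[dap_col] / row["weight_kg"] / 100.0)
            else:
                cf = self.cf_table_.lookup(self.predict_target,
                                           row["weight_kg"], plane=self.plane)
                dap_col = {"total": "total_dap", "frontal": "dap_frontal",
                           "lateral": "dap_lateral"}[mode]
                out.append(cf * row[dap_col] / row["weight_kg"] / 100.0)
        return np.asarray(out, dtype=float)


class CFDoseEstimator(BaseEstimator):
    """Apply a fixed conversion-factor table to a cohort.

    ``predict`` returns effective doses (mSv); :meth:`organ_doses` the
    per-organ doses (mGy).  With ``cf_table=None`` the packaged published
    table is used.
    """

    def __init__(self, cf_table: Optional[ConversionFactorTable] = None,
                 mode: str = "total", weighting: str = "ICRP103"):
        self.cf_table = cf_table
        self.mode = mode
        self.weighting = weighting

    def fit(self, X=None, y=None):
        self.table_ = self.cf_table or ConversionFactorTable.default()
        if X is not None:
            self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "table_")
        X = _check_cohort(X)
        return np.array([
            dose_mod.estimate_effective_dose(
                row, table=self.table_, mode=self.mode,
                weighting=self.weighting).ed
            for _, row in X.iterrows()
        ])

    def organ_doses(self, X) -> pd.DataFrame:
        check_is_fitted(self, "table_")
        X = _check_cohort(X)
        rows = [dose_mod.estimate_organ_doses(row, table=self.table_,
                                              mode=self.mode)
                for _, row in X.iterrows()]
        out = pd.DataFrame(rows)
        if "procedure_id" in X.columns:
            out.insert(0, "procedure_id", X["procedure_id"].to_numpy())
        return out
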