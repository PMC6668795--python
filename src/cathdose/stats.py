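"""Nonparametric group comparison, regression and dispersion diagnostics.

The validation suite behind the DRL-parameter choice: a Kruskal-Wallis H
test across procedure types, Dunn's rank-based pairwise post-hoc with
Bonferroni correction, ordinary least squares with slope confidence
intervals (how conversion factors are derived), and the CI95/med bootstrap
dispersion diagnostic of a distribution's median.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm


@dataclass
class ComparisonResult:
    h_statistic: float
    p_value: float
    pairwise: list = field(default_factory=list)
    # pairwise entries: (label_a, label_b, z, adjusted_p, significant)
    n_significant: int = 0
    n_pairs: int = 0
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairwise,
            columns=["group_a", "group_b", "z", "p_adjusted", "significant"])


@dataclass
class RegressionResult:
    slope: float
    intercept: Optional[float]
    r_squared: float
    slope_ci_low: float
    slope_ci_high: float
    n: int
    through_origin: bool = False


@dataclass
class DispersionDiagnostic:
    ci95_over_median: float   # percent
    ci_low: float
    ci_high: float
    median: float
    n: int
    replicates: int
    seed: int


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def dunn_pairwise(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Dunn's rank-based pairwise comparisons with Bonferroni correction.

    z for a pair is the mean-rank difference over its standard error with
    tie-corrected variance ``(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)``
    where ``T = sum(t^3 - t)`` over tie groups of the pooled sample.  Raw
    two-sided normal p-values are multiplied by the number of pairs
    (clipped at 1).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    k = len(arrays)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]

    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [a.size for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(k)]

    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    tie_term = tie_sum / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    h, p = kruskal_wallis(arrays)
    pairs = list(combinations(range(k), 2))
    pairwise = []
    n_sig = 0
    for i, j in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        raw = 2.0 * sps.norm.sf(abs(z))
        adj = min(1.0, raw * len(pairs))
        sig = adj < alpha
        n_sig += int(sig)
        pairwise.append((labels[i], labels[j], float(z), float(adj), bool(sig)))

    return ComparisonResult(
        h_statistic=h, p_value=p, pairwise=pairwise,
        n_significant=n_sig, n_pairs=len(pairs), alpha=alpha)


def fit_linear(
    x: Sequence[float],
    y: Sequence[float],
    through_origin: bool = False,
    weights: Optional[Sequence[float]] = None,
) -> RegressionResult:
    """Least-squares fit of y on x with the 95% t-interval of the slope.

    Conversion factors are the slope of this fit; the intercept is reported
    but not used downstream, and a through-origin mode exists because the
    conversion-factor usage ``dose = CF * DAP_BW`` implies a zero intercept.
    Optional ``weights`` give a variance-weighted (WLS) fit for
    heteroscedastic responses such as doses with multiplicative error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")

    design = x[:, None] if through_origin else sm.add_constant(x)
    if weights is None:
        fit = sm.OLS(y, design).fit()
    else:
        fit = sm.WLS(y, design, weights=np.asarray(weights, float)).fit()
    slope_idx = 0 if through_origin else 1
    ci = fit.conf_int(alpha=0.05)
    r2 = float(fit.rsquared)
    return RegressionResult(
        slope=float(fit.params[slope_idx]),
        intercept=None if through_origin else float(fit.params[0]),
        r_squared=min(max(r2, 0.0), 1.0),
        slope_ci_low=float(ci[slope_idx][0]),
        slope_ci_high=float(ci[slope_idx][1]),
        n=int(x.size),
        through_origin=through_origin,
    )


def ci95_over_median(
    values: Sequence[float],
    replicates: int = 2000,
    seed: int = 0,
) -> DispersionDiagnostic:
    """Bootstrap 95% CI of the median, expressed as a percentage of the median.

    The width of the percentile-bootstrap interval divided by the sample
    median, times 100 — a sample-size diagnostic for DRL parameters (narrow
    is better).  Deterministic given ``seed``.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 8:
        raise ValueError("need at least 8 values for a meaningful bootstrap")
    med = float(np.median(arr))
    if med == 0:
        raise ValueError("median is zero; CI95/med undefined")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(replicates, arr.size))
    meds = np.median(arr[idx], axis=1)
    lo, hi = np.percentile(meds, [2.5, 97.5])
    return DispersionDiagnostic(
        ci95_over_median=float((hi - lo) / abs(med) * 100.0),
        ci_low=float(lo), ci_high=float(hi), median=med,
        n=int(arr.size), replicates=int(replicates), seed=int(seed))
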