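"""Seeded synthetic cohorts with the structure the analysis assumes.

The generator emulates a paediatric catheterization case stream: a
procedure-type mix weighted like a real single-centre cohort, a heavily
right-skewed age distribution (median ~4.3 y, preterm newborns to adults),
size from simple parametric growth anchors, and a multiplicative DAP model

    DAP = k_type x BW x FT x exp(eps),   eps ~ N(0, sigma^2)

which makes DAP_BWxFT log-normal around k_type — the linear
DAP ~ BW x FT relationship (with log-normal scatter) that motivates
time-and-weight-normalized DRL parameters.  Ground-truth organ/effective
doses are produced from conversion-factor slopes so parameter-recovery
tests have a known answer.  Everything is deterministic given the seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd

from .dose import ConversionFactorTable, ref_column
from .drl import weight_group

#: procedure-type mix weights (single-centre cohort proportions)
DEFAULT_MIX = {
    "Diagnostic": 33, "ASD closure": 33, "PFO closure": 17,
    "PDA closure": 18, "Single Balloon Valvuloplasty": 43,
    "Single Balloon Angioplasty": 34, "Multi Balloon Dilatation": 13,
    "Pulmonary Valve Replacement": 7, "Stenting": 14,
}

#: per-type fluoroscopy-time medians (s) and cine-frame medians
FT_MEDIAN_S = {
    "Diagnostic": 481, "ASD closure": 254, "PFO closure": 243,
    "PDA closure": 358.5, "Single Balloon Valvuloplasty": 490,
    "Single Balloon Angioplasty": 486.5, "Multi Balloon Dilatation": 1142,
    "Pulmonary Valve Replacement": 2055, "Stenting": 1642,
}
FRAMES_MEDIAN = {
    "Diagnostic": 456, "ASD closure": 0, "PFO closure": 0,
    "PDA closure": 172, "Single Balloon Valvuloplasty": 216,
    "Single Balloon Angioplasty": 324, "Multi Balloon Dilatation": 452,
    "Pulmonary Valve Replacement": 1274, "Stenting": 1052,
}

#: median DAP_BWxFT (cGy·cm²/kg/min) per type, back-solved so the pooled P75
#: of the log-normal lands near the ~2 cGy·cm²/kg/min scale of biplane
#: paediatric practice: median = P75_target / exp(0.6745 * sigma)
_P75_TARGET = {
    "Diagnostic": 3.59, "ASD closure": 1.48, "PFO closure": 1.45,
    "PDA closure": 1.33, "Single Balloon Valvuloplasty": 1.53,
    "Single Balloon Angioplasty": 2.01, "Multi Balloon Dilatation": 1.91,
    "Pulmonary Valve Replacement": 3.50, "Stenting": 3.21,
}
DEFAULT_SIGMA = 0.8
DEFAULT_K_TYPE = {t: p / math.exp(0.6745 * DEFAULT_SIGMA)
                  for t, p in _P75_TARGET.items()}

#: growth anchors (age y -> kg, cm); log-linear interpolation between them
WEIGHT_ANCHORS = ((0.0, 3.4), (1.0, 9.2), (5.0, 19.0), (10.0, 32.4),
                  (15.0, 56.3), (20.0, 70.0), (70.0, 75.0))
HEIGHT_ANCHORS = ((0.0, 51.0), (1.0, 75.0), (5.0, 109.0), (10.0, 140.0),
                  (15.0, 168.0), (20.0, 175.0), (70.0, 175.0))


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort; defaults are the study conditions."""

    n_procedures: int = 222
    seed: int = 0
    procedure_mix: dict = dc_field(default_factory=lambda: dict(DEFAULT_MIX))
    age_median: float = 4.3
    age_sigma: float = 2.0
    age_range: tuple = (0.005, 70.0)
    weight_noise_sd: float = 0.15
    height_noise_sd: float = 0.04
    ft_sigma: float = 0.7
    dap_sigma: float = DEFAULT_SIGMA
    k_type: dict = dc_field(default_factory=lambda: dict(DEFAULT_K_TYPE))
    fluoro_frac: dict = dc_field(
        default_factory=lambda: {"Diagnostic": 0.77, "Interventional": 0.91})
    fluoro_frac_concentration: float = 15.0
    biplane_p: dict = dc_field(
        default_factory=lambda: {"Diagnostic": 0.85, "Interventional": 0.73})
    lateral_share_mean: float = 0.35
    lateral_share_concentration: float = 10.0
    events_per_procedure_mean: float = 63.0
    field_area_median_cm2: float = 60.0
    field_area_sigma: float = 0.4

    def validate(self) -> None:
        if self.n_procedures < 1:
            raise ValueError("n_procedures must be >= 1")
        if any(w < 0 for w in self.procedure_mix.values()) \
                or sum(self.procedure_mix.values()) <= 0:
            raise ValueError("procedure_mix weights must be >= 0, sum > 0")
        for name in ("age_median", "events_per_procedure_mean",
                     "field_area_median_cm2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("age_sigma", "dap_sigma", "ft_sigma",
                     "weight_noise_sd", "height_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(k <= 0 for k in self.k_type.values()):
            raise ValueError("k_type scales must be > 0")
        missing = set(self.procedure_mix) - set(self.k_type)
        if missing:
            raise ValueError(f"k_type missing for types: {sorted(missing)}")


@dataclass
class GroundTruth:
    """Generator parameters plus pre-noise reference doses per plane."""

    params: dict
    doses: dict   # plane -> DataFrame (od_*/ed columns, index procedure_id)


def _log_interp(age: np.ndarray, anchors) -> np.ndarray:
    xs = np.array([a for a, _ in anchors])
    ys = np.log([v for _, v in anchors])
    return np.exp(np.interp(age, xs, ys))


def _true_doses(summaries: pd.DataFrame, cf_table: ConversionFactorTable,
                plane: str) -> pd.DataFrame:
    dap_col = {"total": "total_dap", "frontal": "dap_frontal",
               "lateral": "dap_lateral"}[plane]
    x = (summaries[dap_col] / summaries["weight_kg"] / 100.0).to_numpy()
    groups = summaries["weight_kg"].map(weight_group)
    out = pd.DataFrame(index=summaries["procedure_id"])
    for target in cf_table.organs + ["ED"]:
        by_group = {g: cf_table.lookup(target, group=g, plane=plane)
                    for g in groups.unique()}
        out[ref_column(target)] = groups.map(by_group).to_numpy() * x
    return out


def generate_summaries(
    config: Optional[CohortConfig] = None,
    cf_table: Optional[ConversionFactorTable] = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a per-procedure cohort table plus its dose ground truth.

    Fast path for statistical tests that do not need per-event streams;
    :func:`generate_cohort` expands the same summaries into events.
    """
    config = config or CohortConfig()
    config.validate()
    cf_table = cf_table or ConversionFactorTable.default()
    rng = np.random.default_rng(config.seed)
    n = config.n_procedures

    labels = sorted(config.procedure_mix)
    weights = np.array([config.procedure_mix[l] for l in labels], dtype=float)
    ptype = rng.choice(labels, size=n, p=weights / weights.sum())
    stratum = np.where(ptype == "Diagnostic", "Diagnostic", "Interventional")

    age = np.exp(rng.normal(math.log(config.age_median), config.age_sigma, n))
    age = np.clip(age, *config.age_range)
    weight = _log_interp(age, WEIGHT_ANCHORS) \
        * np.exp(rng.normal(0.0, config.weight_noise_sd, n))
    height = _log_interp(age, HEIGHT_ANCHORS) \
        * np.exp(rng.normal(0.0, config.height_noise_sd, n))
    sex = rng.choice(["male", "female"], size=n)

    ft_med = np.array([FT_MEDIAN_S.get(t, 480.0) for t in ptype])
    ft_s = np.maximum(30.0, np.exp(rng.normal(np.log(ft_med), config.ft_sigma)))

    k = np.array([config.k_type[t] for t in ptype])
    dap_bwxft = k * np.exp(rng.normal(0.0, config.dap_sigma, n))
    total_dap = dap_bwxft * weight * (ft_s / 60.0)

    frames_med = np.array([FRAMES_MEDIAN.get(t, 250) for t in ptype])
    frames = np.where(
        frames_med > 0,
        np.round(np.exp(rng.normal(np.log(np.maximum(frames_med, 1)), 0.6))),
        np.where(rng.random(n) < 0.3,
                 np.round(np.exp(rng.normal(np.log(20.0), 1.0))), 0.0),
    ).astype(int)

    ff_mean = np.array([config.fluoro_frac[s] for s in stratum])
    kappa = config.fluoro_frac_concentration
    f = rng.beta(ff_mean * kappa, (1.0 - ff_mean) * kappa)
    f = np.where(frames == 0, 1.0, f)

    bp = np.array([config.biplane_p[s] for s in stratum])
    is_biplane = rng.random(n) < bp
    ls_kappa = config.lateral_share_concentration
    share = rng.beta(config.lateral_share_mean * ls_kappa,
                     (1.0 - config.lateral_share_mean) * ls_kappa, size=n)
    share = np.where(is_biplane, share, 0.0)

    area = np.exp(rng.normal(np.log(config.field_area_median_cm2),
                             config.field_area_sigma, n))
    kerma = total_dap * 10.0 / area   # mGy; DAP cGy·cm² -> mGy·cm² over cm²

    summaries = pd.DataFrame({
        "procedure_id": [f"P{i:05d}" for i in range(n)],
        "patient_id": [f"pt{i:05d}" for i in range(n)],
        "age": age, "sex": sex, "height": height, "weight_kg": weight,
        "procedure_type": ptype,
        "total_dap": total_dap,
        "dap_frontal": total_dap * (1.0 - share),
        "dap_lateral": total_dap * share,
        "dap_fluoro": total_dap * f,
        "dap_cine": total_dap * (1.0 - f),
        "total_kerma_irp": kerma,
        "fluoro_time": ft_s,
        "cine_frames": frames,
        "is_biplane": is_biplane,
    })

    truth = GroundTruth(
        params={"k_type": dict(config.k_type), "dap_sigma": config.dap_sigma,
                "seed": config.seed, "n_procedures": n},
        doses={plane: _true_doses(summaries, cf_table, plane)
               for plane in ("total", "frontal", "lateral")},
    )
    return summaries, truth


def _split(rng, total: float, m: int) -> np.ndarray:
    if m == 0 or total <= 0:
        return np.zeros(m)
    return rng.dirichlet(np.ones(m) * 2.0) * total


def generate_cohort(
    config: Optional[CohortConfig] = None,
    cf_table: Optional[ConversionFactorTable] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate an event table, its procedure summaries and ground truth.

    Each procedure's DAP is split over ~Poisson(mean events/procedure)
    events across the fluoro/cine x frontal/lateral cells, with durations
    summing to the fluoroscopy time and frames to the cine frame count.
    The emitted table is readable by :mod:`cathdose.ingest` with zero
    exclusions and aggregates back to the same summaries.
    """
    config = config or CohortConfig()
    summaries, truth = generate_summaries(config, cf_table=cf_table)
    rng = np.random.default_rng(config.seed + 1)

    rows = []
    for _, s in summaries.iterrows():
        n_ev = max(2, int(rng.poisson(config.events_per_procedure_mean)))
        f = s["dap_fluoro"] / s["total_dap"] if s["total_dap"] > 0 else 1.0
        lat = s["dap_lateral"] / s["total_dap"] if s["total_dap"] > 0 else 0.0

        n_cine = 0 if s["cine_frames"] == 0 else max(1, int(round(n_ev * (1 - f))))
        n_fluoro = max(1, n_ev - n_cine)
        cells = []   # (irradiation_type, plane, n, cell_dap)
        for itype, n_i, dap_i in (("fluoroscopy", n_fluoro, s["dap_fluoro"]),
                                  ("cinegraphy", n_cine, s["dap_cine"])):
            if n_i == 0:
                continue
            # each cell with nonzero DAP must own at least one event,
            # otherwise DAP would be silently lost in the split
            if dap_i * lat > 0:
                if n_i < 2:
                    n_i = 2
                n_lat = min(max(1, int(round(n_i * lat))), n_i - 1)
            else:
                n_lat = 0
            cells.append((itype, "lateral", n_lat, dap_i * lat))
            cells.append((itype, "frontal", n_i - n_lat, dap_i * (1 - lat)))

        dur_left = {"fluoroscopy": s["fluoro_time"], "cinegraphy": 0.0}
        frames_left = int(s["cine_frames"])
        n_fl_total = sum(c[2] for c in cells if c[0] == "fluoroscopy")
        n_ci_total = sum(c[2] for c in cells if c[0] == "cinegraphy")
        durations = _split(rng, dur_left["fluoroscopy"], n_fl_total)
        frames = rng.multinomial(frames_left, np.ones(n_ci_total) / n_ci_total) \
            if n_ci_total else np.array([], dtype=int)

        i_fl = i_ci = 0
        for itype, plane, n_i, cell_dap in cells:
            daps = _split(rng, cell_dap, n_i)
            for d in daps:
                if itype == "fluoroscopy":
                    duration, frame = durations[i_fl], 0
                    i_fl += 1
                else:
                    duration, frame = 0.0, int(frames[i_ci])
                    i_ci += 1
                if plane == "lateral":
                    p_ang = rng.normal(87.0, 5.0)
                    s_ang = rng.normal(1.0, 3.0)
                else:
                    p_ang = rng.normal(0.0, 15.0)
                    s_ang = rng.normal(0.0, 10.0)
                sad = rng.normal(765.0, 20.0)
                rows.append({
                    "procedure_id": s["procedure_id"],
                    "patient_id": s["patient_id"],
                    "age": s["age"], "sex": s["sex"], "height": s["height"],
                    "weight_kg": s["weight_kg"],
                    "procedure_type": s["procedure_type"],
                    "plane": plane, "irradiation_type": itype,
                    "dap": d,
                    "air_kerma_irp": (d / s["total_dap"] * s["total_kerma_irp"]
                                      if s["total_dap"] > 0 else 0.0),
                    "duration": duration, "frame_count": frame,
                    "primary_angle": float(np.clip(p_ang, -180, 180)),
                    "secondary_angle": float(np.clip(s_ang, -90, 90)),
                    "source_isocenter_dist": sad,
                    "source_detector_dist": sad + rng.uniform(250.0, 450.0),
                    "kvp": rng.uniform(60.0, 95.0),
                    "filtration_cu": 0.4,
                })
    events = pd.DataFrame(rows)
    return events, summaries, truth


def attach_reference_doses(
    summaries: pd.DataFrame,
    truth: GroundTruth,
    noise_sd: float = 0.1,
    seed: int = 0,
    plane: str = "total",
) -> pd.DataFrame:
    """Label a cohort with noisy reference doses for conversion-factor recovery.

    reference = truth x exp(eta), eta ~ N(0, noise_sd^2), seeded — stands in
    for a per-procedure Monte Carlo dosimetry result whose expected
    log-dose matches the generating slopes.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    true = truth.doses[plane]
    out = summaries.set_index("procedure_id").copy()
    for col in true.columns:
        eta = rng.normal(0.0, noise_sd, len(true)) if noise_sd > 0 else 0.0
        out[col] = true[col].to_numpy() * np.exp(eta)
    return out.reset_index()
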