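"""BEIR VII lifetime attributable risk (LAR) of cancer incidence and mortality.

The risk tables give the number of cases (or deaths) per 100,000 persons
for a population exposed to 0.1 Gy at a given age, by sex and cancer site,
with a dose and dose-rate effectiveness factor (DDREF) of 1.5 already
applied.  LAR for an actual organ dose scales linearly:

    LAR = dose_Gy / 0.1 x coefficient(site, sex, age) x 1.5 / DDREF

Ages off the table grid are linearly interpolated (clamped at the ends).
Reported values are rounded to whole cases per 100,000 only at formatting;
the conventional DDREF-2 report value rescales the already-rounded
DDREF-1.5 figure, mirroring how such chains are usually printed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

TABLE_DDREF = 1.5          # native DDREF of the risk tables
KINDS = ("incidence", "mortality")

#: BEIR site -> dosimetric organ delivering its dose
DEFAULT_SITE_MAP = {
    "lung": "lungs",
    "stomach": "stomach",
    "liver": "liver",
    "colon": "colon",
    "bladder": "urinary bladder",
    "thyroid": "thyroid",
    "leukemia": "active bone marrow",
    "breast": "breasts",
    "ovary": "ovaries",
    "other": "remainder",
}

#: sites only valid for one sex (zero contribution otherwise)
SEX_SPECIFIC_SITES = {"breast": "female", "ovary": "female",
                      "uterus": "female", "prostate": "male"}

#: aggregate rows never summed into a per-site total
AGGREGATE_SITES = ("all solid", "all cancers")


@dataclass
class RiskEstimate:
    """Per-site and total LAR of one exposure (per 100,000, unrounded)."""

    per_site: dict
    total: float
    kind: str
    ddref: float
    sex: str
    age: float

    def report(self) -> dict:
        """Whole-person formatting: integer cases per 100,000."""
        out = {site: int(round(v)) for site, v in self.per_site.items()}
        out["all cancers"] = int(round(self.total))
        return out


class RiskCoefficientTable:
    """Age/sex/site lookup into the lifetime-risk coefficient grid."""

    def __init__(self, frame: pd.DataFrame):
        need = {"kind", "sex", "site", "age_at_exposure", "coefficient"}
        if not need.issubset(frame.columns):
            raise ValueError(f"risk table needs columns {sorted(need)}")
        if (frame["coefficient"] < 0).any():
            raise ValueError("risk coefficients must be >= 0")
        self.frame = frame.copy()

    @classmethod
    def default(cls) -> "RiskCoefficientTable":
        with resources.files("cathdose.data").joinpath(
                "beir_vii_lar.csv").open() as fh:
            return cls(pd.read_csv(fh))

    @classmethod
    def from_csv(cls, path) -> "RiskCoefficientTable":
        return cls(pd.read_csv(Path(path)))

    def sites(self, kind: str, sex: str) -> list[str]:
        df = self.frame
        sel = df[(df["kind"] == kind) & (df["sex"] == sex)]
        return sorted(set(sel["site"]) - set(AGGREGATE_SITES))

    def coefficient(self, site: str, sex: str, age: float,
                    kind: str = "incidence") -> float:
        """Cases per 100,000 per 0.1 Gy at the given age at exposure.

        Exact grid ages return the table cell; ages between grid points are
        linearly interpolated; ages beyond the grid clamp to the endpoint.
        """
        if age < 0:
            raise ValueError("age must be >= 0")
        if kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        df = self.frame
        sel = df[(df["kind"] == kind) & (df["sex"] == sex)
                 & (df["site"] == site)].sort_values("age_at_exposure")
        if len(sel) == 0:
            raise KeyError(
                f"no coefficients for site={site!r}, sex={sex!r}, kind={kind!r}; "
                f"known sites: {self.sites(kind, sex) + list(AGGREGATE_SITES)}")
        ages = sel["age_at_exposure"].to_numpy(dtype=float)
        vals = sel["coefficient"].to_numpy(dtype=float)
        return float(np.interp(age, ages, vals))   # np.interp clamps at ends


def lar_for_site(
    dose_mgy: float,
    site: str,
    sex: str,
    age: float,
    kind: str = "incidence",
    ddref: float = 1.5,
    table: Optional[RiskCoefficientTable] = None,
) -> float:
    """LAR per 100,000 for one organ dose (mGy), unrounded.

    Linear in dose; rescaled from the tables' native DDREF 1.5 to the
    requested DDREF (the ICRP-recommended value is 2).
    """
    if dose_mgy < 0:
        raise ValueError("dose must be >= 0")
    if ddref <= 0:
        raise ValueError("ddref must be > 0")
    required = SEX_SPECIFIC_SITES.get(site)
    if required is not None and sex != required:
        return 0.0
    table = table or RiskCoefficientTable.default()
    coeff = table.coefficient(site, sex, age, kind)
    dose_gy = dose_mgy / 1000.0
    return dose_gy / 0.1 * coeff * (TABLE_DDREF / ddref)


def lar_total(
    organ_doses: dict[str, float],
    sex: str,
    age: float,
    kind: str = "incidence",
    ddref: float = 1.5,
    site_map: Optional[dict] = None,
    table: Optional[RiskCoefficientTable] = None,
) -> RiskEstimate:
    """All-cancer LAR as the sum of per-site LARs over the site map.

    ``site_map`` assigns each cancer site its dosimetric organ; sites whose
    organ is absent from ``organ_doses`` contribute zero, and sex-specific
    sites contribute zero for the other sex.  The sex-specific remainder
    organ is resolved automatically (``remainder`` -> ``remainder male`` /
    ``remainder female`` when present).
    """
    table = table or RiskCoefficientTable.default()
    site_map = DEFAULT_SITE_MAP if site_map is None else site_map
    available = set(table.sites(kind, sex))
    per_site = {}
    for site, organ in site_map.items():
        if site in AGGREGATE_SITES:
            raise ValueError(f"aggregate row {site!r} cannot be a mapped site")
        required = SEX_SPECIFIC_SITES.get(site)
        if required is not None and sex != required:
            continue
        if site not in available:
            # e.g. thyroid has no mortality row; skip rather than invent one
            continue
        key = organ
        if organ == "remainder" and f"remainder {sex}" in organ_doses:
            key = f"remainder {sex}"
        dose = float(organ_doses.get(key, 0.0))
        per_site[site] = lar_for_site(dose, site, sex, age, kind=kind,
                                      ddref=ddref, table=table)
    return RiskEstimate(
        per_site=per_site, total=sum(per_site.values()),
        kind=kind, ddref=ddref, sex=sex, age=age)


def lar_report(
    dose_mgy: float,
    site: str,
    sex: str,
    age: float,
    kind: str = "incidence",
    table: Optional[RiskCoefficientTable] = None,
) -> dict:
    """Report-formatted LAR chain for one organ dose.

    Returns integer per-100,000 values at DDREF 1.5 and DDREF 2, where the
    DDREF-2 figure rescales the already-rounded DDREF-1.5 figure — the way
    such two-step conversions are conventionally printed.
    """
    raw = lar_for_site(dose_mgy, site, sex, age, kind=kind, ddref=1.5,
                       table=table)
    at_15 = int(round(raw))
    at_2 = int(round(at_15 * TABLE_DDREF / 2.0))
    return {"site": site, "sex": sex, "age": age, "kind": kind,
            "lar_ddref_1.5": at_15, "lar_ddref_2.0": at_2,
            "lar_unrounded_ddref_1.5": raw}
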