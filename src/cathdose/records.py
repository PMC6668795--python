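"""Domain records for per-event exposures and per-procedure summaries.

An *irradiation event* is one exposure run (a fluoroscopy pedal press or a
cinegraphy acquisition) reported by the modality with its dose, duration and
C-arm geometry.  A *procedure* is the full catheterization: the cumulative
dose quantities of its events plus the patient context.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

SEXES = ("male", "female")
PLANES = ("frontal", "lateral")
IRRADIATION_TYPES = ("fluoroscopy", "cinegraphy", "rotational", "other")

#: Procedure-type vocabulary (free strings are mapped to "other").
PROCEDURE_TYPES = (
    "Diagnostic",
    "ASD closure",
    "PFO closure",
    "PDA closure",
    "Single Balloon Valvuloplasty",
    "Single Balloon Angioplasty",
    "Multi Balloon Dilatation",
    "Pulmonary Valve Replacement",
    "Stenting",
    "other",
)


@dataclass(frozen=True)
class PatientInfo:
    """Patient demographics and size at procedure time."""

    patient_id: str
    age: float          # years, fractional allowed
    sex: str            # "male" | "female"
    height: float       # cm
    weight_kg: float    # kg

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.weight_kg <= 0:
            raise ValueError("weight_kg must be > 0")
        if self.height <= 0:
            raise ValueError("height must be > 0")


@dataclass(frozen=True)
class IrradiationEvent:
    """One exposure: dose, duration and C-arm geometry in canonical units."""

    procedure_id: str
    plane: str                      # "frontal" | "lateral"
    irradiation_type: str           # fluoroscopy | cinegraphy | rotational | other
    dap: float                      # cGy·cm²
    air_kerma_irp: float            # mGy
    duration: float                 # s
    frame_count: int
    primary_angle: Optional[float] = None    # deg, RAO- / LAO+
    secondary_angle: Optional[float] = None  # deg, CAU- / CRA+
    source_isocenter_dist: Optional[float] = None  # mm
    source_detector_dist: Optional[float] = None   # mm
    kvp: Optional[float] = None
    filtration_cu: Optional[float] = None    # mm Cu

    def __post_init__(self):
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}, got {self.plane!r}")
        if self.irradiation_type not in IRRADIATION_TYPES:
            raise ValueError(
                f"irradiation_type must be one of {IRRADIATION_TYPES}, "
                f"got {self.irradiation_type!r}"
            )
        for name in ("dap", "air_kerma_irp", "duration", "frame_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        sid, sad = self.source_detector_dist, self.source_isocenter_dist
        if sid is not None and sad is not None and not sid > sad > 0:
            raise ValueError(
                "require source_detector_dist > source_isocenter_dist > 0"
            )

    @property
    def has_geometry(self) -> bool:
        """True when the event carries everything a simulation job needs."""
        return all(
            getattr(self, f) is not None
            for f in ("primary_angle", "secondary_angle",
                      "source_isocenter_dist", "source_detector_dist")
        )


@dataclass(frozen=True)
class ProcedureSummary:
    """Cumulative exposure quantities of one catheterization procedure."""

    procedure_id: str
    patient: PatientInfo
    procedure_type: str
    total_dap: float        # cGy·cm²
    dap_frontal: float
    dap_lateral: float
    dap_fluoro: float
    dap_cine: float
    total_kerma_irp: float  # mGy
    fluoro_time: float      # s
    cine_frames: int
    is_biplane: bool

    def __post_init__(self):
        tol = 1e-6 * max(1.0, abs(self.total_dap))
        if not math.isclose(self.total_dap, self.dap_frontal + self.dap_lateral,
                            abs_tol=tol):
            raise ValueError("total_dap != dap_frontal + dap_lateral")
        if not math.isclose(self.total_dap, self.dap_fluoro + self.dap_cine,
                            abs_tol=tol):
            raise ValueError("total_dap != dap_fluoro + dap_cine")

    @property
    def fluoro_fraction(self) -> Optional[float]:
        """Share of the total DAP delivered by fluoroscopy (None if DAP 0)."""
        if self.total_dap == 0:
            return None
        return self.dap_fluoro / self.total_dap

    def to_row(self) -> dict:
        """Flatten to one cohort-table row (canonical column names)."""
        return {
            "procedure_id": self.procedure_id,
            "patient_id": self.patient.patient_id,
            "age": self.patient.age,
            "sex": self.patient.sex,
            "height": self.patient.height,
            "weight_kg": self.patient.weight_kg,
            "procedure_type": self.procedure_type,
            "total_dap": self.total_dap,
            "dap_frontal": self.dap_frontal,
            "dap_lateral": self.dap_lateral,
            "dap_fluoro": self.dap_fluoro,
            "dap_cine": self.dap_cine,
            "total_kerma_irp": self.total_kerma_irp,
            "fluoro_time": self.fluoro_time,
            "cine_frames": self.cine_frames,
            "is_biplane": self.is_biplane,
        }


@dataclass
class ValidationReport:
    """Outcome of event screening: what was kept, what was excluded and why."""

    n_events_in: int
    n_events_kept: int
    exclusions: list = field(default_factory=list)  # (event index, reason)

    def __post_init__(self):
        if self.n_events_kept + len(self.exclusions) != self.n_events_in:
            raise ValueError("kept + excluded must equal events in")
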