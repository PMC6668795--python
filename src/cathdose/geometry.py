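"""Phantom selection/scaling and focal-spot-to-skin distance (FSD).

The patient trunk is modelled as an elliptical cylinder whose semi-axes at
heart level come from a reference mathematical phantom (selected by age,
scaled to the patient's height and weight).  With the heart assumed at the
C-arm isocenter, the FSD along the central ray is the source-to-isocenter
distance minus the distance from the heart to the point where the ray
pierces the trunk surface.  This is closed-form for an elliptical cylinder;
cranio-caudal angulation is handled by projecting onto the transverse plane
and dividing by cos(secondary angle).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .records import IrradiationEvent, PatientInfo

PHANTOM_CLASSES = ("newborn", "1y", "5y", "10y", "15y", "adult")


@dataclass(frozen=True)
class PhantomSpec:
    """Reference phantom of one age class (dimensions in cm)."""

    reference_age_class: str
    nominal_age: float
    reference_height: float
    reference_weight: float
    trunk_semi_axis_ap: float     # anterior-posterior half-thickness at heart level
    trunk_semi_axis_lat: float    # half-width at heart level
    heart_offset: tuple = (0.0, 0.0, 0.0)   # (ap, lat, cranio-caudal) from trunk axis

    def __post_init__(self):
        if self.reference_age_class not in PHANTOM_CLASSES:
            raise ValueError(f"unknown phantom class {self.reference_age_class!r}")
        for f in ("reference_height", "reference_weight",
                  "trunk_semi_axis_ap", "trunk_semi_axis_lat"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")


@dataclass(frozen=True)
class ScaledPhantom:
    """Reference phantom scaled to one patient under mass conservation."""

    base: PhantomSpec
    scale_height: float
    scale_transverse: float
    patient: PatientInfo

    @property
    def semi_ap(self) -> float:
        return self.base.trunk_semi_axis_ap * self.scale_transverse

    @property
    def semi_lat(self) -> float:
        return self.base.trunk_semi_axis_lat * self.scale_transverse


@dataclass(frozen=True)
class CArmPose:
    """C-arm geometry of one exposure (angles deg, distances mm)."""

    primary_angle: float       # RAO- / LAO+
    secondary_angle: float     # CAU- / CRA+
    source_isocenter_dist: float
    source_detector_dist: float
    plane: str = "frontal"

    def __post_init__(self):
        if not (self.source_detector_dist > 0 and self.source_isocenter_dist > 0):
            raise ValueError("C-arm distances must be positive")
        for a in (self.primary_angle, self.secondary_angle):
            if not -180.0 <= a <= 180.0:
                raise ValueError("angles must lie in [-180, 180] degrees")


@dataclass(frozen=True)
class SimulationJob:
    """Per-event dosimetry job descriptor (the unit of simulation work)."""

    procedure_id: str
    phantom: ScaledPhantom
    pose: CArmPose
    fsd: float                       # mm
    dap: float                       # cGy·cm²
    kvp: Optional[float] = None
    filtration_cu: Optional[float] = None
    field_size_at_skin: Optional[float] = None   # cm²


def load_phantom_table(path=None) -> pd.DataFrame:
    """Load the reference-phantom dimension table (package default or file)."""
    if path is None:
        with resources.files("cathdose.data").joinpath("phantoms.csv").open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(Path(path))


def _spec_from_row(row) -> PhantomSpec:
    return PhantomSpec(
        reference_age_class=row["reference_age_class"],
        nominal_age=float(row["nominal_age"]),
        reference_height=float(row["reference_height"]),
        reference_weight=float(row["reference_weight"]),
        trunk_semi_axis_ap=float(row["trunk_semi_axis_ap"]),
        trunk_semi_axis_lat=float(row["trunk_semi_axis_lat"]),
        heart_offset=(float(row["heart_offset_ap"]),
                      float(row["heart_offset_lat"]),
                      float(row["heart_offset_cc"])),
    )


def select_phantom(age: float, table: Optional[pd.DataFrame] = None) -> PhantomSpec:
    """Pick the reference class whose nominal age is nearest to *age*.

    Ties break toward the older class, so a 3-year-old (equidistant from the
    1 y and 5 y phantoms) gets the 5 y phantom.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    table = load_phantom_table() if table is None else table
    rows = table.sort_values("nominal_age")
    best = None
    for _, row in rows.iterrows():
        d = abs(age - row["nominal_age"])
        if best is None or d <= best[0]:   # <= keeps the older class on ties
            best = (d, row)
    return _spec_from_row(best[1])


def scale_phantom(spec: PhantomSpec, height: float, weight: float,
                  patient: Optional[PatientInfo] = None) -> ScaledPhantom:
    """Scale a reference phantom to a patient's height and weight.

    Height scales the longitudinal axis; the transverse scale follows from
    mass conservation under uniform density:
    ``weight = reference_weight * s_h * s_t**2``.
    """
    if height <= 0 or weight <= 0:
        raise ValueError("height and weight must be > 0")
    s_h = height / spec.reference_height
    s_t = math.sqrt((weight / spec.reference_weight) / s_h)
    if patient is None:
        patient = PatientInfo(patient_id="anon", age=spec.nominal_age,
                              sex="male", height=height, weight_kg=weight)
    return ScaledPhantom(base=spec, scale_height=s_h, scale_transverse=s_t,
                         patient=patient)


def compute_fsd(phantom: ScaledPhantom, pose: CArmPose) -> float:
    """Focal-spot-to-entrance-skin distance in mm, heart at isocenter.

    Works in the transverse plane: the central ray leaves the heart center
    toward the source; the distance to the trunk ellipse along that ray,
    corrected for cranio-caudal angulation, is subtracted from the
    source-to-isocenter distance.
    """
    a = phantom.semi_lat * 10.0   # mm, half-width (x)
    b = phantom.semi_ap * 10.0    # mm, half-thickness (y)
    off_ap, off_lat, _ = phantom.base.heart_offset
    cx = off_lat * 10.0 * phantom.scale_transverse
    cy = off_ap * 10.0 * phantom.scale_transverse

    # unit vector from isocenter toward the source, transverse plane
    alpha = math.radians(pose.primary_angle)
    ux, uy = -math.sin(alpha), -math.cos(alpha)

    # line-ellipse intersection: (cx + t ux)^2/a^2 + (cy + t uy)^2/b^2 = 1
    A = (ux / a) ** 2 + (uy / b) ** 2
    B = 2.0 * (cx * ux / a ** 2 + cy * uy / b ** 2)
    C = (cx / a) ** 2 + (cy / b) ** 2 - 1.0
    disc = B * B - 4.0 * A * C
    if disc < 0 or C >= 0:
        raise ValueError("no skin entry: heart center outside the trunk surface")
    t = (-B + math.sqrt(disc)) / (2.0 * A)
    if t <= 0:
        raise ValueError("no skin entry: ray leaves the trunk immediately")

    cos_sec = math.cos(math.radians(pose.secondary_angle))
    if cos_sec <= 0:
        raise ValueError("secondary angle beyond +/-90 deg is not supported")
    d = t / cos_sec
    fsd = pose.source_isocenter_dist - d
    if not 0.0 < fsd < pose.source_isocenter_dist:
        raise ValueError(
            f"FSD {fsd:.1f} mm outside (0, source_isocenter_dist); "
            "check phantom scale and pose")
    return fsd


def field_size_at_skin(dap: float, air_kerma_irp: float) -> Optional[float]:
    """Approximate beam area (cm²) at the skin as DAP / kerma when both > 0.

    DAP is in cGy·cm² and kerma in mGy; 1 cGy = 10 mGy.
    """
    if dap > 0 and air_kerma_irp > 0:
        return dap * 10.0 / air_kerma_irp
    return None


def build_simulation_job(
    event: IrradiationEvent,
    patient: PatientInfo,
    phantom_table: Optional[pd.DataFrame] = None,
) -> SimulationJob:
    """Compose phantom selection, scaling and FSD into one job descriptor."""
    if not event.has_geometry:
        raise ValueError(
            f"event in procedure {event.procedure_id!r} lacks C-arm geometry")
    spec = select_phantom(patient.age, table=phantom_table)
    phantom = scale_phantom(spec, patient.height, patient.weight_kg,
                            patient=patient)
    pose = CArmPose(
        primary_angle=event.primary_angle,
        secondary_angle=event.secondary_angle,
        source_isocenter_dist=event.source_isocenter_dist,
        source_detector_dist=event.source_detector_dist,
        plane=event.plane,
    )
    return SimulationJob(
        procedure_id=event.procedure_id,
        phantom=phantom,
        pose=pose,
        fsd=compute_fsd(phantom, pose),
        dap=event.dap,
        kvp=event.kvp,
        filtration_cu=event.filtration_cu,
        field_size_at_skin=field_size_at_skin(event.dap, event.air_kerma_irp),
    )


def job_to_text(job: SimulationJob) -> str:
    """Serialize a job as flat ``key=value`` lines in deterministic order."""
    items = [
        ("procedure_id", job.procedure_id),
        ("phantom_class", job.phantom.base.reference_age_class),
        ("scale_height", f"{job.phantom.scale_height:.6f}"),
        ("scale_transverse", f"{job.phantom.scale_transverse:.6f}"),
        ("semi_ap_cm", f"{job.phantom.semi_ap:.4f}"),
        ("semi_lat_cm", f"{job.phantom.semi_lat:.4f}"),
        ("plane", job.pose.plane),
        ("primary_angle_deg", f"{job.pose.primary_angle:.2f}"),
        ("secondary_angle_deg", f"{job.pose.secondary_angle:.2f}"),
        ("source_isocenter_mm", f"{job.pose.source_isocenter_dist:.1f}"),
        ("source_detector_mm", f"{job.pose.source_detector_dist:.1f}"),
        ("fsd_mm", f"{job.fsd:.3f}"),
        ("dap_cGy_cm2", f"{job.dap:.6g}"),
        ("kvp", "" if job.kvp is None else f"{job.kvp:.1f}"),
        ("filtration_cu_mm", "" if job.filtration_cu is None
         else f"{job.filtration_cu:.2f}"),
        ("field_size_at_skin_cm2", "" if job.field_size_at_skin is None
         else f"{job.field_size_at_skin:.3f}"),
    ]
    return "\n".join(f"{k}={v}" for k, v in items) + "\n"
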