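"""Phantom scaling and focal-spot-to-skin distance geometry."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cathdose import geometry as geo
from cathdose.records import IrradiationEvent, PatientInfo


def make_phantom(semi_ap=8.0, semi_lat=11.0, scale=1.0, offset=(0, 0, 0)):
    spec = geo.PhantomSpec(
        reference_age_class="10y", nominal_age=10, reference_height=140.0,
        reference_weight=32.0, trunk_semi_axis_ap=semi_ap,
        trunk_semi_axis_lat=semi_lat, heart_offset=offset)
    patient = PatientInfo(patient_id="x", age=10, sex="male",
                          height=140.0, weight_kg=32.0 * scale**2)
    return geo.ScaledPhantom(base=spec, scale_height=1.0,
                             scale_transverse=scale, patient=patient)


def make_pose(primary=0.0, secondary=0.0, sad=765.0, sid=1100.0):
    return geo.CArmPose(primary_angle=primary, secondary_angle=secondary,
                        source_isocenter_dist=sad, source_detector_dist=sid)


def fsd_oracle(phantom, pose, step=0.001):
    """Numeric ray-march along the 3D central ray over the elliptical
    cylinder trunk; independent of the closed-form path."""
    a = phantom.semi_lat * 10.0
    b = phantom.semi_ap * 10.0
    off_ap, off_lat, _ = phantom.base.heart_offset
    cx = off_lat * 10.0 * phantom.scale_transverse
    cy = off_ap * 10.0 * phantom.scale_transverse
    alpha = math.radians(pose.primary_angle)
    gamma = math.radians(pose.secondary_angle)
    ux = -math.sin(alpha) * math.cos(gamma)
    uy = -math.cos(alpha) * math.cos(gamma)

    def inside(t):
        x, y = cx + t * ux, cy + t * uy
        return (x / a) ** 2 + (y / b) ** 2 < 1.0

    lo, hi = 0.0, 4.0 * max(a, b) / max(math.cos(gamma), 1e-9)
    t = lo
    while inside(t) and t < hi:
        t += step * hi
    lo_t, hi_t = t - step * hi, t
    for _ in range(80):   # bisection refine
        mid = 0.5 * (lo_t + hi_t)
        if inside(mid):
            lo_t = mid
        else:
            hi_t = mid
    return pose.source_isocenter_dist - 0.5 * (lo_t + hi_t)


class TestSelectPhantom:
    @pytest.mark.parametrize("age,expected", [
        (0.9, "1y"),          # nearest of newborn/1y
        (3.0, "5y"),          # tie 1y/5y breaks toward the older class
        (69.6, "adult"),
        (0.0, "newborn"),
        (12.4, "10y"),
    ])
    def test_nearest_with_older_tiebreak(self, age, expected):
        assert geo.select_phantom(age).reference_age_class == expected

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            geo.select_phantom(-1.0)


class TestScalePhantom:
    SPEC = geo.PhantomSpec(reference_age_class="10y", nominal_age=10,
                           reference_height=140.0, reference_weight=32.0,
                           trunk_semi_axis_ap=8.0, trunk_semi_axis_lat=10.0)

    def test_identity(self):
        s = geo.scale_phantom(self.SPEC, 140.0, 32.0)
        assert s.scale_height == pytest.approx(1.0)
        assert s.scale_transverse == pytest.approx(1.0)

    def test_quadruple_weight_doubles_transverse(self):
        s = geo.scale_phantom(self.SPEC, 140.0, 4 * 32.0)
        assert s.scale_transverse == pytest.approx(2.0)

    def test_closed_form_example(self):
        s = geo.scale_phantom(self.SPEC, 150.0, 35.0)
        assert s.scale_height == pytest.approx(150.0 / 140.0)
        expected = math.sqrt((35.0 / 32.0) / (150.0 / 140.0))
        assert s.scale_transverse == pytest.approx(expected, rel=1e-12)

    @given(height=st.floats(40.0, 200.0), weight=st.floats(2.0, 120.0))
    @settings(max_examples=50, deadline=None)
    def test_mass_conservation(self, height, weight):
        s = geo.scale_phantom(self.SPEC, height, weight)
        recon = self.SPEC.reference_weight * s.scale_height * s.scale_transverse**2
        assert recon == pytest.approx(weight, rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            geo.scale_phantom(self.SPEC, 0.0, 30.0)


class TestComputeFSD:
    def test_pa_beam_straight_line(self):
        """PA beam at SAD 765 mm through an 80 mm AP semi-axis: 685 mm."""
        ph = make_phantom(semi_ap=8.0)
        assert geo.compute_fsd(ph, make_pose(0.0)) == pytest.approx(685.0)

    def test_pure_lateral(self):
        ph = make_phantom(semi_lat=11.0)
        assert geo.compute_fsd(ph, make_pose(90.0)) == pytest.approx(765.0 - 110.0)

    def test_circular_trunk_angle_independent(self):
        ph = make_phantom(semi_ap=9.0, semi_lat=9.0)
        vals = [geo.compute_fsd(ph, make_pose(a))
                for a in range(-180, 181, 30)]
        assert all(v == pytest.approx(765.0 - 90.0, abs=1e-9) for v in vals)

    def test_left_right_symmetry(self):
        ph = make_phantom()
        for a in (15.0, 40.0, 87.0, 130.0):
            assert geo.compute_fsd(ph, make_pose(a)) == pytest.approx(
                geo.compute_fsd(ph, make_pose(-a)), abs=1e-9)

    def test_monotone_in_semi_axes(self):
        pose = make_pose(30.0)
        f = [geo.compute_fsd(make_phantom(semi_ap=ap), pose)
             for ap in (6.0, 7.0, 8.0, 9.0)]
        assert all(a >= b for a, b in zip(f, f[1:]))

    def test_oracle_agreement_oblique(self):
        """LAO 30 with elliptical trunk matches the ray-marching oracle."""
        ph = make_phantom(semi_ap=8.0, semi_lat=11.0)
        pose = make_pose(30.0)
        assert geo.compute_fsd(ph, pose) == pytest.approx(
            fsd_oracle(ph, pose), abs=0.1)

    def test_heart_offset_shifts_entry(self):
        on_axis = geo.compute_fsd(make_phantom(), make_pose(0.0))
        # heart shifted 2 cm anteriorly -> posterior entry is farther away
        shifted = geo.compute_fsd(make_phantom(offset=(2.0, 0.0, 0.0)),
                                  make_pose(0.0))
        assert shifted == pytest.approx(on_axis - 20.0, abs=1e-9)

    def test_no_skin_entry_error(self):
        ph = make_phantom(offset=(50.0, 0.0, 0.0))   # heart outside trunk
        with pytest.raises(ValueError, match="no skin entry"):
            geo.compute_fsd(ph, make_pose(0.0))

    def test_fsd_below_source_distance(self):
        ph = make_phantom()
        for a in range(-180, 181, 45):
            for sec in (-30.0, 0.0, 30.0):
                fsd = geo.compute_fsd(ph, make_pose(a, sec))
                assert 0 < fsd < 765.0


class TestSimulationJobs:
    PATIENT = PatientInfo(patient_id="pt", age=10.0, sex="male",
                          height=140.0, weight_kg=32.15)

    def make_event(self, **kw):
        base = dict(procedure_id="P1", plane="frontal",
                    irradiation_type="fluoroscopy", dap=100.0,
                    air_kerma_irp=10.0, duration=60.0, frame_count=0,
                    primary_angle=0.0, secondary_angle=0.0,
                    source_isocenter_dist=765.0, source_detector_dist=1100.0,
                    kvp=70.0)
        base.update(kw)
        return IrradiationEvent(**base)

    def test_job_composition(self):
        job = geo.build_simulation_job(self.make_event(), self.PATIENT)
        assert job.phantom.base.reference_age_class == "10y"
        assert 0 < job.fsd < 765.0
        assert job.field_size_at_skin == pytest.approx(100.0 * 10 / 10.0)

    def test_incomplete_geometry_rejected(self):
        ev = self.make_event(primary_angle=None)
        with pytest.raises(ValueError, match="geometry"):
            geo.build_simulation_job(ev, self.PATIENT)

    def test_one_job_per_event(self):
        events = [self.make_event(dap=float(i)) for i in range(63)]
        jobs = [geo.build_simulation_job(e, self.PATIENT) for e in events]
        assert len(jobs) == 63

    def test_job_serialization_deterministic(self):
        job = geo.build_simulation_job(self.make_event(), self.PATIENT)
        text = geo.job_to_text(job)
        assert text == geo.job_to_text(job)
        assert text.startswith("procedure_id=P1\n")
        assert "fsd_mm=" in text
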