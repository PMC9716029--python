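import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thasim import (
    ComponentOrientation,
    HipPose,
    cup_angles_from_axis,
    cup_axis,
    hip_rotation,
    liner_frame,
    neck_axis_in_femur,
    neck_axis_in_liner,
)
from thasim.clearance import neck_polar_angle_deg


def _orientation(ri=40.0, ra=15.0, sa=30.0, side="right"):
    return ComponentOrientation(ri, ra, sa, side)


class TestCupAxis:
    def test_zero_angles_face_inferior(self):
        n = cup_axis(_orientation(0, 0))
        assert n == pytest.approx([0, 0, -1])

    def test_coronal_plane_faces_lateral(self):
        assert cup_axis(_orientation(90 - 1e-9, 0)) == pytest.approx(
            [1, 0, 0], abs=1e-9
        )

    def test_left_side_mirrors_lateral_component(self):
        nr = cup_axis(_orientation(40, 20, side="right"))
        nl = cup_axis(_orientation(40, 20, side="left"))
        assert nl == pytest.approx([-nr[0], nr[1], nr[2]])

    @given(
        ri=st.floats(1.0, 89.0),
        ra=st.floats(-89.0, 89.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_radiographic_angles_round_trip(self, ri, ra):
        n = cup_axis(_orientation(ri, ra))
        ri2, ra2 = cup_angles_from_axis(n)
        assert ri2 == pytest.approx(ri, abs=1e-9)
        assert ra2 == pytest.approx(ra, abs=1e-9)


class TestLinerFrame:
    def test_orthonormal_right_handed(self):
        L = liner_frame(_orientation(40, 15))
        assert np.abs(L @ L.T - np.eye(3)).max() < 1e-9
        assert np.linalg.det(L) == pytest.approx(1.0, abs=1e-9)

    def test_third_column_is_cup_axis(self):
        o = _orientation(40, 15)
        assert liner_frame(o)[:, 2] @ cup_axis(o) == pytest.approx(1.0, abs=1e-12)

    def test_azimuth_origin_is_anterior_projection(self):
        L = liner_frame(_orientation(40, 0))
        assert L[:, 0] @ np.array([0, 1, 0]) > 0


class TestNeckAxisInFemur:
    def test_zero_anteversion_lies_in_coronal_plane(self, spec):
        d = neck_axis_in_femur(spec, 0.0)
        # head-to-shaft: lateral and inferior, sin 50 = 0.766
        assert d == pytest.approx([0.766, 0.0, -0.643], abs=1e-3)

    def test_anteversion_sets_sagittal_component(self, spec):
        d = neck_axis_in_femur(spec, 30.0)
        # shaft-to-head y-component sin50*sin30 = 0.383; head-to-shaft negates
        assert -d[1] == pytest.approx(math.sin(math.radians(50)) * 0.5, abs=1e-9)

    def test_unit_norm(self, spec):
        assert np.linalg.norm(neck_axis_in_femur(spec, 17.0, "left")) == pytest.approx(1.0)


class TestHipRotation:
    def test_neutral_pose_is_identity(self):
        assert np.abs(hip_rotation(HipPose(0, 0, 0)) - np.eye(3)).max() < 1e-12

    def test_pure_flexion_carries_distal_femur_anterior(self):
        # 90 degrees flexion: the thigh (femur -z) points anterior (+y).
        R = hip_rotation(HipPose(90, 0, 0))
        assert R @ np.array([0, 0, -1.0]) == pytest.approx([0, 1, 0], abs=1e-12)

    def test_intrinsic_xyz_composition_order(self):
        def ax(a, axis):
            a = math.radians(a)
            c, s = math.cos(a), math.sin(a)
            m = {
                "x": [[1, 0, 0], [0, c, -s], [0, s, c]],
                "y": [[c, 0, s], [0, 1, 0], [-s, 0, c]],
                "z": [[c, -s, 0], [s, c, 0], [0, 0, 1]],
            }
            return np.array(m[axis])

        R = hip_rotation(HipPose(30, 10, 20))
        expected = ax(30, "x") @ ax(10, "y") @ ax(20, "z")
        assert np.abs(R - expected).max() < 1e-12
        wrong_order = ax(20, "z") @ ax(10, "y") @ ax(30, "x")
        assert np.abs(R - wrong_order).max() > 1e-3

    def test_gimbal_degeneracy_flagged(self):
        with pytest.raises(ValueError, match="gimbal"):
            hip_rotation(HipPose(10, 90, 5))

    @given(
        f=st.floats(-120, 150),
        a=st.floats(-45, 45),
        r=st.floats(-90, 90),
        side=st.sampled_from(["right", "left"]),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rotation_matrices_are_proper(self, f, a, r, side):
        R = hip_rotation(HipPose(f, a, r), side)
        assert np.abs(R @ R.T - np.eye(3)).max() < 1e-9
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


class TestNeckAxisInLiner:
    def test_unit_norm_preserved(self, spec):
        d = neck_axis_in_liner(spec, _orientation(40, 20, 30), HipPose(0, 0, 0))
        assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-12)

    def test_polar_angle_monotone_in_internal_rotation_at_flexion(self, spec):
        o = _orientation(40, 15, 30)
        angles = [
            neck_polar_angle_deg(neck_axis_in_liner(spec, o, HipPose(90, 0, ir)))
            for ir in range(0, 61, 5)
        ]
        assert all(b > a for a, b in zip(angles, angles[1:]))

    def test_flexion_matching_cup_tilt_reduces_polar_angle(self, spec):
        # For an anteverted cup, flexing by the anteversion-induced tilt brings
        # the neck closer to the liner axis than no flexion at all.
        o = _orientation(40, 20, 20)
        at_zero = neck_polar_angle_deg(neck_axis_in_liner(spec, o, HipPose(0, 0, 0)))
        at_tilt = neck_polar_angle_deg(neck_axis_in_liner(spec, o, HipPose(20, 0, 0)))
        assert at_tilt < at_zero

    def test_mirror_symmetry(self, spec):
        # A left hip with the same (side-neutral) pose angles is the mirror
        # image: the lateral liner-frame component negates, the polar angle
        # and anterior component are unchanged.
        pose = HipPose(70, 12, 25)
        dr = neck_axis_in_liner(spec, _orientation(38, 16, 34, "right"), pose)
        dl = neck_axis_in_liner(spec, _orientation(38, 16, 34, "left"), pose)
        assert dl == pytest.approx([dr[0], -dr[1], dr[2]], abs=1e-12)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(cup_inclination=95, cup_anteversion=10, stem_anteversion=10),
            dict(cup_inclination=-1, cup_anteversion=10, stem_anteversion=10),
            dict(cup_inclination=40, cup_anteversion=95, stem_anteversion=10),
            dict(cup_inclination=40, cup_anteversion=10, stem_anteversion=-95),
        ],
    )
    def test_orientation_range_checks(self, kwargs):
        with pytest.raises(ValueError):
            ComponentOrientation(**kwargs)

    def test_pose_range_check(self):
        with pytest.raises(ValueError, match="flexion"):
            HipPose(200, 0, 0)

    def test_combined_anteversion_is_sum(self):
        o = _orientation(40, 16, 34)
        assert o.combined_anteversion == pytest.approx(50.0)
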