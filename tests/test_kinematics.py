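"""Geometry of the marker-derived quantities: pelvis center, FPA,
relative toe-in, knee joint center, static alignment, mirroring."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from toegait import kinematics as kin


class TestPelvisCenter:
    def test_mean_of_four_markers(self):
        lasi, rasi = np.array([100.0, 0, 900]), np.array([-100.0, 0, 900])
        lpsi, rpsi = np.array([80.0, -120, 910]), np.array([-80.0, -120, 910])
        np.testing.assert_allclose(
            kin.pelvis_center(lasi, rasi, lpsi, rpsi), [0.0, -60.0, 905.0]
        )

    def test_translation_equivariance(self):
        pts = [np.array([10.0, 2, 3]), np.array([4.0, 5, 6]),
               np.array([7.0, 8, 9]), np.array([1.0, 0, -1])]
        t = np.array([5.0, -3.0, 2.0])
        np.testing.assert_allclose(
            kin.pelvis_center(*(p + t for p in pts)),
            kin.pelvis_center(*pts) + t,
        )


class TestPelvisRelative:
    def test_identity_and_invariance(self, rng):
        traj = rng.normal(size=(50, 3)) * 100
        pelvis = rng.normal(size=(50, 3)) * 100
        ml, ap = kin.to_pelvis_relative(traj, pelvis)
        np.testing.assert_allclose(ml, traj[:, 0] - pelvis[:, 0])
        shift = np.array([31.0, -7.0, 12.0])
        ml2, ap2 = kin.to_pelvis_relative(traj + shift, pelvis + shift)
        np.testing.assert_allclose(ml2, ml, atol=1e-9)
        np.testing.assert_allclose(ap2, ap, atol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kin.to_pelvis_relative(np.zeros((5, 3)), np.zeros((4, 3)))


class TestFootProgressionAngle:
    @pytest.mark.parametrize(
        "v, expected",
        [
            ((0.0, 1.0, 0.0), 0.0),
            ((-np.sin(np.radians(10)), np.cos(np.radians(10)), 0.0), 10.0),
            ((np.sin(np.radians(5)), np.cos(np.radians(5)), 0.0), -5.0),
        ],
    )
    def test_signed_angle(self, v, expected):
        """Toe-out (foot vector rotated toward -X on the left leg) is
        positive; toe-in negative."""
        calc = np.zeros(3)
        assert kin.foot_progression_angle(calc, np.asarray(v)) == pytest.approx(expected)

    @given(
        angle=st.floats(-60, 60),
        scale=st.floats(0.1, 10),
        tx=st.floats(-500, 500),
        ty=st.floats(-500, 500),
    )
    def test_invariant_to_translation_and_scale(self, angle, scale, tx, ty):
        a = np.radians(angle)
        v = np.array([-np.sin(a), np.cos(a), 0.3])
        calc = np.array([tx, ty, 30.0])
        fpa = kin.foot_progression_angle(calc, calc + scale * v)
        assert fpa == pytest.approx(angle, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            kin.foot_progression_angle([0, 0, 0], [0, 0, 10.0])


class TestRelativeToeIn:
    def test_paper_scale_means(self):
        # baseline 3.97 deg, toe-in step at -5.65 deg => 9.62 deg toe-in
        assert kin.relative_toe_in_angle(-5.65, 3.97) == pytest.approx(9.62)

    def test_zero_and_definition(self):
        assert kin.relative_toe_in_angle(6.46, 6.46) == 0.0
        assert kin.relative_toe_in_angle(6.46 - 5.0, 6.46) == pytest.approx(5.0)


class TestKneeJointCenter:
    def test_midpoint(self):
        np.testing.assert_allclose(
            kin.knee_joint_center([-120.0, 0, 480], [-40.0, 0, 480]),
            [-80.0, 0, 480],
        )

    def test_degenerate_equal_markers(self):
        p = np.array([-70.0, 5, 470])
        np.testing.assert_allclose(kin.knee_joint_center(p, p), p)

    def test_medial_fallback(self):
        np.testing.assert_allclose(
            kin.knee_joint_center([-120.0, 0, 480], None, half_width_mm=50.0),
            [-70.0, 0, 480],
        )


class TestStaticValgus:
    def test_collinear_is_zero(self):
        assert kin.static_valgus_angle(
            [-100.0, 0, 80], [-100.0, 0, 480], [-100.0, 0, 880]
        ) == pytest.approx(0.0)

    def test_hand_geometry_valgus_positive(self):
        # knee medial to the ankle-hip line => knock-knee => positive
        ang = kin.static_valgus_angle([-100.0, 0, 80], [-80.0, 0, 480], [-100.0, 0, 880])
        assert ang == pytest.approx(5.7248, abs=1e-3)

    def test_antisymmetry_under_x_mirror(self, rng):
        for _ in range(20):
            lmal, lepi, hjc = rng.normal(size=(3, 3)) * 200 + [0, 0, 400]
            a = kin.static_valgus_angle(lmal, lepi, hjc)
            m = np.array([-1.0, 1.0, 1.0])
            b = kin.static_valgus_angle(lmal * m, lepi * m, hjc * m)
            assert b == pytest.approx(-a, abs=1e-9)


class TestMirror:
    def _make_record(self, side):
        from toegait.datatypes import REQUIRED_MARKERS, TrialRecording

        rng = np.random.default_rng(0)
        markers = {lab: rng.normal(size=(20, 3)) * 100 for lab in REQUIRED_MARKERS}
        return TrialRecording(
            subject_id="S1", condition="baseline", side=side,
            marker_series=markers,
            grf_series=rng.normal(size=(40, 3)) * 100,
            cop_series=rng.normal(size=(40, 3)) * 100,
            plate_vertical_other=np.zeros(40),
            marker_rate=100.0, force_rate=200.0,
            walking_speed=1.2, height=1.7, weight=70.0,
        )

    def test_left_unchanged(self):
        rec = self._make_record("left")
        assert kin.mirror_to_canonical(rec) is rec

    def test_right_x_negated_and_involution(self):
        rec = self._make_record("right")
        mirrored = kin.mirror_to_canonical(rec)
        assert mirrored.side == "left"
        np.testing.assert_allclose(
            mirrored.marker_series["CALC"][:, 0], -rec.marker_series["CALC"][:, 0]
        )
        np.testing.assert_allclose(
            mirrored.marker_series["CALC"][:, 1:], rec.marker_series["CALC"][:, 1:]
        )
        np.testing.assert_allclose(mirrored.grf_series[:, 0], -rec.grf_series[:, 0])
        # mirror twice restores the geometry
        import dataclasses

        twice = kin.mirror_to_canonical(dataclasses.replace(mirrored, side="right"))
        assert twice.equals(rec.__class__(**{**rec.__dict__, "side": "left"}))

    def test_side_independence_of_clinical_quantities(self):
        """A right leg whose geometry mirrors a left leg yields the same
        FPA and valgus after mirroring."""
        calc, met2 = np.array([-100.0, 0, 30]), np.array([-130.0, 170, 25])
        fpa_left = kin.foot_progression_angle(calc, met2)
        m = np.array([-1.0, 1.0, 1.0])
        fpa_right_mirrored = kin.foot_progression_angle(calc * m * m, met2 * m * m)
        assert fpa_right_mirrored == pytest.approx(fpa_left)
        lmal, lepi, hjc = (
            np.array([-100.0, 0, 80]), np.array([-80.0, 0, 480]), np.array([-100.0, 0, 880])
        )
        v_left = kin.static_valgus_angle(lmal, lepi, hjc)
        # the mirrored right-leg markers, mirrored back to canonical:
        v_right = kin.static_valgus_angle(lmal * m * m, lepi * m * m, hjc * m * m)
        assert v_right == pytest.approx(v_left)
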