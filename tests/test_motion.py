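"""Rigid-transform algebra, motion-score metrics, trace processing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from mocosim.motion import (
    MotionScoreParams,
    MotionTrace,
    RigidTransform,
    combined_rotation_angle,
    expected_deflection,
    lowpass_filter_trace,
    mean_motion_score,
    motion_score_frame,
    rebase_trace,
    rotation_angle_from_matrix,
    sphere_displacement,
)

angles = st.floats(-80.0, 80.0)
shifts = st.floats(-20.0, 20.0)


@st.composite
def transforms(draw):
    return RigidTransform(
        draw(angles), draw(angles), draw(angles), draw(shifts), draw(shifts), draw(shifts)
    )


class TestRigidTransform:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(transforms())
    def test_compose_inverse_is_identity(self, t):
        assert np.abs(t.compose(t.inverse()).params).max() < 1e-9

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(transforms())
    def test_rotation_is_orthonormal(self, t):
        r = t.rotation_matrix()
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)

    def test_apply_matches_matrix(self):
        t = RigidTransform(10, -20, 30, 1, 2, 3)
        p = np.array([5.0, -7.0, 11.0])
        assert np.allclose(t.apply(p), t.rotation_matrix() @ p + t.translation)


class TestCombinedRotationAngle:
    def test_identity(self):
        assert combined_rotation_angle(0, 0, 0) == 0.0

    @pytest.mark.parametrize("axis", [0, 1, 2])
    def test_single_axis_reduces_to_input(self, axis):
        a = [0.0, 0.0, 0.0]
        a[axis] = 5.7
        assert combined_rotation_angle(*a) == pytest.approx(5.7, abs=1e-9)

    def test_closed_form_matches_matrix_trace_oracle(self):
        """The closed-form angle equals arccos((trace(R)-1)/2) evaluated
        through an independent rotation construction, including at the
        printed example angles (1.9, 1.9, 1.9)."""
        rng = np.random.default_rng(7)
        cases = [np.array([1.9, 1.9, 1.9])] + list(rng.uniform(-150, 150, (200, 3)))
        for a in cases:
            # independent oracle: scipy rotation, extrinsic x-y-z order
            r = Rotation.from_euler("xyz", a, degrees=True).as_matrix()
            oracle = np.rad2deg(np.arccos(np.clip((np.trace(r) - 1) / 2, -1, 1)))
            assert combined_rotation_angle(*a) == pytest.approx(oracle, abs=1e-8)
            assert rotation_angle_from_matrix(RigidTransform(*a)) == pytest.approx(
                oracle, abs=1e-8
            )

    def test_clamping_handles_rounding(self):
        assert combined_rotation_angle(180, 0, 0) == pytest.approx(180.0)


class TestSphereDisplacement:
    def test_endpoints(self):
        assert sphere_displacement(0.0) == 0.0
        assert sphere_displacement(180.0) == pytest.approx(128.0)

    def test_half_angle_identity(self):
        for th in np.linspace(0, 180, 37):
            assert sphere_displacement(th) == pytest.approx(
                2 * 64 * np.sin(np.deg2rad(th) / 2), rel=1e-9
            )

    def test_brute_force_sphere_oracle(self):
        """Largest displacement over 10,000 sampled points on the 64 mm
        sphere agrees with the closed form to <0.1%."""
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((10_000, 3))
        pts *= 64.0 / np.linalg.norm(pts, axis=1, keepdims=True)
        theta = 1.9
        r = RigidTransform(theta, 0, 0).rotation_matrix()
        brute = np.max(np.linalg.norm(pts @ r.T - pts, axis=1))
        assert brute == pytest.approx(sphere_displacement(theta), rel=1e-3)


class TestMotionScore:
    def test_identity_scores_zero(self):
        assert motion_score_frame(RigidTransform()) == 0.0

    def test_pure_translation_345(self):
        assert motion_score_frame(RigidTransform(0, 0, 0, 1, 2, 2)) == pytest.approx(3.0)

    def test_pure_rotation_equals_sphere_displacement(self):
        assert motion_score_frame(RigidTransform(0, 0, 1.9)) == pytest.approx(
            sphere_displacement(1.9), rel=1e-12
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(transforms())
    def test_nonnegative_and_zero_only_at_identity(self, t):
        s = motion_score_frame(t)
        assert s >= 0
        if np.abs(t.params).max() > 1e-6:
            assert s > 0

    def test_monotone_in_each_translation(self):
        base = motion_score_frame(RigidTransform(1, 0, 0, 1, 1, 1))
        for j, kw in enumerate(["t_x", "t_y", "t_z"]):
            bigger = motion_score_frame(
                RigidTransform(1, 0, 0, *(2.0 if i == j else 1.0 for i in range(3)))
            )
            assert bigger > base


class TestMeanMotionScore:
    def _trace(self, poses, dt=1.0):
        poses = np.asarray(poses, float)
        return MotionTrace(times=np.arange(len(poses)) * dt, poses=poses)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            mean_motion_score(self._trace(np.zeros((1, 6))))

    def test_constant_trace_scores_zero(self):
        poses = np.tile([3, -2, 1, 4, 5, 6], (10, 1))
        assert mean_motion_score(self._trace(poses)) == pytest.approx(0.0, abs=1e-9)

    def test_alternating_translation(self):
        poses = np.zeros((11, 6))
        poses[1::2, 3:] = [1, 2, 2]
        assert mean_motion_score(self._trace(poses)) == pytest.approx(3.0)

    def test_invariant_under_rebasing_and_reversal(self):
        rng = np.random.default_rng(3)
        poses = np.cumsum(rng.normal(0, 0.3, (20, 6)), axis=0)
        trace = self._trace(poses)
        base = mean_motion_score(trace)
        rebased = rebase_trace(trace, 10.0)
        assert mean_motion_score(rebased) == pytest.approx(base, abs=1e-9)
        reversed_ = MotionTrace(times=trace.times, poses=poses[::-1].copy())
        assert mean_motion_score(reversed_) == pytest.approx(base, abs=1e-9)


class TestExpectedDeflection:
    @pytest.mark.parametrize(
        "disp,expected", [(2.5, 1.9), (3.5, 2.6), (5.0, 3.8), (7.5, 5.7)]
    )
    def test_printed_protocol_values(self, disp, expected):
        assert round(expected_deflection(disp, 76.0), 1) == expected

    def test_zero_displacement(self):
        assert expected_deflection(0.0, 76.0) == 0.0

    def test_invalid_distance_rejected(self):
        with pytest.raises(ValueError):
            expected_deflection(2.5, 0.0)


class TestLowpassFilter:
    def _sine_trace(self, freq_hz, fs=30.0, duration=60.0):
        t = np.arange(int(duration * fs)) / fs
        poses = np.zeros((len(t), 6))
        poses[:, 0] = np.sin(2 * np.pi * freq_hz * t)
        return MotionTrace(times=t, poses=poses)

    def test_constant_trace_unchanged(self):
        t = np.arange(300) / 30.0
        poses = np.tile([1, 2, 3, 4, 5, 6], (300, 1)).astype(float)
        out = lowpass_filter_trace(MotionTrace(times=t, poses=poses), 1.0)
        assert np.abs(out.poses - poses).max() < 1e-9

    def test_stopband_attenuation(self):
        trace = self._sine_trace(5.0)
        out = lowpass_filter_trace(trace, 1.0)
        rms_in = np.sqrt(np.mean(trace.poses[:, 0] ** 2))
        rms_out = np.sqrt(np.mean(out.poses[:, 0] ** 2))
        assert rms_out < 0.05 * rms_in

    def test_passband_preserved(self):
        trace = self._sine_trace(0.1)
        out = lowpass_filter_trace(trace, 1.0)
        rms_in = np.sqrt(np.mean(trace.poses[:, 0] ** 2))
        rms_out = np.sqrt(np.mean(out.poses[:, 0] ** 2))
        assert rms_out == pytest.approx(rms_in, rel=0.05)

    def test_nonuniform_sampling_rejected(self):
        t = np.array([0.0, 1.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            lowpass_filter_trace(MotionTrace(times=t, poses=np.zeros((4, 6))), 0.1)

    def test_tracker_label_promoted(self):
        t = np.arange(100) / 30.0
        trace = MotionTrace(times=t, poses=np.zeros((100, 6)), sampling_label="tracker")
        assert lowpass_filter_trace(trace, 1.0).sampling_label == "tracker_filtered"


class TestRebase:
    def _random_trace(self, n=15):
        rng = np.random.default_rng(11)
        return MotionTrace(times=np.arange(n, dtype=float), poses=rng.normal(0, 2, (n, 6)))

    def test_reference_sample_becomes_identity(self):
        trace = self._random_trace()
        out = rebase_trace(trace, 7.2)
        idx = out.nearest_index(7.2)
        assert np.abs(out.poses[idx]).max() < 1e-9

    def test_idempotent(self):
        trace = rebase_trace(self._random_trace(), 5.0)
        again = rebase_trace(trace, 5.0)
        assert np.abs(again.poses - trace.poses).max() < 1e-9

    def test_two_rebasings_differ_by_constant_transform(self):
        trace = self._random_trace()
        a = rebase_trace(trace, 3.0)
        b = rebase_trace(trace, 9.0)
        # constant C with pose_b = C o pose_a for every sample
        c0 = b.pose(0).compose(a.pose(0).inverse())
        for i in range(len(trace)):
            recon = c0.compose(a.pose(i))
            assert np.abs(recon.params - b.poses[i]).max() < 1e-6

    def test_ties_break_to_earlier_sample(self):
        trace = self._random_trace()
        assert trace.nearest_index(2.5) == 2


class TestTraceCsv:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        trace = MotionTrace(
            times=np.arange(8) * 2.41,
            poses=rng.normal(0, 1, (8, 6)),
            reference_time=4.82,
            sampling_label="navigator",
        )
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        back = MotionTrace.from_csv(path)
        assert np.allclose(back.times, trace.times)
        assert np.allclose(back.poses, trace.poses, atol=1e-6)
        assert back.reference_time == trace.reference_time
        assert back.sampling_label == "navigator"
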