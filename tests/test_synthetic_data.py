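"""Phantom construction, motion scenarios and emulated tracking."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mocosim.motion import (
    MotionScoreParams,
    MotionTrace,
    RigidTransform,
    expected_deflection,
    lowpass_filter_trace,
    mean_motion_score,
)
from mocosim.phantom import build_default_phantom, grid_coords, _soft_ellipsoid
from mocosim.scenarios import (
    SCENARIO_NAMES,
    ScenarioSpec,
    expected_motion_score,
    generate_scenario_trace,
    peak_rotation_deg,
)
from mocosim.tracking import (
    TrackerNoiseModel,
    emulate_tracker,
    navigator_series,
    simulate_navigator_volume,
)


def _grid_points(matrix, fov):
    c = grid_coords(matrix, fov)
    xs, ys, zs = np.meshgrid(c[:, 0], c[:, 1], c[:, 2], indexing="ij")
    return np.stack([xs, ys, zs], -1).reshape(-1, 3)


class TestPhantom:
    def test_deterministic(self):
        a = build_default_phantom(64, 200.0).rasterize(64)
        b = build_default_phantom(64, 200.0).rasterize(64)
        assert np.array_equal(a, b)

    def test_support_inside_outer_shell(self, phantom):
        vol = phantom.rasterize(64)
        pts = _grid_points(64, 200.0)
        outer = phantom.components[0]
        v = (pts - np.asarray(outer.center)) / np.asarray(outer.semi_axes)
        rho = np.linalg.norm(v, axis=1).reshape(64, 64, 64)
        neck = phantom.select(["neck_fat"])[0]
        vn = (pts - np.asarray(neck.center)) / np.asarray(neck.semi_axes)
        rho_n = np.linalg.norm(vn, axis=1).reshape(64, 64, 64)
        outside = (rho > 1.3) & (rho_n > 2.0)  # beyond the smoothed edges
        assert np.abs(vol[outside]).max() < 1e-4

    def test_required_components_present(self, phantom):
        tags = {c.tissue_tag for c in phantom.components}
        assert {"brain", "scalp_fat", "neck_fat"} <= tags
        assert len(phantom.select(["feature"])) >= 5

    def test_voxel_count_matches_analytic_volume(self, phantom):
        """Binarised rasterisation of every ellipsoid agrees with its
        analytic volume within 5% at 64^3."""
        pts = _grid_points(64, 200.0)
        voxvol = (200.0 / 64) ** 3
        for comp in phantom.components:
            count = float((_soft_ellipsoid(pts, comp, 2.0) >= 0.5).sum()) * voxvol
            assert count == pytest.approx(comp.volume_mm3, rel=0.05)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            build_default_phantom(16)

    def test_component_outside_fov_rejected(self):
        with pytest.raises(ValueError):
            build_default_phantom(64, fov_mm=120.0)


class TestScenarioTraces:
    @pytest.mark.parametrize("name", sorted(SCENARIO_NAMES))
    def test_deterministic_and_peak_amplitude(self, name):
        """Peak rotation of every scenario equals the predicted deflection
        of its printed geometry (full-length timings, 30 Hz)."""
        sc = ScenarioSpec.named(name)
        t1 = generate_scenario_trace(sc, 30.0)
        t2 = generate_scenario_trace(sc, 30.0)
        assert np.array_equal(t1.poses, t2.poses)
        assert peak_rotation_deg(t1) == pytest.approx(sc.deflection_deg, abs=1e-6)
        assert np.abs(t1.poses[:, 3:]).max() == 0.0  # prescribed: no translation

    def test_stepwise_identity_before_motion_onset(self):
        trace = generate_scenario_trace(ScenarioSpec.named("stepwise-small"), 10.0)
        pre = trace.poses[trace.times < 20.0 - 1e-9]
        assert np.abs(pre).max() == 0.0
        post = trace.poses[(trace.times > 21.0) & (trace.times < 54.0)]
        assert np.abs(post).max() > 0

    def test_circular_period_six_cycles_per_minute(self):
        trace = generate_scenario_trace(ScenarioSpec.named("circular-6"), 30.0)
        # mid-bout, away from the on/off ramps: poses repeat every 10 s
        sel = (trace.times >= 20.0) & (trace.times <= 45.0)
        t_sel = trace.times[sel]
        p_sel = trace.poses[sel]
        shifted = trace.sample_at(t_sel + 10.0)
        assert np.abs(p_sel - shifted).max() < 1e-9

    def test_pitchwise_moving_time_17s_per_cycle(self):
        trace = generate_scenario_trace(ScenarioSpec.named("pitch-large"), 30.0)
        # first cycle starts at 20 s and lasts 52 s (2 down + 15 up + 35 rest)
        sel = (trace.times >= 20.0) & (trace.times < 72.0)
        tx = trace.poses[sel, 0]
        moving = np.abs(np.diff(tx)) > 1e-12
        assert moving.sum() / 30.0 == pytest.approx(17.0, abs=0.1)

    def test_diagonal_timing_and_hold(self):
        trace = generate_scenario_trace(ScenarioSpec.named("diag-up"), 10.0)
        assert np.abs(trace.poses[trace.times < 120.0 - 1e-9]).max() == 0.0
        hold = trace.poses[trace.times >= 210.0]
        assert np.abs(hold - hold[0]).max() < 1e-12
        assert np.linalg.norm(hold[0, :3]) == pytest.approx(
            expected_deflection(3.5, 76.0), abs=1e-9
        )

    def test_timings_scale_with_scan_duration(self):
        sc = ScenarioSpec.named("stepwise-small", scan_duration_s=169.0)  # half scale
        trace = generate_scenario_trace(sc, 30.0)
        assert np.abs(trace.poses[trace.times < 10.0 - 1e-9]).max() == 0.0
        assert np.abs(trace.poses[(trace.times > 10.1) & (trace.times < 27.0)]).max() > 0

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(family="wobble")
        with pytest.raises(ValueError):
            ScenarioSpec.named("wiggle")


class TestExpectedMotionScore:
    def test_still_is_zero(self):
        assert expected_motion_score(ScenarioSpec.named("still")) == 0.0

    def test_all_moving_scenarios_positive(self):
        for name in sorted(SCENARIO_NAMES):
            if name == "still":
                continue
            assert expected_motion_score(ScenarioSpec.named(name)) > 0

    def test_stepwise_closed_form_count_oracle(self):
        """Mean motion score of the stepwise trace equals an independent
        recomputation: per sampled frame pair, the step rotation angle via
        scipy rotation matrices and the 64 mm sphere chord."""
        sc = ScenarioSpec.named("stepwise-large")
        dt = 2.41
        trace = generate_scenario_trace(sc, sample_rate_hz=1.0 / dt)
        scores = []
        for i in range(len(trace) - 1):
            ra = Rotation.from_euler("xyz", trace.poses[i, :3], degrees=True)
            rb = Rotation.from_euler("xyz", trace.poses[i + 1, :3], degrees=True)
            ang = np.rad2deg((ra.inv() * rb).magnitude() * 1.0)
            scores.append(2 * 64 * np.sin(np.deg2rad(ang) / 2))
        oracle = float(np.mean(scores))
        assert expected_motion_score(sc, frame_interval_s=dt) == pytest.approx(
            oracle, rel=1e-9
        )

    def test_circular_converges_with_finer_sampling(self):
        """Total frame-to-frame displacement of the circular trace is a
        discretisation of a smooth path: 10x finer sampling changes the
        summed score by <5%."""
        sc = ScenarioSpec.named("circular-4")
        params = MotionScoreParams()
        coarse = generate_scenario_trace(sc, 1.0)
        fine = generate_scenario_trace(sc, 10.0)
        total_coarse = mean_motion_score(coarse, params) * (len(coarse) - 1)
        total_fine = mean_motion_score(fine, params) * (len(fine) - 1)
        assert total_fine == pytest.approx(total_coarse, rel=0.05)


class TestTracker:
    def _true_trace(self):
        sc = ScenarioSpec.named("stepwise-small", scan_duration_s=154.24)
        return generate_scenario_trace(sc, 30.0)

    def test_zero_noise_reproduces_interpolated_truth(self):
        true = self._true_trace()
        zero = TrackerNoiseModel(
            white_sigma_rot_deg=0, white_sigma_trans_mm=0, jitter_sigma_rot_deg=0
        )
        obs = emulate_tracker(true, zero, seed=1)
        assert np.abs(obs.poses - true.sample_at(obs.times)).max() < 1e-12

    def test_seed_reproducibility(self):
        true = self._true_trace()
        a = emulate_tracker(true, seed=42)
        b = emulate_tracker(true, seed=42)
        c = emulate_tracker(true, seed=43)
        assert np.array_equal(a.poses, b.poses)
        assert not np.array_equal(a.poses, c.poses)

    def test_noise_vanishes_with_magnitude(self):
        true = self._true_trace()
        rmses = []
        for scale in (1.0, 0.1, 0.0):
            nm = TrackerNoiseModel(
                white_sigma_rot_deg=0.05 * scale,
                white_sigma_trans_mm=0.05 * scale,
                jitter_sigma_rot_deg=0.1 * scale,
            )
            obs = emulate_tracker(true, nm, seed=5)
            err = obs.poses - true.sample_at(obs.times)
            rmses.append(np.sqrt((err**2).mean()))
        assert rmses[0] > rmses[1] > rmses[2]
        assert rmses[2] < 1e-12

    def test_lowpass_filtering_recovers_truth(self):
        """1 Hz filtering brings the emulated trace closer to the truth
        (RMSE averaged over 20 seeds)."""
        true = self._true_trace()
        truth = None
        raw_rmse = []
        filt_rmse = []
        for seed in range(20):
            obs = emulate_tracker(true, seed=seed)
            if truth is None:
                truth = true.sample_at(obs.times)
            filt = lowpass_filter_trace(obs, 1.0)
            raw_rmse.append(np.sqrt(((obs.poses - truth) ** 2).mean()))
            filt_rmse.append(np.sqrt(((filt.poses - truth) ** 2).mean()))
        assert np.mean(filt_rmse) < np.mean(raw_rmse)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            TrackerNoiseModel(white_sigma_rot_deg=-0.1)


class TestNavigators:
    def test_identity_pose_matches_reference(self, phantom):
        a = simulate_navigator_volume(phantom, RigidTransform(), 32)
        b = simulate_navigator_volume(phantom, RigidTransform(), 32)
        assert np.array_equal(a, b)
        assert a.max() > 0

    def test_only_fat_components_visible(self, phantom):
        nav = simulate_navigator_volume(phantom, RigidTransform(), 32)
        # deep brain interior (well inside the inner shell surface, away
        # from the neck) must be empty in the fat-only navigator
        pts = _grid_points(32, 200.0)
        inner = phantom.components[1]
        rho_in = np.linalg.norm(
            (pts - np.asarray(inner.center)) / np.asarray(inner.semi_axes), axis=1
        ).reshape(32, 32, 32)
        neck = phantom.select(["neck_fat"])[0]
        rho_n = np.linalg.norm(
            (pts - np.asarray(neck.center)) / np.asarray(neck.semi_axes), axis=1
        ).reshape(32, 32, 32)
        interior = (rho_in < 0.75) & (rho_n > 2.0)
        assert interior.sum() > 100
        assert np.abs(nav[interior]).max() < 1e-3

    def test_translation_moves_center_of_mass(self, rigid_phantom):
        t = np.array([8.0, -5.0, 4.0])
        ref = simulate_navigator_volume(rigid_phantom, RigidTransform(), 32)
        mov = simulate_navigator_volume(rigid_phantom, RigidTransform(0, 0, 0, *t), 32)

        def com(v):
            idx = np.indices(v.shape).reshape(3, -1)
            return (idx * v.ravel()).sum(1) / v.sum()

        voxel = rigid_phantom.fov_mm / 32
        shift_vox = com(mov) - com(ref)
        assert np.abs(shift_vox * voxel - t).max() < voxel / 2

    def test_translation_conserves_fat_signal(self, rigid_phantom):
        ref = simulate_navigator_volume(rigid_phantom, RigidTransform(), 32)
        mov = simulate_navigator_volume(rigid_phantom, RigidTransform(0, 0, 0, 3, -4, 2), 32)
        assert mov.sum() == pytest.approx(ref.sum(), rel=0.01)

    def test_neck_follows_coupled_rotation(self, phantom):
        """Under a pitch pose the scalp displaces per the full rotation,
        the neck per the coupling-scaled rotation (centroid oracle)."""
        pose = RigidTransform(5.7, 0, 0)
        matrix, fov = 48, phantom.fov_mm
        voxel = fov / matrix

        def com_mm(v):
            idx = np.indices(v.shape).reshape(3, -1).astype(float)
            c = (idx * v.ravel()).sum(1) / v.sum()
            return (c - matrix // 2) * voxel

        for tags, angle in (
            (("scalp_fat",), 5.7),
            (("neck_fat",), 5.7 * phantom.neck_coupling),
        ):
            ref = phantom.rasterize(matrix, fov, tags=tags)
            eff_pose = phantom.component_pose(phantom.select(tags)[0], pose)
            mov = phantom.rasterize(matrix, fov, pose=pose, tags=tags)
            expected = RigidTransform(angle, 0, 0).apply(com_mm(ref))
            assert np.abs(com_mm(mov) - expected).max() < voxel / 2

    def test_series_one_volume_per_tr(self, phantom):
        sc = ScenarioSpec.named("still", scan_duration_s=24.1)
        trace = generate_scenario_trace(sc, 10.0)
        series = navigator_series(phantom, trace, tr_s=2.41, matrix=24)
        assert len(series) == 10
        for v in series.volumes[1:]:
            assert np.array_equal(v, series.volumes[0])

    def test_series_distinct_poses_give_distinct_volumes(self, phantom):
        sc = ScenarioSpec.named("stepwise-large", scan_duration_s=154.24)
        trace = generate_scenario_trace(sc, 30.0)
        times = np.array([2.41, 20.0, 45.0])  # rest, "up" target, "down" target
        series = navigator_series(phantom, trace, matrix=24, times=times)
        assert not np.array_equal(series.volumes[0], series.volumes[1])
        assert not np.array_equal(series.volumes[1], series.volumes[2])

    def test_rician_noise_reproducible(self, phantom):
        a = navigator_series(
            phantom,
            generate_scenario_trace(ScenarioSpec.named("still", scan_duration_s=10.0), 10.0),
            tr_s=2.41,
            matrix=16,
            noise_sigma=0.05,
            seed=9,
        )
        b = navigator_series(
            phantom,
            generate_scenario_trace(ScenarioSpec.named("still", scan_duration_s=10.0), 10.0),
            tr_s=2.41,
            matrix=16,
            noise_sigma=0.05,
            seed=9,
        )
        assert np.array_equal(a.volumes, b.volumes)
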