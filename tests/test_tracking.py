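"""Cost terms, Levenberg–Marquardt pose estimation, and Kalman smoothing."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitfit.depth_io import deproject
from gaitfit.geometry import (
    FramePose,
    GroundPlane,
    PoseDelta,
    angular_distance,
    rotation_to_quat_wxyz,
)
from gaitfit.segmentation import SegmentedObservation
from gaitfit.synthetic import (
    GaitScript,
    default_shapes,
    ground_plane,
    render_depth,
    synthesize_gait,
)
from gaitfit.tracking import (
    CostWeights,
    KalmanConfig,
    OptimizerConfig,
    TrackerConfig,
    TrackingError,
    _Residuals,
    cost_additional,
    cost_breakdown,
    cost_foot,
    cost_shank,
    kalman_init,
    kalman_update,
    optimize_limb,
    track_sequence,
    transform_to_model_frame,
)


def _observation_from_truth(frame, labels, foot_id, shank_id):
    cloud = deproject(frame)
    lab = labels[cloud.pixel_index[:, 0], cloud.pixel_index[:, 1]]
    return SegmentedObservation(
        foot_points=cloud.points[lab == foot_id],
        shank_points=cloud.points[lab == shank_id],
        foot_pixels=cloud.pixel_index[lab == foot_id],
        shank_pixels=cloud.pixel_index[lab == shank_id],
        method="expansion",
    )


@pytest.fixture(scope="module")
def posed_scene():
    """A mid-stance frame with truth-labeled observations for the right limb."""
    from .conftest import TEST_INTRINSICS

    shapes = default_shapes()
    # splayed calibration-stance script: the camera sees back and side of the
    # foot, which makes the full orientation observable for a single frame
    truth = synthesize_gait(GaitScript(n_cycles=1, toe_out_deg=12.0), shapes)
    k = 48  # mid-stance, left foot flat at mid-range
    poses = {s: truth.poses[s][k] for s in truth.poses}
    frame, labels = render_depth(poses, shapes, truth.plane, TEST_INTRINSICS)
    obs = _observation_from_truth(frame, labels, 2, 3)
    return shapes, truth.plane, poses["left"], obs, TEST_INTRINSICS


class TestTransform:
    def test_identity_pose_zero_delta_is_identity(self):
        pose = FramePose(
            foot_rotation=np.array([1.0, 0, 0, 0]),
            shank_angles=np.zeros(2),
            translation=np.zeros(3),
        )
        p = np.array([10.0, -5.0, 30.0])
        np.testing.assert_allclose(transform_to_model_frame(p, pose), p)

    def test_point_at_translation_maps_to_origin(self):
        pose = FramePose(
            foot_rotation=np.array([1.0, 0, 0, 0]),
            shank_angles=np.zeros(2),
            translation=np.array([50.0, 20.0, 600.0]),
        )
        np.testing.assert_allclose(
            transform_to_model_frame(pose.translation.copy(), pose), np.zeros(3)
        )

    def test_inverse_round_trip(self, rng):
        pose = FramePose(
            foot_rotation=rotation_to_quat_wxyz(Rotation.random(random_state=3)),
            shank_angles=rng.normal(size=2),
            translation=rng.normal(scale=100, size=3),
        )
        delta = PoseDelta(
            foot_rotvec=rng.normal(scale=0.1, size=3), dt=rng.normal(scale=5, size=3)
        )
        p = rng.normal(scale=200, size=3)
        pm = transform_to_model_frame(p, pose, delta)
        # invert: p = R̃ ΔRᵀ pm + (t̃ + Δt)
        r_eff = (
            pose.foot_matrix()
            @ Rotation.from_rotvec(delta.foot_rotvec).as_matrix().T
        )
        back = r_eff @ pm + pose.translation + delta.dt
        np.testing.assert_allclose(back, p, atol=1e-9)


class TestCostTerms:
    def test_on_surface_points_give_zero_distance_cost(self, posed_scene):
        shapes, plane, pose, obs, K = posed_scene
        bd = cost_breakdown(
            obs, shapes["left"], pose, PoseDelta.identity(), None, plane, K
        )
        n = len(obs.foot_points) + len(obs.shank_points)
        # rendered points sit on the model surface up to pixel quantization
        assert (bd.E_dist_foot + bd.E_dist_shank) / n < 1.0

    def test_model_above_ground_has_zero_ground_cost(self, posed_scene):
        shapes, plane, pose, obs, K = posed_scene
        lifted = pose.copy()
        lifted.translation = lifted.translation + np.array([0.0, -50.0, 0.0])
        bd = cost_foot(obs, shapes["left"].foot, lifted, PoseDelta.identity(), plane, K)
        assert bd.E_ground == 0.0

    def test_single_key_point_below_plane_sums_its_depth(self, posed_scene):
        shapes, plane, pose, obs, K = posed_scene
        kp = np.array([[0.0, 0.0, -shapes["left"].foot.h]])  # sole center
        sole_cam = pose.foot_matrix() @ kp[0] + pose.translation
        # raise the floor so the sole key point sits 5 mm below it
        plane5 = GroundPlane(normal=plane.normal, point=sole_cam + 5.0 * plane.normal)
        bd = cost_foot(
            obs, shapes["left"].foot, pose, PoseDelta.identity(), plane5, K, keypoints=kp
        )
        assert bd.E_ground == pytest.approx(5.0, abs=1e-6)

    def test_orientation_zero_when_vertical_one_when_horizontal(self, posed_scene):
        shapes, plane, pose, obs, K = posed_scene
        plane_flat = ground_plane()
        vertical = FramePose.neutral(pose.translation)
        bd = cost_shank(
            obs, shapes["left"].shank, vertical, PoseDelta.identity(), plane_flat, K
        )
        assert bd.E_orientation == pytest.approx(0.0, abs=1e-12)
        horizontal = vertical.copy()
        horizontal.shank_angles = np.array([np.pi / 2, 0.0])
        bd = cost_shank(
            obs, shapes["left"].shank, horizontal, PoseDelta.identity(), plane_flat, K
        )
        assert bd.E_orientation == pytest.approx(1.0, abs=1e-12)

    def test_limit_zero_in_neutral_stance(self):
        pose = FramePose.neutral([0, 0, 600.0])
        bd = cost_additional(pose, PoseDelta.identity(), None)
        assert bd.E_limit == pytest.approx(0.0, abs=1e-12)

    def test_temporal_terms(self):
        pose = FramePose.neutral([0, 0, 600.0])
        bd = cost_additional(pose, PoseDelta.identity(), pose.copy())
        assert bd.E_temporal_rot == pytest.approx(0.0, abs=1e-7)
        assert bd.E_temporal_trans == pytest.approx(0.0, abs=1e-9)
        moved = pose.copy()
        moved.translation = moved.translation + np.array([0.0, 0.0, 10.0])
        bd = cost_additional(moved, PoseDelta.identity(), pose)
        assert bd.E_temporal_trans == pytest.approx(10.0)
        assert bd.E_temporal_rot == pytest.approx(0.0, abs=1e-7)

    def test_empty_foot_observation_flagged(self, posed_scene):
        shapes, plane, pose, obs, K = posed_scene
        empty = SegmentedObservation(
            foot_points=np.empty((0, 3)),
            shank_points=obs.shank_points,
            foot_pixels=np.empty((0, 2), dtype=int),
            shank_pixels=obs.shank_pixels,
            method="expansion",
        )
        bd = cost_foot(empty, shapes["left"].foot, pose, PoseDelta.identity(), plane, K)
        assert bd.foot_empty
        assert bd.E_dist_foot == 0.0 and bd.E_silhouette_foot == 0.0


class TestOptimization:
    def _perturbed(self, pose, rng, angle_deg=5.0, trans_mm=10.0):
        ax = rng.normal(size=3)
        ax /= np.linalg.norm(ax)
        r = Rotation.from_rotvec(np.radians(angle_deg) * ax).as_matrix() @ pose.foot_matrix()
        off = rng.normal(size=3)
        off = off / np.linalg.norm(off) * trans_mm
        return FramePose(
            rotation_to_quat_wxyz(r),
            pose.shank_angles + np.radians([3.0, -2.0]),
            pose.translation + off,
        )

    def test_perturbed_initialization_recovers_pose(self, posed_scene, rng):
        shapes, plane, pose_true, obs, K = posed_scene
        init = self._perturbed(pose_true, rng)
        pose, _, _, _ = optimize_limb(
            obs, shapes["left"], init, None, plane, CostWeights(), OptimizerConfig(), K
        )
        assert np.degrees(angular_distance(pose.foot_matrix(), pose_true.foot_matrix())) < 2.0
        assert np.linalg.norm(pose.translation - pose_true.translation) < 5.0

    def test_descent_property(self, posed_scene, rng):
        shapes, plane, pose_true, obs, K = posed_scene
        weights = CostWeights()
        init = self._perturbed(pose_true, rng, angle_deg=8.0, trans_mm=20.0)
        e0 = cost_breakdown(
            obs, shapes["left"], init, PoseDelta.identity(), None, plane, K
        ).total(weights)
        pose, bd, _, _ = optimize_limb(
            obs, shapes["left"], init, None, plane, weights, OptimizerConfig(), K
        )
        assert bd.total(weights) <= e0 + 1e-6

    def test_already_optimal_initialization_stops_quickly(self, posed_scene):
        shapes, plane, pose_true, obs, K = posed_scene
        opt = OptimizerConfig()
        pose1, _, _, _ = optimize_limb(
            obs, shapes["left"], pose_true, None, plane, CostWeights(), opt, K
        )
        pose2, _, _, it = optimize_limb(
            obs, shapes["left"], pose1, None, plane, CostWeights(), opt, K
        )
        assert it <= 2
        assert np.linalg.norm(pose2.translation - pose1.translation) < 0.5
        assert angular_distance(pose2.foot_matrix(), pose1.foot_matrix()) < 0.01

    def test_finite_difference_jacobian_consistency(self, posed_scene, rng):
        """Forward-difference Jacobian used by LM vs. central differences.

        The linearization point is kept away from the cost kinks: the
        previous-frame pose differs from the current one (temporal terms are
        absolute values) and the model is lifted clear of the floor (the
        ground term is one-sided).
        """
        shapes, plane, pose_true, obs, K = posed_scene
        pose = self._perturbed(pose_true, rng, angle_deg=4.0, trans_mm=6.0)
        pose.translation = pose.translation + np.array([0.0, -15.0, 0.0])
        prev = self._perturbed(pose_true, rng, angle_deg=3.0, trans_mm=8.0)
        fn = _Residuals(obs, shapes["left"], prev, plane, CostWeights(), K, 200)
        r0 = fn(pose, np.zeros(8))
        steps = np.array([1e-4] * 3 + [1e-2] * 3 + [1e-4] * 2)
        for j in range(8):
            e = np.zeros(8)
            e[j] = steps[j]
            forward = (fn(pose, e) - r0) / steps[j]
            central = (fn(pose, e) - fn(pose, -e)) / (2 * steps[j])
            rel = np.abs(forward - central) / np.maximum(np.abs(central), 1.0)
            # the cost is piecewise smooth (min over patches, NN pixel
            # queries): isolated residuals may sit on a switch surface
            assert (rel < 0.05).mean() > 0.99

    def test_empty_observation_carries_pose_forward(self, posed_scene):
        shapes, plane, pose, obs, K = posed_scene
        empty = SegmentedObservation(
            foot_points=np.empty((0, 3)),
            shank_points=np.empty((0, 3)),
            foot_pixels=np.empty((0, 2), dtype=int),
            shank_pixels=np.empty((0, 2), dtype=int),
            method="contour",
            degenerate=True,
        )
        out, _, _, it = optimize_limb(
            empty, shapes["left"], pose, None, plane, CostWeights(), OptimizerConfig(), K
        )
        assert it == 0
        np.testing.assert_array_equal(out.translation, pose.translation)


class TestKalman:
    def test_constant_velocity_tracks_within_one_mm(self):
        cfg = KalmanConfig()
        pose = FramePose.neutral([0.0, 0.0, 500.0])
        state = kalman_init(pose, cfg)
        dt = 0.02
        errs = []
        for k in range(1, 80):
            meas = FramePose.neutral([0.0, 0.0, 500.0 + 10.0 * k])
            smoothed, state = kalman_update(state, meas, dt, cfg)
            errs.append(abs(smoothed.translation[2] - (500.0 + 10.0 * k)))
        assert max(errs[40:]) < 1.0  # steady state

    def test_spike_is_gated_out(self):
        cfg = KalmanConfig()
        pose = FramePose.neutral([0.0, 0.0, 500.0])
        state = kalman_init(pose, cfg)
        for _ in range(30):
            smoothed, state = kalman_update(state, pose, 0.02, cfg)
        spike = FramePose.neutral([0.0, 0.0, 700.0])  # 200 mm outlier
        smoothed, state = kalman_update(state, spike, 0.02, cfg)
        assert abs(smoothed.translation[2] - 500.0) < 10.0

    def test_zero_measurement_noise_limit_follows_measurement(self):
        cfg = KalmanConfig(meas_noise_trans=1e-4, meas_noise_rot=1e-6, gate_chi2=1e12)
        pose = FramePose.neutral([0.0, 0.0, 500.0])
        state = kalman_init(pose, cfg)
        meas = FramePose.neutral([3.0, -2.0, 512.0])
        smoothed, state = kalman_update(state, meas, 0.02, cfg)
        np.testing.assert_allclose(smoothed.translation, meas.translation, atol=1e-2)

    def test_rejects_nonpositive_dt(self):
        cfg = KalmanConfig()
        state = kalman_init(FramePose.neutral([0, 0, 500.0]), cfg)
        with pytest.raises(ValueError):
            kalman_update(state, FramePose.neutral([0, 0, 500.0]), 0.0, cfg)


class TestTrackSequence:
    def test_static_sequence_low_pose_variance(self, intrinsics):
        shapes = default_shapes()
        truth = synthesize_gait(GaitScript(n_cycles=1), shapes)
        poses = {s: truth.poses[s][0] for s in truth.poses}
        rng = np.random.default_rng(0)
        frames = [
            render_depth(poses, shapes, truth.plane, intrinsics, timestamp=k / 50.0, rng=rng)[0]
            for k in range(15)
        ]
        traj = track_sequence(frames, shapes, TrackerConfig())
        for side in ("left", "right"):
            g = traj[traj.side == side].iloc[5:]  # after settling
            assert g[["tx", "ty", "tz"]].std().max() < 2.0
            assert np.degrees(g[["theta_x", "theta_y"]].std()).max() < 2.0

    def test_first_frame_single_group_aborts(self, intrinsics):
        shapes = default_shapes()
        truth = synthesize_gait(GaitScript(n_cycles=1), shapes)
        frames = [
            render_depth(
                {"left": truth.poses["left"][0]},
                {"left": shapes["left"]},
                truth.plane,
                intrinsics,
            )[0]
        ]
        with pytest.raises(TrackingError):
            track_sequence(frames, shapes, TrackerConfig())

    def test_occluded_limb_does_not_crash(self, intrinsics):
        shapes = default_shapes()
        truth = synthesize_gait(GaitScript(n_cycles=1), shapes)
        rng = np.random.default_rng(0)
        frames = []
        n = 28
        for k in range(n):
            poses = {s: truth.poses[s][k] for s in truth.poses}
            if 12 <= k < 17:  # one limb fully occluded for 5 frames
                poses = {"right": poses["right"]}
            frames.append(
                render_depth(
                    poses,
                    {s: shapes[s] for s in poses},
                    truth.plane,
                    intrinsics,
                    timestamp=k / 50.0,
                    rng=rng,
                )[0]
            )
        traj = track_sequence(frames, shapes, TrackerConfig())
        assert len(traj) == 2 * n  # both limbs reported for every frame
        g = traj[traj.side == "left"].reset_index(drop=True)
        err = abs(g.loc[n - 1, "tz"] - truth.poses["left"][n - 1].translation[2])
        assert err < 50.0  # recovered after the occlusion
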