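"""Ground-plane estimation, limb clustering, and foot/shank labeling."""

import numpy as np
import pytest

from gaitfit.depth_io import PointCloud, deproject
from gaitfit.segmentation import (
    GroundPlaneError,
    LimbGroup,
    SegmentationConfig,
    above_ground,
    cluster_and_group,
    contour_segmentation,
    estimate_ground_plane,
    expansion_segmentation,
)
from gaitfit.synthetic import GaitScript, default_shapes, render_depth, synthesize_gait
from gaitfit.tracking import (
    OptimizerConfig,
    CostWeights,
    optimize_limb,
)


@pytest.fixture(scope="module")
def standing_scene():
    """One noiseless standing frame with truth labels."""
    from .conftest import TEST_INTRINSICS

    shapes = default_shapes()
    script = GaitScript(n_cycles=1)
    truth = synthesize_gait(script, shapes)
    poses = {s: truth.poses[s][0] for s in truth.poses}
    frame, labels = render_depth(poses, shapes, truth.plane, TEST_INTRINSICS)
    return shapes, truth, poses, frame, labels, TEST_INTRINSICS


def _preprocessed(frame, config, seed=0):
    cloud = deproject(frame)
    keep = cloud.points[:, 2] <= config.max_range
    cloud = PointCloud(cloud.points[keep], cloud.pixel_index[keep])
    plane = estimate_ground_plane(cloud, config, np.random.default_rng(seed))
    return cloud, plane


class TestGroundPlane:
    def test_noiseless_scene_recovers_normal_within_one_degree(self, standing_scene):
        _, truth, _, frame, _, _ = standing_scene
        config = SegmentationConfig()
        _, plane = _preprocessed(frame, config)
        cos = np.clip(plane.normal @ truth.plane.normal, -1, 1)
        assert np.degrees(np.arccos(cos)) < 1.0

    def test_noisy_floor_recovers_normal_within_three_degrees(self, rng):
        pts = np.column_stack(
            [
                rng.uniform(-400, 400, 4000),
                100.0 + rng.normal(0, 2.0, 4000),
                rng.uniform(200, 1000, 4000),
            ]
        )
        cloud = PointCloud(pts, np.zeros((len(pts), 2), dtype=int))
        plane = estimate_ground_plane(cloud, SegmentationConfig(), rng)
        cos = np.clip(plane.normal @ np.array([0.0, -1.0, 0.0]), -1, 1)
        assert np.degrees(np.arccos(cos)) < 3.0

    def test_unstructured_cloud_fails(self, rng):
        pts = rng.uniform(-500, 500, size=(600, 3))
        cloud = PointCloud(pts, np.zeros((len(pts), 2), dtype=int))
        with pytest.raises(GroundPlaneError):
            estimate_ground_plane(cloud, SegmentationConfig(), rng)


class TestClusterAndGroup:
    def test_two_separated_legs_match_generator_sides(self, standing_scene):
        _, truth, _, frame, labels, _ = standing_scene
        config = SegmentationConfig()
        cloud, plane = _preprocessed(frame, config)
        fg = above_ground(cloud, plane, config.surface_tolerance)
        cl = cluster_and_group(fg, config)
        assert not cl.single_group
        for side, truth_ids in (("left", (2, 3)), ("right", (4, 5))):
            g = getattr(cl, side)
            tl = labels[g.pixels[:, 0], g.pixels[:, 1]]
            assert np.isin(tl, truth_ids).mean() > 0.95

    def test_touching_legs_flag_single_group(self, intrinsics):
        shapes = default_shapes()
        script = GaitScript(n_cycles=1, step_width=60.0)  # narrow walking base
        truth = synthesize_gait(script, shapes)
        # frame where the swing foot passes the stance foot: shanks in contact
        z = np.array(
            [
                [truth.poses[s][k].translation[2] for k in range(len(truth.times))]
                for s in ("left", "right")
            ]
        )
        gait_start = int(script.lead_in_s * script.fps)
        k = gait_start + int(np.argmin(np.abs(z[0] - z[1])[gait_start:]))
        frame, _ = render_depth(
            {s: truth.poses[s][k] for s in truth.poses}, shapes, truth.plane, intrinsics
        )
        config = SegmentationConfig()
        cloud, plane = _preprocessed(frame, config)
        fg = above_ground(cloud, plane, config.surface_tolerance)
        cl = cluster_and_group(fg, config)
        assert cl.single_group
        assert cl.merged is not None

    def test_single_leg_flags_single_group(self, intrinsics):
        shapes = default_shapes()
        script = GaitScript(n_cycles=1)
        truth = synthesize_gait(script, shapes)
        frame, _ = render_depth(
            {"left": truth.poses["left"][0]},
            {"left": shapes["left"]},
            truth.plane,
            intrinsics,
        )
        config = SegmentationConfig()
        cloud, plane = _preprocessed(frame, config)
        fg = above_ground(cloud, plane, config.surface_tolerance)
        cl = cluster_and_group(fg, config)
        assert cl.single_group

    def test_empty_cloud(self):
        cl = cluster_and_group(
            PointCloud(np.empty((0, 3)), np.empty((0, 2), dtype=int)),
            SegmentationConfig(),
        )
        assert cl.single_group and cl.cluster_count_raw == 0


class TestExpansionSegmentation:
    def test_stopping_rule_with_scripted_costs(self):
        """The sweep stops at the first strict cost increase and returns the
        previous line; the cost sequence is evaluated strictly in order."""
        rows = np.repeat(np.arange(100, 140), 5)
        pixels = np.column_stack([rows, np.tile(np.arange(5), 40)])
        points = np.zeros((len(rows), 3))
        group = LimbGroup(points, pixels)
        true_row = 120
        seen = []

        def optimizer(obs):
            seen.append(obs.separation_row)
            return None, abs(obs.separation_row - true_row)

        obs, _, cost = expansion_segmentation(
            group, optimizer, SegmentationConfig(r_initial=10)
        )
        assert seen == sorted(seen, reverse=True)  # swept upward one row at a time
        assert obs.separation_row == true_row
        assert cost == 0
        # the returned line's cost is <= its successor's (the one that stopped it)
        assert cost <= abs(seen[-1] - true_row)

    def test_degenerate_small_group_all_foot(self):
        pixels = np.column_stack([np.repeat(np.arange(100, 105), 3), np.tile(np.arange(3), 5)])
        group = LimbGroup(np.zeros((len(pixels), 3)), pixels)
        obs, _, _ = expansion_segmentation(
            group, lambda o: (None, 0.0), SegmentationConfig(r_initial=10)
        )
        assert obs.degenerate
        assert len(obs.foot_pixels) == len(pixels)
        assert len(obs.shank_pixels) == 0

    def test_separation_row_near_true_ankle(self, standing_scene):
        shapes, truth, poses, frame, labels, K = standing_scene
        config = SegmentationConfig()
        cloud, plane = _preprocessed(frame, config)
        fg = above_ground(cloud, plane, config.surface_tolerance)
        cl = cluster_and_group(fg, config)
        side = "right"
        group = getattr(cl, side)
        pose0 = poses[side]

        from gaitfit.geometry import PoseDelta
        from gaitfit.tracking import cost_breakdown

        def optimizer(obs):
            pose, _, _, _ = optimize_limb(
                obs, shapes[side], pose0, None, plane,
                CostWeights(), OptimizerConfig(), K, max_points=200, n_max=8,
            )
            bd = cost_breakdown(
                obs, shapes[side], pose, PoseDelta.identity(), None, plane, K
            )
            return pose, bd.total(CostWeights())

        obs, _, _ = expansion_segmentation(group, optimizer, config)
        # true ankle row: boundary between shank (5) and foot (4) truth labels
        tl = labels[group.pixels[:, 0], group.pixels[:, 1]]
        ankle_row = group.pixels[tl == 5, 0].max()
        assert abs(obs.separation_row - ankle_row) <= 3

        # labeled foot pixel count close to the generator's foot mask
        n_truth_foot = int((tl == 4).sum())
        assert abs(len(obs.foot_pixels) - n_truth_foot) <= 0.15 * n_truth_foot

    def test_foot_and_shank_pixels_disjoint(self, standing_scene):
        shapes, truth, poses, frame, _, K = standing_scene
        config = SegmentationConfig()
        cloud, plane = _preprocessed(frame, config)
        fg = above_ground(cloud, plane, config.surface_tolerance)
        cl = cluster_and_group(fg, config)
        obs, _, _ = expansion_segmentation(
            cl.left, lambda o: (None, float(len(o.shank_pixels))), config
        )
        foot = set(map(tuple, obs.foot_pixels))
        shank = set(map(tuple, obs.shank_pixels))
        assert not foot & shank


class TestContourSegmentation:
    def test_true_pose_labels_most_foot_pixels(self, standing_scene):
        shapes, truth, poses, frame, labels, K = standing_scene
        config = SegmentationConfig()
        cloud, _ = _preprocessed(frame, config)
        side = "right"
        obs = contour_segmentation(
            cloud, shapes[side].foot, shapes[side].shank, poses[side], K, config
        )
        truth_foot = {
            tuple(px)
            for px in np.argwhere(labels == 4)
        }
        labeled_foot = set(map(tuple, obs.foot_pixels))
        assert len(labeled_foot & truth_foot) >= 0.85 * len(truth_foot)
        assert not set(map(tuple, obs.shank_pixels)) & labeled_foot

    def test_off_surface_points_inside_hull_excluded(self, standing_scene):
        shapes, truth, poses, frame, _, K = standing_scene
        config = SegmentationConfig()
        side = "right"
        pose = poses[side]
        # a point 100 mm in front of the model surface, projecting inside the hull
        from gaitfit.depth_io import project

        p = pose.translation + np.array([0.0, 20.0, -100.0])
        px = np.round(project(p[None], K)).astype(int)
        cloud = PointCloud(np.array([p]), px)
        obs = contour_segmentation(
            cloud, shapes[side].foot, shapes[side].shank, pose, K, config
        )
        assert len(obs.foot_points) == 0 and len(obs.shank_points) == 0

    def test_empty_cloud_no_crash(self, standing_scene):
        shapes, truth, poses, frame, _, K = standing_scene
        obs = contour_segmentation(
            PointCloud(np.empty((0, 3)), np.empty((0, 2), dtype=int)),
            shapes["left"].foot,
            shapes["left"].shank,
            poses["left"],
            K,
            SegmentationConfig(),
        )
        assert obs.degenerate
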