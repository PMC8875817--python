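"""Synthetic back-view walking scenes with full ground truth.

The generator animates the same rigid foot-shank models the tracker fits, so
the whole pipeline can be validated by parameter recovery.  Kinematics mimic
treadmill-style walking seen from a camera mounted low (10 cm) behind the
walker: during stance the foot translates backward at belt speed
``2·step_length / cycle_time``; during swing it advances by a smooth
monotone profile with a clearance arc and a plantarflexion pulse after
toe-off.  Left and right are half a cycle out of phase and laterally offset
by the step width, so at every heel-strike the inter-foot displacement equals
the scripted step length/width exactly — these are the analytic cycle truths.

Rendering is a z-buffer rasterization of densely sampled model surfaces over
an analytic ground plane, with optional Gaussian depth noise, dropout holes
and near-range row fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .depth_io import CameraIntrinsics, DepthFrame, PointCloud
from .gait import GaitCycle, GaitEvent
from .geometry import (
    NEUTRAL_ROTATION,
    FootShape,
    FramePose,
    GroundPlane,
    ShankShape,
    rotation_to_quat_wxyz,
    sample_foot_surface,
    sample_shank_surface,
)
from .tracking import LimbShapes

__all__ = [
    "GaitScript",
    "SceneTruth",
    "default_shapes",
    "synthesize_gait",
    "render_depth",
    "render_sequence",
]

#: Camera height above the floor (mm); the study setup mounts the depth
#: camera 10 cm above the walking surface.
CAMERA_HEIGHT = 100.0


@dataclass(frozen=True)
class GaitScript:
    """Scripted walking conditions; the seed fixes all randomness."""

    cycle_time: float = 1.2  # s
    stance_ratio: float = 0.6
    step_length: float = 500.0  # mm
    step_width: float = 100.0  # mm
    foot_clearance: float = 30.0  # mm, peak swing height of the sole
    plantarflexion_deg: float = 15.0  # peak toe-down pitch after toe-off
    shank_tilt_deg: float = 12.0  # sagittal shank oscillation amplitude
    toe_out_deg: float = 7.0  # outward foot yaw (foot progression angle)
    fps: float = 50.0
    n_cycles: int = 3
    ap_far: float = 950.0  # mm, ankle AP position at heel-strike
    lead_in_s: float = 0.6  # static standing phase before gait (calibration stance)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.stance_ratio < 1:
            raise ValueError("stance_ratio must be in (0, 1)")
        if self.fps <= 0 or self.cycle_time <= 0 or self.n_cycles < 1:
            raise ValueError("fps, cycle_time and n_cycles must be positive")
        if self.lead_in_s < 0:
            raise ValueError("lead_in_s must be non-negative")


@dataclass
class SceneTruth:
    """Ground truth accompanying a synthetic sequence."""

    poses: Dict[str, List[FramePose]]  # per side, per frame
    times: np.ndarray
    plane: GroundPlane
    events: List[GaitEvent]
    cycles: List[GaitCycle]
    label_masks: Optional[List[np.ndarray]] = None  # 0 bg, 1 ground, 2/3 L foot/shank, 4/5 R


def default_shapes() -> Dict[str, LimbShapes]:
    """Adult-sized limb parameters (mm), both sides identical.

    A slim adult build: heel radius 35, foot length 250, foot height 70,
    calcaneus bulge 12; ankle radius 35 tapering to 45 over a 350 mm shank.
    """
    foot = FootShape(r=35.0, l=250.0, h=70.0, d=12.0)
    shank = ShankShape(r1=35.0, r2=45.0, s=350.0)
    return {"left": LimbShapes(foot, shank), "right": LimbShapes(foot, shank)}


def ground_plane() -> GroundPlane:
    """Floor for the default camera: y = +CAMERA_HEIGHT, normal toward −y."""
    return GroundPlane(normal=(0.0, -1.0, 0.0), point=(0.0, CAMERA_HEIGHT, 0.0))


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _side_trajectory(
    t: np.ndarray, phase_offset: float, script: GaitScript, shapes: LimbShapes
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(ap, height, foot_pitch, shank_tilt) for one side over time.

    ``ap`` is the ankle z (camera frame); ``height`` the sole clearance above
    the floor; ``pitch`` the plantarflexion angle (radians, positive =
    toe-down); ``tilt`` the sagittal shank angle θx.
    """
    T = script.cycle_time
    Ts = script.stance_ratio * T
    L = script.step_length
    belt = 2.0 * L / T  # mm/s
    tau = t - script.lead_in_s  # gait time; negative during the lead-in
    phase = np.mod(tau / T + phase_offset, 1.0)
    stance = phase < script.stance_ratio

    ap = np.empty_like(t, dtype=float)
    ap[stance] = script.ap_far - belt * phase[stance] * T
    swing_u = (phase[~stance] - script.stance_ratio) / (1.0 - script.stance_ratio)
    ap_to = script.ap_far - belt * Ts
    ap[~stance] = ap_to + (script.ap_far - ap_to) * _smoothstep(swing_u)

    height = np.zeros_like(t, dtype=float)
    height[~stance] = script.foot_clearance * np.sin(np.pi * swing_u)

    pitch = np.zeros_like(t, dtype=float)
    # plantarflexion pulse over the first half of swing
    pitch[~stance] = np.radians(script.plantarflexion_deg) * np.sin(
        np.pi * np.clip(swing_u / 0.5, 0.0, 1.0)
    )

    tilt = np.radians(script.shank_tilt_deg) * np.sin(2.0 * np.pi * phase)

    if script.lead_in_s > 0:
        # standing calibration stance, then a smooth first step into the gait:
        # the leading (left) foot swings forward to its heel-strike position
        # while the trailing foot slides back to its mid-stance position
        Tt = min(0.4 * T, script.lead_in_s)  # transition duration
        ap_stand = script.ap_far - 0.7 * L
        ap_gait_start = script.ap_far if phase_offset == 0.0 else script.ap_far - L
        standing = tau <= -Tt
        trans = (~standing) & (tau < 0)
        ap[standing] = ap_stand
        height[standing] = 0.0
        pitch[standing] = 0.0
        tilt[standing] = 0.0
        u = (tau[trans] + Tt) / Tt
        ap[trans] = ap_stand + (ap_gait_start - ap_stand) * _smoothstep(u)
        height[trans] = (
            script.foot_clearance * np.sin(np.pi * u) if phase_offset == 0.0 else 0.0
        )
        pitch[trans] = 0.0
        tilt[trans] = 0.0
    return ap, height, pitch, tilt


def synthesize_gait(
    script: GaitScript, shapes: Optional[Dict[str, LimbShapes]] = None
) -> SceneTruth:
    """Pose trajectories, events and per-cycle truths for a scripted gait.

    The AP series of each side has exactly one maximum (heel-strike) and one
    minimum (toe-off) per cycle.  Raises on an infeasible script (clearance
    exceeding the shank length).
    """
    shapes = shapes or default_shapes()
    if script.foot_clearance >= min(s.shank.s for s in shapes.values()):
        raise ValueError("foot clearance exceeds shank length; script infeasible")
    n = int(round((script.lead_in_s + script.n_cycles * script.cycle_time) * script.fps))
    t = np.arange(n) / script.fps
    plane = ground_plane()

    poses: Dict[str, List[FramePose]] = {}
    events: List[GaitEvent] = []
    phase_off = {"left": 0.0, "right": 0.5}
    # calibration stance is wider than the walking base so the limbs are
    # cleanly separated on the first frame; blended to the walking width
    # during the first step
    stand_width = max(script.step_width, 170.0)
    tau = t - script.lead_in_s
    Tt = min(0.4 * script.cycle_time, script.lead_in_s) if script.lead_in_s > 0 else 0.0
    if Tt > 0:
        blend = _smoothstep((tau + Tt) / Tt)
    else:
        blend = np.ones_like(t)
    half_width = (stand_width + (script.step_width - stand_width) * blend) / 2.0

    for side in ("left", "right"):
        ap, height, pitch, tilt = _side_trajectory(
            t, phase_off[side], script, shapes[side]
        )
        lateral = {-1: -half_width, 1: half_width}[-1 if side == "left" else 1]
        foot_h = shapes[side].foot.h
        # outward yaw about the vertical model axis (toe-out), mirrored per side
        yaw = np.radians(script.toe_out_deg) * (-1.0 if side == "left" else 1.0)
        side_poses = []
        for k in range(n):
            # plantarflexion = toe-down rotation about the lateral (x) axis
            rf = (
                NEUTRAL_ROTATION
                @ Rotation.from_rotvec([0.0, 0.0, yaw]).as_matrix()
                @ Rotation.from_rotvec([pitch[k], 0.0, 0.0]).as_matrix()
            )
            pose = FramePose(
                foot_rotation=rotation_to_quat_wxyz(rf),
                shank_angles=np.array([tilt[k], 0.0]),
                translation=np.array(
                    [lateral[k], CAMERA_HEIGHT - foot_h - height[k], ap[k]]
                ),
            )
            side_poses.append(pose)
        poses[side] = side_poses

        # analytic events: HS at gait phase 0, TO at phase = stance_ratio
        T = script.cycle_time
        for c in range(script.n_cycles + 1):
            ths = script.lead_in_s + (c - phase_off[side]) * T
            tto = ths + script.stance_ratio * T
            for kind, tev in (("HS", ths), ("TO", tto)):
                if script.lead_in_s <= tev <= t[-1]:
                    events.append(
                        GaitEvent(
                            kind=kind,
                            side=side,
                            frame=int(round(tev * script.fps)),
                            time=float(tev),
                        )
                    )
    events.sort(key=lambda e: e.time)

    cycles: List[GaitCycle] = []
    for side in ("left", "right"):
        mine = [e for e in events if e.side == side]
        hs = [e for e in mine if e.kind == "HS"]
        tos = [e for e in mine if e.kind == "TO"]
        for a, b in zip(hs[:-1], hs[1:]):
            inner = [x for x in tos if a.time < x.time < b.time]
            if inner:
                cycles.append(
                    GaitCycle(
                        side=side,
                        hs_start=a,
                        to=inner[0],
                        hs_end=b,
                        step_length=script.step_length,
                        step_width=script.step_width,
                    )
                )
    cycles.sort(key=lambda c: c.hs_start.time)
    return SceneTruth(poses=poses, times=t, plane=plane, events=events, cycles=cycles)


# ---------------------------------------------------------------------------
# rendering

_LABELS = {("left", "foot"): 2, ("left", "shank"): 3, ("right", "foot"): 4, ("right", "shank"): 5}


def render_depth(
    poses: Dict[str, FramePose],
    shapes: Dict[str, LimbShapes],
    plane: GroundPlane,
    intrinsics: CameraIntrinsics,
    timestamp: float = 0.0,
    noise_sigma: float = 0.0,
    dropout_fraction: float = 0.0,
    fragment_below_mm: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    max_range: float = 1100.0,
    spacing: float = 1.2,
    grazing_cos: float = 0.15,
) -> Tuple[DepthFrame, np.ndarray]:
    """Z-buffer render of both limbs over the floor; returns (frame, labels).

    Surfaces are sampled at ``spacing`` mm (≥1 sample per projected pixel at
    the near range for the default intrinsics).  Labels: 0 invalid/empty,
    1 ground, 2/3 left foot/shank, 4/5 right foot/shank.  ``noise_sigma`` adds
    per-pixel Gaussian depth noise; ``dropout_fraction`` zeroes random valid
    pixels; ``fragment_below_mm`` removes random row bands from limb pixels
    nearer than the threshold (near-range fragmentation artifact).
    """
    rng = rng or np.random.default_rng(0)
    h, w = intrinsics.height, intrinsics.width
    depth = np.full((h, w), np.inf)
    labels = np.zeros((h, w), dtype=np.uint8)

    # analytic ground: intersect each pixel ray with the floor plane
    vv, uu = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dirs = np.stack(
        [
            (uu - intrinsics.cx) / intrinsics.fx,
            (vv - intrinsics.cy) / intrinsics.fy,
            np.ones_like(uu, dtype=float),
        ],
        axis=-1,
    )
    denom = dirs @ plane.normal
    tparam = (plane.point @ plane.normal) / np.where(np.abs(denom) < 1e-9, np.nan, denom)
    zg = tparam  # z-coordinate of the intersection (dir_z = 1)
    ok = np.isfinite(zg) & (zg > 0) & (zg <= max_range)
    depth[ok] = zg[ok]
    labels[ok] = 1

    for side, pose in poses.items():
        for part in ("foot", "shank"):
            if part == "foot":
                pts, normals = sample_foot_surface(
                    shapes[side].foot, spacing, with_normals=True
                )
                r = pose.foot_matrix()
            else:
                pts, normals = sample_shank_surface(
                    shapes[side].shank, spacing, with_normals=True
                )
                r = pose.shank_matrix()
            cam = pts @ r.T + pose.translation
            if np.any(cam[:, 2] <= 1.0):
                keep = cam[:, 2] > 1.0
                cam, normals = cam[keep], normals[keep]
            if len(cam) == 0:
                raise ValueError("camera inside a model or model behind camera")
            # back-face and grazing-incidence culling: a depth camera returns
            # neither surfaces facing away nor surfaces seen nearly edge-on
            n_cam = normals @ r.T
            cosine = np.einsum("ij,ij->i", n_cam, cam) / np.linalg.norm(cam, axis=1)
            cam = cam[cosine < -grazing_cos]
            if len(cam) == 0:
                continue
            cols = np.round(cam[:, 0] * intrinsics.fx / cam[:, 2] + intrinsics.cx).astype(int)
            rows = np.round(cam[:, 1] * intrinsics.fy / cam[:, 2] + intrinsics.cy).astype(int)
            inb = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
            rows, cols, z = rows[inb], cols[inb], cam[inb, 2]
            # z-test against the current buffer
            part_depth = np.full((h, w), np.inf)
            np.minimum.at(part_depth, (rows, cols), z)
            nearer = part_depth < depth
            depth[nearer] = part_depth[nearer]
            labels[nearer] = _LABELS[(side, part)]

    depth[~np.isfinite(depth)] = 0.0
    labels[depth == 0] = 0

    valid = depth > 0
    if noise_sigma > 0:
        depth[valid] += rng.normal(0.0, noise_sigma, size=int(valid.sum()))
        depth[depth < 0] = 0.0
    if dropout_fraction > 0:
        drop = valid & (rng.random(depth.shape) < dropout_fraction)
        depth[drop] = 0.0
        labels[drop] = 0
    if fragment_below_mm > 0:
        limb = (labels >= 2) & (depth > 0) & (depth < fragment_below_mm)
        if limb.any():
            rows_with = np.unique(np.nonzero(limb)[0])
            n_bands = max(1, len(rows_with) // 8)
            for r0 in rng.choice(rows_with, size=n_bands, replace=False):
                band = limb & (np.arange(h)[:, None] >= r0) & (np.arange(h)[:, None] < r0 + 2)
                depth[band] = 0.0
                labels[band] = 0

    return (
        DepthFrame(depth=depth, timestamp=timestamp, intrinsics=intrinsics),
        labels,
    )


def render_sequence(
    script: GaitScript,
    shapes: Optional[Dict[str, LimbShapes]] = None,
    intrinsics: Optional[CameraIntrinsics] = None,
    noise_sigma: float = 0.0,
    dropout_fraction: float = 0.0,
    fragment_below_mm: float = 0.0,
    keep_masks: bool = False,
    spacing: float = 1.2,
) -> Tuple[List[DepthFrame], SceneTruth]:
    """Synthesize a gait and render every frame; truth masks optional."""
    from .depth_io import DEFAULT_INTRINSICS

    shapes = shapes or default_shapes()
    intrinsics = intrinsics or DEFAULT_INTRINSICS
    truth = synthesize_gait(script, shapes)
    rng = np.random.default_rng(script.seed)
    frames = []
    masks = [] if keep_masks else None
    for k, t in enumerate(truth.times):
        frame, lab = render_depth(
            {s: truth.poses[s][k] for s in ("left", "right")},
            shapes,
            truth.plane,
            intrinsics,
            timestamp=float(t),
            noise_sigma=noise_sigma,
            dropout_fraction=dropout_fraction,
            fragment_below_mm=fragment_below_mm,
            rng=rng,
            spacing=spacing,
        )
        frames.append(frame)
        if keep_masks:
            masks.append(lab)
    truth.label_masks = masks
    return frames, truth
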