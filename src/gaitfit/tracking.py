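"""Per-frame pose estimation for the foot-shank model pair.

The tracker aligns the rigid foot and shank models to the labeled observation
points by minimizing a multi-term cost

``E = E_foot + E_shank + E_additional``

with

* ``E_foot  = E_dist,foot  + w1·E_silhouette,foot  + w2·E_ground``
* ``E_shank = E_dist,shank + w3·E_silhouette,shank + w4·E_orientation``
* ``E_additional = w5·E_limit + w6·E_temporal,rot + w7·E_temporal,trans``

The distance terms sum closed-form point-to-model distances of the observed
points transformed into the model frame; the silhouette terms pull projected
model key points toward the nearest observed pixel of the same part; the
ground term penalizes key points that sink below the floor; the orientation
term keeps the shank near vertical; the limit term discourages large
dorsi/plantarflexion and inversion/eversion; and the temporal terms tie the
pose to the previous frame.

Minimization is Levenberg–Marquardt over the eight *incremental* parameters
(foot rotation vector, shared translation, two shank angle increments): each
accepted step is integrated into the current pose (``R̃ ← R̃·ΔRᵀ``,
``t̃ ← t̃ + Δt``) and the increment is reset, which keeps every linearization
centered at the current estimate.  A constant-velocity Kalman filter with
innovation gating smooths the resulting trajectory and rejects outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .depth_io import CameraIntrinsics, DepthFrame, deproject, project
from .geometry import (
    NEUTRAL_ROTATION,
    FootShape,
    FramePose,
    GroundPlane,
    PoseDelta,
    ShankShape,
    angular_distance,
    foot_surface_distance,
    model_key_points,
    point_to_plane_distance,
    rotation_to_quat_wxyz,
    shank_rotation_matrix,
    shank_surface_distance,
)
from .segmentation import (
    LimbClusterSet,
    SegmentationConfig,
    SegmentedObservation,
    above_ground,
    cluster_and_group,
    contour_segmentation,
    estimate_ground_plane,
    expansion_segmentation,
)

__all__ = [
    "CostWeights",
    "CostBreakdown",
    "OptimizerConfig",
    "KalmanConfig",
    "TrackerConfig",
    "LimbShapes",
    "TrackState",
    "TrackingError",
    "transform_to_model_frame",
    "cost_foot",
    "cost_shank",
    "cost_additional",
    "cost_breakdown",
    "optimize_limb",
    "optimize_frame",
    "kalman_init",
    "kalman_update",
    "track_sequence",
]

# constant residual offset: residual_i = sqrt(term_i + _EPS0) keeps the LM
# objective equal to the cost plus a constant while bounding the gradient of
# the square root near zero.
_EPS0 = 1.0


@dataclass(frozen=True)
class CostWeights:
    """Dimensionless multipliers for the seven weighted cost terms.

    Defaults are calibrated on the synthetic suite so that each weighted term
    contributes the same order of magnitude at a 5° / 20 mm perturbation of a
    typical standing pose.
    """

    w1: float = 10.0  # silhouette, foot (px)
    w2: float = 10.0  # ground penetration (mm)
    w3: float = 4.0  # silhouette, shank (px)
    w4: float = 2000.0  # shank orientation (1 - cos)
    w5: float = 200.0  # ankle-excursion limit (dot products)
    w6: float = 200.0  # temporal, rotation (rad)
    w7: float = 0.5  # temporal, translation (mm)

    def __post_init__(self) -> None:
        for k in ("w1", "w2", "w3", "w4", "w5", "w6", "w7"):
            if getattr(self, k) < 0:
                raise ValueError("cost weights must be non-negative")


@dataclass
class CostBreakdown:
    E_dist_foot: float = 0.0
    E_silhouette_foot: float = 0.0
    E_ground: float = 0.0
    E_dist_shank: float = 0.0
    E_silhouette_shank: float = 0.0
    E_orientation: float = 0.0
    E_limit: float = 0.0
    E_temporal_rot: float = 0.0
    E_temporal_trans: float = 0.0
    foot_empty: bool = False
    shank_empty: bool = False

    def totals(self, w: CostWeights) -> Tuple[float, float, float, float]:
        e_foot = self.E_dist_foot + w.w1 * self.E_silhouette_foot + w.w2 * self.E_ground
        e_shank = (
            self.E_dist_shank
            + w.w3 * self.E_silhouette_shank
            + w.w4 * self.E_orientation
        )
        e_add = (
            w.w5 * self.E_limit
            + w.w6 * self.E_temporal_rot
            + w.w7 * self.E_temporal_trans
        )
        return e_foot, e_shank, e_add, e_foot + e_shank + e_add

    def total(self, w: CostWeights) -> float:
        return self.totals(w)[3]


@dataclass
class OptimizerConfig:
    n_max: int = 30
    cost_threshold: float = 1e-6  # stop when the LM objective falls below this
    cost_change_threshold: float = 1e-3  # relative objective change
    param_change_threshold: float = 1e-3  # ‖δ‖, mm/rad mixed
    lm_damping_init: float = 1e-2
    lm_damping_up: float = 5.0
    lm_damping_down: float = 3.0
    max_points: int = 400  # observation subsample cap per part
    expansion_n_max: int = 8  # cheaper settings inside the separation sweep
    expansion_max_points: int = 200
    limit_abs: bool = False  # |dot| variant of the ankle limit term

    def __post_init__(self) -> None:
        if self.n_max < 1 or self.lm_damping_init <= 0:
            raise ValueError("invalid optimizer configuration")


@dataclass
class KalmanConfig:
    process_accel_trans: float = 4000.0  # mm/s^2, white-accel spectral density
    process_accel_rot: float = 40.0  # rad/s^2
    meas_noise_trans: float = 4.0  # mm (1 sigma)
    meas_noise_rot: float = 0.04  # rad
    gate_chi2: float = 40.0  # Mahalanobis gate on the 8-dim innovation
    enabled: bool = True


@dataclass(frozen=True)
class LimbShapes:
    foot: FootShape
    shank: ShankShape


@dataclass
class TrackerConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    weights: CostWeights = field(default_factory=CostWeights)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    kalman: KalmanConfig = field(default_factory=KalmanConfig)
    reestimate_ground: bool = False
    seed: int = 0


class TrackingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# pose algebra


def transform_to_model_frame(
    p_camera: np.ndarray, pose: FramePose, delta: Optional[PoseDelta] = None
) -> np.ndarray:
    """Observed camera-frame point(s) → foot model frame.

    ``p_M = ΔR·R̃ᵀ·(p_C − t̃ − Δt)`` — the inverse of the model-to-camera map
    ``p_C = R̃·ΔRᵀ·p_M + (t̃ + Δt)`` used by the ground term.
    """
    delta = delta or PoseDelta.identity()
    r_eff = pose.foot_matrix() @ Rotation.from_rotvec(delta.foot_rotvec).as_matrix().T
    t_eff = pose.translation + delta.dt
    p = np.asarray(p_camera, dtype=float)
    return (p - t_eff) @ r_eff


def _effective(pose: FramePose, delta: PoseDelta):
    """Effective (model→camera) rotations and translation under an increment."""
    dr = Rotation.from_rotvec(delta.foot_rotvec).as_matrix()
    rf = pose.foot_matrix() @ dr.T
    rs = shank_rotation_matrix(pose.shank_angles + delta.shank_dangles)
    t = pose.translation + delta.dt
    return rf, rs, t


def _integrate(pose: FramePose, delta: PoseDelta) -> FramePose:
    rf, _, t = _effective(pose, delta)
    return FramePose(
        foot_rotation=rotation_to_quat_wxyz(rf),
        shank_angles=pose.shank_angles + delta.shank_dangles,
        translation=t,
    )


def _pixel_tree(obs: SegmentedObservation, part: str) -> Optional[cKDTree]:
    attr = f"_{part}_tree"
    tree = getattr(obs, attr, None)
    if tree is None:
        px = obs.foot_pixels if part == "foot" else obs.shank_pixels
        tree = cKDTree(px.astype(float)) if len(px) else False
        setattr(obs, attr, tree)
    return tree or None


# ---------------------------------------------------------------------------
# cost terms


def cost_foot(
    obs: SegmentedObservation,
    shape: FootShape,
    pose: FramePose,
    delta: PoseDelta,
    plane: GroundPlane,
    intrinsics: CameraIntrinsics,
    keypoints: Optional[np.ndarray] = None,
) -> CostBreakdown:
    """Foot distance, silhouette and ground-penetration terms (unweighted)."""
    if keypoints is None:
        keypoints = model_key_points(shape, ShankShape(1, 1, 1)).foot
    rf, _, t = _effective(pose, delta)
    out = CostBreakdown(foot_empty=len(obs.foot_points) == 0)

    kp_cam = keypoints @ rf.T + t
    if not out.foot_empty:
        pm = (obs.foot_points - t) @ rf
        out.E_dist_foot = float(foot_surface_distance(pm, shape).sum())
        tree = _pixel_tree(obs, "foot")
        if tree is not None:
            kp_px = project(kp_cam, intrinsics)
            ok = ~np.isnan(kp_px).any(axis=1)
            if ok.any():
                d, _ = tree.query(kp_px[ok])
                out.E_silhouette_foot = float(d.sum())

    signed = point_to_plane_distance(kp_cam, plane)
    out.E_ground = float(np.abs(signed[signed < 0]).sum())
    return out


def cost_shank(
    obs: SegmentedObservation,
    shape: ShankShape,
    pose: FramePose,
    delta: PoseDelta,
    plane: GroundPlane,
    intrinsics: CameraIntrinsics,
    keypoints: Optional[np.ndarray] = None,
) -> CostBreakdown:
    """Shank distance, silhouette and verticality terms (unweighted)."""
    if keypoints is None:
        keypoints = model_key_points(FootShape(30, 200, 60, 10), shape).shank
    _, rs, t = _effective(pose, delta)
    out = CostBreakdown(shank_empty=len(obs.shank_points) == 0)

    if not out.shank_empty:
        pm = (obs.shank_points - t) @ rs
        out.E_dist_shank = float(shank_surface_distance(pm, shape).sum())
        tree = _pixel_tree(obs, "shank")
        if tree is not None:
            kp_px = project(keypoints @ rs.T + t, intrinsics)
            ok = ~np.isnan(kp_px).any(axis=1)
            if ok.any():
                d, _ = tree.query(kp_px[ok])
                out.E_silhouette_shank = float(d.sum())

    axis = rs @ np.array([0.0, 0.0, 1.0])
    out.E_orientation = float(1.0 - axis @ plane.normal)
    return out


def cost_additional(
    pose: FramePose,
    delta: PoseDelta,
    pose_prev: Optional[FramePose],
    limit_abs: bool = False,
) -> CostBreakdown:
    """Ankle-excursion limit and temporal continuity terms (unweighted).

    On the first frame (no previous pose) the temporal terms are zero.  The
    limit term is the sum of the two dot products between the shank long axis
    and the foot forward/lateral axes (zero in neutral stance, where the axes
    are orthogonal); ``limit_abs`` switches to the absolute-value variant.
    """
    rf, rs, t = _effective(pose, delta)
    out = CostBreakdown()
    axis = rs @ np.array([0.0, 0.0, 1.0])
    dot1 = float(axis @ (rf @ np.array([0.0, 1.0, 0.0])))  # dorsi/plantarflexion
    dot2 = float(axis @ (rf @ np.array([1.0, 0.0, 0.0])))  # inversion/eversion
    out.E_limit = abs(dot1) + abs(dot2) if limit_abs else dot1 + dot2
    if pose_prev is not None:
        out.E_temporal_rot = angular_distance(
            pose_prev.foot_matrix(), rf
        ) + angular_distance(pose_prev.shank_matrix(), rs)
        out.E_temporal_trans = float(np.linalg.norm(pose_prev.translation - t))
    return out


def cost_breakdown(
    obs: SegmentedObservation,
    shapes: LimbShapes,
    pose: FramePose,
    delta: PoseDelta,
    pose_prev: Optional[FramePose],
    plane: GroundPlane,
    intrinsics: CameraIntrinsics,
    limit_abs: bool = False,
) -> CostBreakdown:
    """Full cost breakdown at a given pose + increment."""
    kp = model_key_points(shapes.foot, shapes.shank)
    bf = cost_foot(obs, shapes.foot, pose, delta, plane, intrinsics, kp.foot)
    bs = cost_shank(obs, shapes.shank, pose, delta, plane, intrinsics, kp.shank)
    ba = cost_additional(pose, delta, pose_prev, limit_abs)
    return CostBreakdown(
        E_dist_foot=bf.E_dist_foot,
        E_silhouette_foot=bf.E_silhouette_foot,
        E_ground=bf.E_ground,
        E_dist_shank=bs.E_dist_shank,
        E_silhouette_shank=bs.E_silhouette_shank,
        E_orientation=bs.E_orientation,
        E_limit=ba.E_limit,
        E_temporal_rot=ba.E_temporal_rot,
        E_temporal_trans=ba.E_temporal_trans,
        foot_empty=bf.foot_empty,
        shank_empty=bs.shank_empty,
    )


# ---------------------------------------------------------------------------
# Levenberg-Marquardt


def _subsample(arr: np.ndarray, cap: int) -> np.ndarray:
    if len(arr) <= cap:
        return arr
    idx = np.linspace(0, len(arr) - 1, cap).astype(int)
    return arr[idx]


class _Residuals:
    """LM residual vector for one limb; Σ residual² = E + constant.

    Every non-negative cost term enters as ``sqrt(term + 1)`` so the LM
    objective equals the total cost up to an additive constant while the
    square-root gradient stays bounded near a perfect fit.  The (possibly
    signed) limit dot products enter individually as plain residuals, i.e.
    with a symmetric squared penalty.
    """

    def __init__(
        self,
        obs: SegmentedObservation,
        shapes: LimbShapes,
        pose_prev: Optional[FramePose],
        plane: GroundPlane,
        weights: CostWeights,
        intrinsics: CameraIntrinsics,
        max_points: int,
    ):
        self.obs = obs
        self.shapes = shapes
        self.pose_prev = pose_prev
        self.plane = plane
        self.w = weights
        self.k = intrinsics
        kp = model_key_points(shapes.foot, shapes.shank)
        self.kp_foot = kp.foot
        self.kp_shank = kp.shank
        self.p_foot = _subsample(obs.foot_points, max_points)
        self.p_shank = _subsample(obs.shank_points, max_points)
        self.tree_foot = _pixel_tree(obs, "foot")
        self.tree_shank = _pixel_tree(obs, "shank")

    def __call__(self, pose: FramePose, delta_vec: np.ndarray) -> np.ndarray:
        delta = PoseDelta(
            foot_rotvec=delta_vec[0:3],
            dt=delta_vec[3:6],
            shank_dangles=delta_vec[6:8],
        )
        rf, rs, t = _effective(pose, delta)
        w = self.w
        res: List[np.ndarray] = []

        if len(self.p_foot):
            pm = (self.p_foot - t) @ rf
            res.append(np.sqrt(foot_surface_distance(pm, self.shapes.foot) + _EPS0))
            if self.tree_foot is not None:
                px = project(self.kp_foot @ rf.T + t, self.k)
                ok = ~np.isnan(px).any(axis=1)
                d = np.zeros(len(px))
                if ok.any():
                    d[ok], _ = self.tree_foot.query(px[ok])
                res.append(np.sqrt(w.w1 * d + _EPS0))
        kp_cam = self.kp_foot @ rf.T + t
        pen = np.maximum(0.0, -point_to_plane_distance(kp_cam, self.plane))
        res.append(np.sqrt(w.w2 * pen + _EPS0))

        if len(self.p_shank):
            pm = (self.p_shank - t) @ rs
            res.append(np.sqrt(shank_surface_distance(pm, self.shapes.shank) + _EPS0))
            if self.tree_shank is not None:
                px = project(self.kp_shank @ rs.T + t, self.k)
                ok = ~np.isnan(px).any(axis=1)
                d = np.zeros(len(px))
                if ok.any():
                    d[ok], _ = self.tree_shank.query(px[ok])
                res.append(np.sqrt(w.w3 * d + _EPS0))

        axis = rs @ np.array([0.0, 0.0, 1.0])
        res.append(
            np.array([np.sqrt(w.w4 * max(0.0, 1.0 - axis @ self.plane.normal) + _EPS0)])
        )
        dot1 = axis @ (rf @ np.array([0.0, 1.0, 0.0]))
        dot2 = axis @ (rf @ np.array([1.0, 0.0, 0.0]))
        res.append(np.sqrt(w.w5) * np.array([dot1, dot2]))
        if self.pose_prev is not None:
            ang = angular_distance(self.pose_prev.foot_matrix(), rf) + angular_distance(
                self.pose_prev.shank_matrix(), rs
            )
            tr = np.linalg.norm(self.pose_prev.translation - t)
            res.append(np.array([np.sqrt(w.w6 * ang + _EPS0)]))
            res.append(np.array([np.sqrt(w.w7 * tr + _EPS0)]))
        return np.concatenate(res)


_FD_STEPS = np.array([1e-3] * 3 + [0.5] * 3 + [1e-3] * 2)


def optimize_limb(
    obs: SegmentedObservation,
    shapes: LimbShapes,
    pose_init: FramePose,
    pose_prev: Optional[FramePose],
    plane: GroundPlane,
    weights: CostWeights,
    config: OptimizerConfig,
    intrinsics: CameraIntrinsics,
    max_points: Optional[int] = None,
    n_max: Optional[int] = None,
) -> Tuple[FramePose, CostBreakdown, float, int]:
    """LM minimization of the limb cost over the 8 incremental parameters.

    Returns ``(pose, breakdown, objective, n_iterations)`` where ``objective``
    is the LM sum of squares (cost + constant) at the final pose.  Steps that
    do not decrease the objective are rejected (damping increases), so the
    objective never increases relative to initialization.
    """
    if len(obs.foot_points) == 0 and len(obs.shank_points) == 0:
        bd = cost_breakdown(
            obs, shapes, pose_init, PoseDelta.identity(), pose_prev, plane,
            intrinsics, config.limit_abs,
        )
        return pose_init.copy(), bd, np.inf, 0

    fn = _Residuals(
        obs, shapes, pose_prev, plane, weights, intrinsics,
        max_points or config.max_points,
    )
    pose = pose_init.copy()
    lam = config.lm_damping_init
    zero = np.zeros(8)
    r0 = fn(pose, zero)
    s0 = float(r0 @ r0)
    if not np.isfinite(s0):
        raise TrackingError("non-finite cost at initialization")
    it = 0
    limit = n_max if n_max is not None else config.n_max
    while it < limit and s0 > config.cost_threshold:
        it += 1
        # finite-difference Jacobian at delta = 0
        J = np.empty((len(r0), 8))
        for j in range(8):
            step = np.zeros(8)
            step[j] = _FD_STEPS[j]
            J[:, j] = (fn(pose, step) - r0) / _FD_STEPS[j]
        jtj = J.T @ J
        g = J.T @ r0
        accepted = False
        for _ in range(5):
            try:
                delta_vec = np.linalg.solve(
                    jtj + lam * np.diag(np.diag(jtj)) + 1e-10 * np.eye(8), -g
                )
            except np.linalg.LinAlgError:
                break
            r_new = fn(pose, delta_vec)
            s_new = float(r_new @ r_new)
            if np.isfinite(s_new) and s_new < s0:
                accepted = True
                break
            lam *= config.lm_damping_up
        if not accepted:
            break
        pose = _integrate(
            pose,
            PoseDelta(
                foot_rotvec=delta_vec[0:3],
                dt=delta_vec[3:6],
                shank_dangles=delta_vec[6:8],
            ),
        )
        lam = max(lam / config.lm_damping_down, 1e-8)
        rel_drop = (s0 - s_new) / max(s0, 1e-12)
        step_norm = float(np.linalg.norm(delta_vec))
        r0, s0 = r_new, s_new
        if rel_drop < config.cost_change_threshold:
            break
        if step_norm < config.param_change_threshold:
            break
    bd = cost_breakdown(
        obs, shapes, pose, PoseDelta.identity(), pose_prev, plane,
        intrinsics, config.limit_abs,
    )
    return pose, bd, s0, it


def optimize_frame(
    obs_by_side: Dict[str, SegmentedObservation],
    shapes_by_side: Dict[str, LimbShapes],
    poses_prev: Dict[str, FramePose],
    plane: GroundPlane,
    weights: CostWeights,
    config: OptimizerConfig,
    intrinsics: CameraIntrinsics,
) -> Dict[str, Tuple[FramePose, CostBreakdown]]:
    """Independent per-limb optimization (no cross-limb cost terms)."""
    out = {}
    for side, obs in obs_by_side.items():
        pose, bd, _, _ = optimize_limb(
            obs,
            shapes_by_side[side],
            poses_prev[side],
            poses_prev[side],
            plane,
            weights,
            config,
            intrinsics,
        )
        out[side] = (pose, bd)
    return out


# ---------------------------------------------------------------------------
# Kalman smoothing


@dataclass
class TrackState:
    """Per-limb tracker state: previous raw pose + Kalman mean/covariance."""

    pose_prev: FramePose
    x: np.ndarray  # [t(3), foot rotvec rel. neutral (3), θx, θy] + velocities
    P: np.ndarray  # 16×16 covariance


def _pose_to_vec(pose: FramePose) -> np.ndarray:
    rel = NEUTRAL_ROTATION.T @ pose.foot_matrix()
    rv = Rotation.from_matrix(rel).as_rotvec()
    return np.concatenate([pose.translation, rv, pose.shank_angles])


def _vec_to_pose(v: np.ndarray) -> FramePose:
    rf = NEUTRAL_ROTATION @ Rotation.from_rotvec(v[3:6]).as_matrix()
    return FramePose(
        foot_rotation=rotation_to_quat_wxyz(rf),
        shank_angles=v[6:8].copy(),
        translation=v[0:3].copy(),
    )


def kalman_init(pose: FramePose, config: KalmanConfig) -> TrackState:
    x = np.concatenate([_pose_to_vec(pose), np.zeros(8)])
    P = np.diag(
        [config.meas_noise_trans**2] * 3
        + [config.meas_noise_rot**2] * 5
        + [1e4] * 3
        + [1e2] * 5
    ).astype(float)
    return TrackState(pose_prev=pose.copy(), x=x, P=P)


def kalman_predict(
    state: TrackState, dt: float, config: KalmanConfig
) -> Tuple[FramePose, TrackState]:
    """Predict-only step (used when a limb yields no observation)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not config.enabled:
        return state.pose_prev.copy(), state
    F, Q = _transition(dt, config)
    x_pred = F @ state.x
    P_pred = F @ state.P @ F.T + Q
    pose = _vec_to_pose(x_pred[:8])
    return pose, TrackState(pose_prev=pose.copy(), x=x_pred, P=P_pred)


def _transition(dt: float, config: KalmanConfig):
    F = np.eye(16)
    F[:8, 8:] = dt * np.eye(8)
    q_diag = np.array(
        [config.process_accel_trans**2] * 3 + [config.process_accel_rot**2] * 5
    )
    Q = np.zeros((16, 16))
    Q[:8, :8] = np.diag(q_diag) * dt**4 / 4.0
    Q[:8, 8:] = Q[8:, :8] = np.diag(q_diag) * dt**3 / 2.0
    Q[8:, 8:] = np.diag(q_diag) * dt**2
    return F, Q


def kalman_update(
    state: TrackState, measured: FramePose, dt: float, config: KalmanConfig
) -> Tuple[FramePose, TrackState]:
    """Constant-velocity predict/update with Mahalanobis innovation gating.

    A measurement whose innovation exceeds ``gate_chi2`` is treated as an
    outlier: the prediction is held and the covariance grows accordingly.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    z = _pose_to_vec(measured)
    if not config.enabled:
        return measured.copy(), TrackState(measured.copy(), state.x, state.P)

    F, Q = _transition(dt, config)
    x_pred = F @ state.x
    P_pred = F @ state.P @ F.T + Q

    R = np.diag(
        [config.meas_noise_trans**2] * 3 + [config.meas_noise_rot**2] * 5
    ).astype(float)
    H = np.zeros((8, 16))
    H[:, :8] = np.eye(8)
    y = z - H @ x_pred
    S = H @ P_pred @ H.T + R
    maha = float(y @ np.linalg.solve(S, y))
    if maha > config.gate_chi2:
        x_new, P_new = x_pred, P_pred  # outlier: hold the prediction
    else:
        K = P_pred @ H.T @ np.linalg.inv(S)
        x_new = x_pred + K @ y
        P_new = (np.eye(16) - K @ H) @ P_pred
        P_new = 0.5 * (P_new + P_new.T)
    smoothed = _vec_to_pose(x_new[:8])
    return smoothed, TrackState(pose_prev=measured.copy(), x=x_new, P=P_new)


# ---------------------------------------------------------------------------
# sequence driver


def _initial_pose(group, plane: GroundPlane, shapes: LimbShapes) -> FramePose:
    """Neutral standing pose placed at the limb cluster (calibration stance)."""
    c = group.points.mean(axis=0)
    n, cp = plane.normal, plane.point
    # floor height (camera y) beneath the cluster centroid
    ground_y = cp[1] - ((c[0] - cp[0]) * n[0] + (c[2] - cp[2]) * n[2]) / n[1]
    # ankle: foot height above the floor, axis slightly beyond the visible
    # back surface (the cluster shows the camera-facing side of the limb)
    t = np.array([c[0], ground_y - shapes.foot.h, c[2] + shapes.shank.r1])
    return FramePose.neutral(t)


def track_sequence(
    frames: Sequence[DepthFrame],
    shapes_by_side: Dict[str, LimbShapes],
    config: Optional[TrackerConfig] = None,
) -> pd.DataFrame:
    """Track both limbs through a depth sequence.

    Per frame: preprocess and cluster the cloud; two groups → expansion-
    segmentation per limb, one group → contour-segmentation (projecting the
    previous pose); optimize; Kalman-smooth.  Returns one trajectory record
    per limb per frame with the smoothed pose, cost and segmentation method.

    The first frame must yield two groups (the subject starts in the standing
    calibration stance); otherwise a :class:`TrackingError` is raised.
    """
    config = config or TrackerConfig()
    seg = config.segmentation
    rng = np.random.default_rng(config.seed)
    if not frames:
        raise TrackingError("empty sequence")
    intrinsics = frames[0].intrinsics

    records = []
    plane: Optional[GroundPlane] = None
    states: Dict[str, TrackState] = {}
    poses: Dict[str, FramePose] = {}
    prev_centroids = None
    prev_ts = None

    for i, frame in enumerate(frames):
        cloud = deproject(frame)
        keep = cloud.points[:, 2] <= seg.max_range
        cloud.points, cloud.pixel_index = cloud.points[keep], cloud.pixel_index[keep]
        if plane is None or config.reestimate_ground:
            plane = estimate_ground_plane(cloud, seg, rng)
        fg = above_ground(cloud, plane, clearance=seg.surface_tolerance)
        clusters = cluster_and_group(fg, seg, prev_centroids)

        if i == 0:
            if clusters.single_group or clusters.left is None:
                raise TrackingError(
                    "first frame must show two separated limbs (standing pose)"
                )
            for side, group in (("left", clusters.left), ("right", clusters.right)):
                poses[side] = _initial_pose(group, plane, shapes_by_side[side])

        for side in ("left", "right"):
            shapes = shapes_by_side[side]
            pose_prev = poses[side]
            group = getattr(clusters, side)
            method = "expansion"
            if clusters.single_group or group is None or len(group) == 0:
                method = "contour"
                if clusters.merged is not None:
                    from .depth_io import PointCloud as _PC

                    source = _PC(clusters.merged.points, clusters.merged.pixels)
                else:
                    source = fg
                obs = contour_segmentation(
                    source, shapes.foot, shapes.shank, pose_prev, intrinsics, seg
                )
                pose, bd, _, _ = optimize_limb(
                    obs, shapes, pose_prev, pose_prev if i else None,
                    plane, config.weights, config.optimizer, intrinsics,
                )
            else:
                def handle(o, _prev=pose_prev, _shapes=shapes, _first=(i == 0)):
                    pose_o, _, _, _ = optimize_limb(
                        o, _shapes, _prev, None if _first else _prev,
                        plane, config.weights, config.optimizer, intrinsics,
                        max_points=config.optimizer.expansion_max_points,
                        n_max=config.optimizer.expansion_n_max,
                    )
                    # score the line by the full-observation cost: the
                    # subsampled LM objective jitters as the line moves
                    bd_o = cost_breakdown(
                        o, _shapes, pose_o, PoseDelta.identity(),
                        None if _first else _prev, plane, intrinsics,
                        config.optimizer.limit_abs,
                    )
                    return pose_o, bd_o.total(config.weights)

                obs, pose_coarse, _ = expansion_segmentation(group, handle, seg)
                pose, bd, _, _ = optimize_limb(
                    obs, shapes, pose_coarse, pose_prev if i else None,
                    plane, config.weights, config.optimizer, intrinsics,
                )

            dt = (frame.timestamp - prev_ts) if prev_ts is not None else None
            empty = len(obs.foot_points) == 0 and len(obs.shank_points) == 0
            if side not in states:
                states[side] = kalman_init(pose, config.kalman)
                smoothed = pose
            elif empty:
                # no observation: coast on the constant-velocity prediction
                method += "-empty"
                smoothed, states[side] = kalman_predict(
                    states[side], dt if dt else 1e-2, config.kalman
                )
                pose = smoothed
            else:
                smoothed, states[side] = kalman_update(
                    states[side], pose, dt if dt else 1e-2, config.kalman
                )
            poses[side] = pose  # temporal terms compare against the raw pose

            q = smoothed.foot_rotation
            records.append(
                {
                    "frame": i,
                    "time_s": frame.timestamp,
                    "side": side,
                    "qw": q[0],
                    "qx": q[1],
                    "qy": q[2],
                    "qz": q[3],
                    "theta_x": smoothed.shank_angles[0],
                    "theta_y": smoothed.shank_angles[1],
                    "tx": smoothed.translation[0],
                    "ty": smoothed.translation[1],
                    "tz": smoothed.translation[2],
                    "E_total": bd.total(config.weights),
                    "segmentation_method": method,
                }
            )
        prev_ts = frame.timestamp
        if not clusters.single_group and clusters.left is not None:
            prev_centroids = (
                clusters.left.pixels[:, 1].mean(),
                clusters.right.pixels[:, 1].mean(),
            )
    return pd.DataFrame.from_records(records)
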