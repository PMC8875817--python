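"""Parametric foot and shank models and rotation utilities.

The lower limb is approximated by two rigid primitives that share an origin at
the ankle (the center of the plane where shank meets foot):

* **Foot** — a U-shaped prism seen from behind: a half-cylindrical heel wall of
  radius ``r`` (rear half only), two planar side walls running forward to the
  toe edge, and a flat sole.  The top and front faces are removed because they
  are never visible to a camera looking at the walker's back.  A calcaneus
  bulge of depth ``d`` widens the rear heel arc over the top 40 % of the foot
  height.
* **Shank** — the rear half of a tapered cylinder (radius ``r1`` at the ankle,
  ``r2`` below the knee, length ``s``); the front half and the end caps are
  removed for the same visibility reason.

Model frame convention (both models, all lengths in millimetres):

* ``x`` — lateral, ``y`` — forward (toe direction), ``z`` — up along the shank
  axis in neutral stance.  The origin sits at the ankle: the foot occupies
  ``z ∈ [-h, 0]``, the shank ``z ∈ [0, s]``.

Every point-to-surface distance below is closed-form (minimum over a handful
of cylinder/cone/rectangle/region patches), which is what makes the tracker's
alignment cost cheap to evaluate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "FootShape",
    "ShankShape",
    "FramePose",
    "PoseDelta",
    "GroundPlane",
    "ModelKeyPoints",
    "NEUTRAL_ROTATION",
    "foot_surface_distance",
    "shank_surface_distance",
    "model_key_points",
    "point_to_plane_distance",
    "angular_distance",
    "average_quaternion",
    "sample_foot_surface",
    "sample_shank_surface",
    "shank_rotation_matrix",
    "quat_wxyz_to_rotation",
    "rotation_to_quat_wxyz",
]

#: Fraction of the foot height (from the top) over which the calcaneus bulge
#: blends from zero to its full depth ``d``.
_PROTRUSION_FRACTION = 0.4

#: Neutral model-to-camera rotation for a camera behind the walker with
#: x right / y down / z forward: model x (lateral) -> camera x, model y
#: (forward) -> camera z, model z (up) -> camera -y.
NEUTRAL_ROTATION = np.array(
    [
        [1.0, 0.0, 0.0],
        [0.0, 0.0, -1.0],
        [0.0, 1.0, 0.0],
    ]
)  # columns are the camera-frame images of the model x, y, z axes


@dataclass(frozen=True)
class FootShape:
    """Foot model parameters (mm): heel radius, length, height, calcaneus bulge."""

    r: float
    l: float
    h: float
    d: float

    def __post_init__(self) -> None:
        if not (self.r > 0 and self.l > 0 and self.h > 0 and self.d >= 0):
            raise ValueError("foot shape parameters must be positive (d >= 0)")
        if self.l <= self.r:
            raise ValueError("foot length l must exceed heel radius r")
        if self.d >= self.r:
            raise ValueError("heel protrusion d must be smaller than r")


@dataclass(frozen=True)
class ShankShape:
    """Shank (tapered cylinder) parameters: lower/upper radius and length, mm."""

    r1: float
    r2: float
    s: float

    def __post_init__(self) -> None:
        if not (self.r1 > 0 and self.r2 > 0 and self.s > 0):
            raise ValueError("shank shape parameters must be strictly positive")


@dataclass
class FramePose:
    """Pose of the foot-shank pair w.r.t. the camera for one frame.

    ``foot_rotation`` is a unit quaternion (w, x, y, z) mapping model to camera
    coordinates.  The shank orientation is ``NEUTRAL_ROTATION @ Rx(θx) @ Ry(θy)``
    — the rotation about its own long axis is unobservable for a cylinder and
    is dropped.  Both models share ``translation`` (ankle origin, camera frame,
    mm).
    """

    foot_rotation: np.ndarray
    shank_angles: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.foot_rotation = np.asarray(self.foot_rotation, dtype=float)
        self.shank_angles = np.asarray(self.shank_angles, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        n = np.linalg.norm(self.foot_rotation)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("foot_rotation must be a unit quaternion")
        self.foot_rotation = self.foot_rotation / n

    @classmethod
    def neutral(cls, translation=(0.0, 0.0, 0.0)) -> "FramePose":
        return cls(
            foot_rotation=rotation_to_quat_wxyz(NEUTRAL_ROTATION),
            shank_angles=np.zeros(2),
            translation=np.asarray(translation, dtype=float),
        )

    def foot_matrix(self) -> np.ndarray:
        return quat_wxyz_to_rotation(self.foot_rotation).as_matrix()

    def shank_matrix(self) -> np.ndarray:
        return shank_rotation_matrix(self.shank_angles)

    def copy(self) -> "FramePose":
        return FramePose(
            self.foot_rotation.copy(),
            self.shank_angles.copy(),
            self.translation.copy(),
        )


@dataclass
class PoseDelta:
    """Per-iteration pose increment: rotation ΔR (as rotvec) and Δt (mm)."""

    foot_rotvec: np.ndarray = field(default_factory=lambda: np.zeros(3))
    shank_dangles: np.ndarray = field(default_factory=lambda: np.zeros(2))
    dt: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @classmethod
    def identity(cls) -> "PoseDelta":
        return cls()


@dataclass(frozen=True)
class GroundPlane:
    """Floor plane: unit normal (pointing up, away from the floor) + a point on it."""

    normal: np.ndarray
    point: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        object.__setattr__(self, "normal", n / np.linalg.norm(n))
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))


@dataclass(frozen=True)
class ModelKeyPoints:
    """Deterministic key-point sets (model frame) used by silhouette/ground costs."""

    foot: np.ndarray
    shank: np.ndarray


# ---------------------------------------------------------------------------
# rotation helpers


def quat_wxyz_to_rotation(q: np.ndarray) -> Rotation:
    q = np.asarray(q, dtype=float)
    return Rotation.from_quat(np.concatenate([q[..., 1:4], q[..., 0:1]], axis=-1))


def rotation_to_quat_wxyz(rot) -> np.ndarray:
    if isinstance(rot, np.ndarray) and rot.shape[-2:] == (3, 3):
        rot = Rotation.from_matrix(rot)
    q = rot.as_quat()
    q = np.concatenate([q[..., 3:4], q[..., 0:3]], axis=-1)
    # canonical sign: non-negative scalar part
    if q.ndim == 1 and q[0] < 0:
        q = -q
    return q


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def shank_rotation_matrix(angles) -> np.ndarray:
    """Model-to-camera shank rotation: neutral alignment composed with Rx·Ry."""
    tx, ty = float(angles[0]), float(angles[1])
    return NEUTRAL_ROTATION @ _rx(tx) @ _ry(ty)


def angular_distance(r_a, r_b) -> float:
    """Geodesic angle (radians, in [0, π]) between two rotations.

    Accepts 3×3 matrices, scipy Rotations, or (w,x,y,z) quaternions.
    """
    ma = _as_matrix(r_a)
    mb = _as_matrix(r_b)
    rel = ma @ mb.T
    # angle from trace, clipped for numerical safety
    cos = (np.trace(rel) - 1.0) / 2.0
    return float(np.arccos(np.clip(cos, -1.0, 1.0)))


def _as_matrix(r) -> np.ndarray:
    if isinstance(r, Rotation):
        return r.as_matrix()
    r = np.asarray(r, dtype=float)
    if r.shape == (3, 3):
        return r
    if r.shape == (4,):
        return quat_wxyz_to_rotation(r).as_matrix()
    raise ValueError(f"cannot interpret rotation with shape {r.shape}")


def average_quaternion(quats) -> np.ndarray:
    """Mean orientation of ≥1 unit quaternions (w,x,y,z).

    Returns the normalized principal eigenvector of the 4×4 accumulation
    matrix Q·Qᵀ, which minimizes the summed squared chordal distance and is
    invariant to per-element sign flips and to input ordering.  Sign is fixed
    to a non-negative scalar part.
    """
    Q = np.atleast_2d(np.asarray(quats, dtype=float))
    if Q.size == 0:
        raise ValueError("average_quaternion requires at least one quaternion")
    A = Q.T @ Q  # 4x4, sign-flip invariant
    w, v = np.linalg.eigh(A)
    q = v[:, np.argmax(w)]
    q = q / np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    return q


# ---------------------------------------------------------------------------
# closed-form surface distances


def _seg_dist_2d(px, py, ax, ay, bx, by):
    """Vectorized point-to-segment distance in 2D."""
    abx, aby = bx - ax, by - ay
    denom = abx * abx + aby * aby
    if denom < 1e-12:
        return np.hypot(px - ax, py - ay)
    t = np.clip(((px - ax) * abx + (py - ay) * aby) / denom, 0.0, 1.0)
    return np.hypot(px - (ax + t * abx), py - (ay + t * aby))


def _seg_dist_3d(p, a, b):
    """Vectorized point-to-segment distance in 3D; p is (..., 3)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-12:
        return np.linalg.norm(p - a, axis=-1)
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    return np.linalg.norm(p - proj, axis=-1)


def _heel_profile(shape: FootShape):
    """(ρ, z) polyline of the rear heel wall, bottom to top, with bulge."""
    z0 = -_PROTRUSION_FRACTION * shape.h
    if shape.d > 0:
        return [(shape.r, -shape.h), (shape.r, z0), (shape.r + shape.d, 0.0)]
    return [(shape.r, -shape.h), (shape.r, 0.0)]


def foot_surface_distance(p, shape: FootShape):
    """Minimum Euclidean distance (mm, ≥0) from point(s) ``p`` to the foot surface.

    Retained surface patches: rear heel wall (half cylinder, bulged near the
    top), two planar side walls, and the sole.  Top and front faces are open.
    Accepts a single 3-vector or an (N, 3) array.
    """
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    r, l, h = shape.r, shape.l, shape.h
    ytoe = l - r  # forward extent of the side walls / sole rectangle

    dists = []

    # --- heel wall (rear half: y <= 0) --------------------------------------
    rho = np.hypot(x, y)
    profile = _heel_profile(shape)
    d_prof = np.full(len(pts), np.inf)
    for (a, b) in zip(profile[:-1], profile[1:]):
        d_prof = np.minimum(d_prof, _seg_dist_2d(rho, z, a[0], a[1], b[0], b[1]))
    rear = y <= 0
    d_heel = np.full(len(pts), np.inf)
    d_heel[rear] = d_prof[rear]
    # front points see only the two vertical boundary edges of the half wall
    front = ~rear
    if np.any(front):
        pf = pts[front]
        d_edge = np.full(front.sum(), np.inf)
        for sgn in (-1.0, 1.0):
            verts = [np.array([sgn * rr, 0.0, zz]) for rr, zz in profile]
            for a, b in zip(verts[:-1], verts[1:]):
                d_edge = np.minimum(d_edge, _seg_dist_3d(pf, a, b))
        d_heel[front] = d_edge
    dists.append(d_heel)

    # --- side walls x = ±r, y ∈ [0, l-r], z ∈ [-h, 0] -----------------------
    dy = np.maximum.reduce([np.zeros_like(y), -y, y - ytoe])
    dz = np.maximum.reduce([np.zeros_like(z), z, -h - z])
    for sgn in (-1.0, 1.0):
        dists.append(np.sqrt((x - sgn * r) ** 2 + dy**2 + dz**2))

    # --- sole z = -h: rear half-disc (radius r) ∪ forward rectangle ---------
    # horizontal distance to the footprint region (0 inside)
    in_rect = (np.abs(x) <= r) & (y >= 0) & (y <= ytoe)
    in_disc = (rho <= r) & (y <= 0)
    d_rect = np.sqrt(
        np.maximum(np.abs(x) - r, 0.0) ** 2
        + np.maximum.reduce([np.zeros_like(y), -y, y - ytoe]) ** 2
    )
    d_disc = np.where(y <= 0, np.maximum(rho - r, 0.0), _seg_dist_2d(x, y, -r, 0.0, r, 0.0))
    d_horiz = np.where(in_rect | in_disc, 0.0, np.minimum(d_rect, d_disc))
    dists.append(np.hypot(d_horiz, z + h))

    out = np.minimum.reduce(dists)
    return float(out[0]) if single else out


def shank_surface_distance(p, shape: ShankShape):
    """Minimum distance (mm, ≥0) to the rear half of the tapered shank wall.

    The front half (y > 0 side) and both end caps are open; a point beyond the
    ends measures its distance to the nearest rim arc (the profile segment is
    clamped at the rims).
    """
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    rho = np.hypot(x, y)

    d = np.empty(len(pts))
    rear = y <= 0
    d[rear] = _seg_dist_2d(rho[rear], z[rear], shape.r1, 0.0, shape.r2, shape.s)
    front = ~rear
    if np.any(front):
        pf = pts[front]
        d_edge = np.full(front.sum(), np.inf)
        for sgn in (-1.0, 1.0):
            a = np.array([sgn * shape.r1, 0.0, 0.0])
            b = np.array([sgn * shape.r2, 0.0, shape.s])
            d_edge = np.minimum(d_edge, _seg_dist_3d(pf, a, b))
        d[front] = d_edge
    return float(d[0]) if single else d


# ---------------------------------------------------------------------------
# key points and surface sampling


def model_key_points(foot: FootShape, shank: ShankShape) -> ModelKeyPoints:
    """Deterministic key points on the retained surfaces (model frame).

    Foot (13): 8 sole-perimeter points (rear, two heel sides, two mid-sides,
    two toe corners, toe mid), 4 top-rim corners of the side walls, and the
    heel-arc midpoint.  Shank (16): 8 points on the back half of each rim.
    The sole-perimeter subset is what the ground-penetration cost and the
    base-of-support projection use.
    """
    r, l, h = foot.r, foot.l, foot.h
    ytoe = l - r
    sole = np.array(
        [
            [0.0, -r, -h],
            [-r, 0.0, -h],
            [r, 0.0, -h],
            [-r, ytoe / 2.0, -h],
            [r, ytoe / 2.0, -h],
            [-r, ytoe, -h],
            [r, ytoe, -h],
            [0.0, ytoe, -h],
        ]
    )
    top = np.array(
        [
            [-r, 0.0, 0.0],
            [r, 0.0, 0.0],
            [-r, ytoe, 0.0],
            [r, ytoe, 0.0],
        ]
    )
    heel_mid = np.array([[0.0, -r, -h / 2.0]])
    foot_kp = np.vstack([sole, top, heel_mid])

    angles = np.linspace(-np.pi / 2.0, np.pi / 2.0, 8)
    rims = []
    for radius, zz in ((shank.r1, 0.0), (shank.r2, shank.s)):
        rims.append(
            np.column_stack(
                [
                    radius * np.sin(angles),
                    -radius * np.cos(angles),
                    np.full(8, zz),
                ]
            )
        )
    return ModelKeyPoints(foot=foot_kp, shank=np.vstack(rims))


def foot_sole_points(foot: FootShape) -> np.ndarray:
    """The 8 sole-perimeter key points (used for ground cost and BoS)."""
    return model_key_points(foot, ShankShape(1.0, 1.0, 1.0)).foot[:8]


def sample_foot_surface(
    shape: FootShape, spacing: float = 5.0, with_normals: bool = False
):
    """Dense, deterministic sampling of the retained foot patches (model frame).

    ``spacing`` is the approximate inter-sample distance in mm; used by the
    synthetic renderer and the contour-segmentation hulls.  With
    ``with_normals`` the outward surface normal of each sample is returned as
    well (the renderer needs them for back-face culling).
    """
    r, l, h, d = shape.r, shape.l, shape.h, shape.d
    ytoe = l - r
    pts = []
    nrm = []

    # heel wall: azimuth × height grid, radius following the bulge profile
    n_az = max(int(np.ceil(np.pi * r / spacing)) + 1, 4)
    n_z = max(int(np.ceil(h / spacing)) + 1, 3)
    az = np.linspace(-np.pi / 2.0, np.pi / 2.0, n_az)
    zs = np.linspace(-h, 0.0, n_z)
    z0 = -_PROTRUSION_FRACTION * h
    slope = (d / (0.0 - z0)) if d > 0 else 0.0  # dρ/dz on the bulged band
    for z in zs:
        on_bulge = d > 0 and z > z0
        bulge = d * (z - z0) / (0.0 - z0) if on_bulge else 0.0
        radius = r + bulge
        pts.append(
            np.column_stack(
                [radius * np.sin(az), -radius * np.cos(az), np.full(n_az, z)]
            )
        )
        if with_normals:
            tilt = slope if on_bulge else 0.0
            scale = 1.0 / np.sqrt(1.0 + tilt * tilt)
            nrm.append(
                np.column_stack(
                    [
                        np.sin(az) * scale,
                        -np.cos(az) * scale,
                        np.full(n_az, -tilt * scale),
                    ]
                )
            )

    # side walls
    n_y = max(int(np.ceil(ytoe / spacing)) + 1, 3)
    ys = np.linspace(0.0, ytoe, n_y)
    yy, zz = np.meshgrid(ys, zs)
    for sgn in (-1.0, 1.0):
        pts.append(
            np.column_stack([np.full(yy.size, sgn * r), yy.ravel(), zz.ravel()])
        )
        if with_normals:
            n = np.zeros((yy.size, 3))
            n[:, 0] = sgn
            nrm.append(n)

    # sole: rectangle + rear half disc, outward normal pointing down
    n_x = max(int(np.ceil(2 * r / spacing)) + 1, 3)
    xs = np.linspace(-r, r, n_x)
    xx, yy = np.meshgrid(xs, ys)
    pts.append(np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, -h)]))
    if with_normals:
        n = np.zeros((xx.size, 3))
        n[:, 2] = -1.0
        nrm.append(n)
    xx, yy = np.meshgrid(xs, np.linspace(-r, 0.0, n_x))
    mask = np.hypot(xx, yy) <= r
    pts.append(np.column_stack([xx[mask], yy[mask], np.full(mask.sum(), -h)]))
    if with_normals:
        n = np.zeros((int(mask.sum()), 3))
        n[:, 2] = -1.0
        nrm.append(n)

    points = np.vstack(pts)
    if with_normals:
        return points, np.vstack(nrm)
    return points


def sample_shank_surface(
    shape: ShankShape, spacing: float = 5.0, with_normals: bool = False
):
    """Dense, deterministic sampling of the rear half of the shank wall."""
    rmax = max(shape.r1, shape.r2)
    n_az = max(int(np.ceil(np.pi * rmax / spacing)) + 1, 4)
    n_z = max(int(np.ceil(shape.s / spacing)) + 1, 3)
    az = np.linspace(-np.pi / 2.0, np.pi / 2.0, n_az)
    zs = np.linspace(0.0, shape.s, n_z)
    taper = (shape.r2 - shape.r1) / shape.s
    scale = 1.0 / np.sqrt(1.0 + taper * taper)
    pts = []
    nrm = []
    for z in zs:
        radius = shape.r1 + taper * z
        pts.append(
            np.column_stack(
                [radius * np.sin(az), -radius * np.cos(az), np.full(n_az, z)]
            )
        )
        if with_normals:
            nrm.append(
                np.column_stack(
                    [
                        np.sin(az) * scale,
                        -np.cos(az) * scale,
                        np.full(n_az, -taper * scale),
                    ]
                )
            )
    points = np.vstack(pts)
    if with_normals:
        return points, np.vstack(nrm)
    return points


# ---------------------------------------------------------------------------
# planes


def point_to_plane_distance(p, plane: GroundPlane):
    """Signed distance (mm): (p − c)·n.  Negative means below the floor."""
    p = np.asarray(p, dtype=float)
    return (p - plane.point) @ plane.normal
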