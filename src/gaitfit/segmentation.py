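"""Point-cloud preprocessing and foot/shank pixel labeling.

Pipeline per frame: cut the cloud at ``max_range``, fit the ground plane
(RANSAC), keep above-ground points, group connected pixels of similar depth
into clusters, split clusters into a left and a right limb (1-D K-means on the
horizontal pixel coordinate of cluster centroids), then label each limb's
pixels as foot or shank by one of two methods:

* **expansion-segmentation** — sweep a horizontal separation line upward from
  just above the lowest pixel; at each line, pixels below are foot, above are
  shank; re-run the pose optimizer and stop at the first line whose optimized
  cost increases.  Used when both limbs are cleanly separated.
* **contour-segmentation** — project the posed models into the image, form a
  convex hull per model, and label in-hull pixels whose 3D points lie within a
  tolerance of that model's surface.  Used as the fallback when clustering
  finds only one group (occlusion, legs touching).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, Delaunay, QhullError
from sklearn.cluster import KMeans

from .depth_io import CameraIntrinsics, PointCloud, project
from .geometry import (
    FootShape,
    FramePose,
    GroundPlane,
    ShankShape,
    foot_surface_distance,
    point_to_plane_distance,
    sample_foot_surface,
    sample_shank_surface,
    shank_surface_distance,
)

__all__ = [
    "SegmentationConfig",
    "LimbGroup",
    "LimbClusterSet",
    "SegmentedObservation",
    "GroundPlaneError",
    "estimate_ground_plane",
    "above_ground",
    "cluster_and_group",
    "expansion_segmentation",
    "contour_segmentation",
]


@dataclass
class SegmentationConfig:
    max_range: float = 1000.0  # mm; points further from the camera are dropped
    cluster_depth_threshold: float = 20.0  # mm; "similar depth" for connectivity
    min_cluster_size: int = 50  # px; suppress sensor speckle
    r_initial: int = 10  # rows above the lowest pixel for the first separation line
    surface_tolerance: float = 15.0  # mm; plane inliers & contour surface gate
    ransac_iterations: int = 60
    min_plane_inlier_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "max_range",
            "cluster_depth_threshold",
            "min_cluster_size",
            "r_initial",
            "surface_tolerance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"SegmentationConfig.{name} must be positive")


@dataclass
class LimbGroup:
    """One limb's 3D points and their source pixels."""

    points: np.ndarray  # (N, 3) mm
    pixels: np.ndarray  # (N, 2) row/col

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class LimbClusterSet:
    left: Optional[LimbGroup]
    right: Optional[LimbGroup]
    cluster_count_raw: int
    single_group: bool = False
    merged: Optional[LimbGroup] = None  # populated when single_group


@dataclass
class SegmentedObservation:
    """Foot/shank labeling of one limb in one frame (disjoint pixel sets)."""

    foot_points: np.ndarray
    shank_points: np.ndarray
    foot_pixels: np.ndarray
    shank_pixels: np.ndarray
    method: str  # "expansion" | "contour"
    separation_row: Optional[int] = None
    degenerate: bool = False


class GroundPlaneError(RuntimeError):
    """No plane with sufficient inlier support was found."""


def estimate_ground_plane(
    cloud: PointCloud,
    config: SegmentationConfig,
    rng: Optional[np.random.Generator] = None,
) -> GroundPlane:
    """RANSAC plane fit; the normal is oriented upward (camera −y side).

    Candidate planes must be near-horizontal (normal within ~50° of camera up)
    so limb surfaces cannot win the consensus vote.
    """
    rng = rng or np.random.default_rng(0)
    pts = cloud.points
    if len(pts) < 3:
        raise GroundPlaneError("too few points to fit a plane")
    up = np.array([0.0, -1.0, 0.0])
    best_inliers = -1
    best: Optional[Tuple[np.ndarray, np.ndarray]] = None
    n = len(pts)
    for _ in range(config.ransac_iterations):
        idx = rng.choice(n, size=3, replace=False)
        a, b, c = pts[idx]
        normal = np.cross(b - a, c - a)
        norm = np.linalg.norm(normal)
        if norm < 1e-9:
            continue
        normal = normal / norm
        if normal @ up < 0:
            normal = -normal
        if normal @ up < 0.65:  # reject steep (non-floor) planes
            continue
        dist = np.abs((pts - a) @ normal)
        inliers = int((dist < config.surface_tolerance).sum())
        if inliers > best_inliers:
            best_inliers = inliers
            best = (normal, a)
    if best is None or best_inliers < config.min_plane_inlier_fraction * n:
        raise GroundPlaneError(
            f"no dominant ground plane ({best_inliers}/{n} inliers)"
        )
    normal, anchor = best
    # refine with an SVD fit on the inliers
    mask = np.abs((pts - anchor) @ normal) < config.surface_tolerance
    inlier_pts = pts[mask]
    centroid = inlier_pts.mean(axis=0)
    _, _, vt = np.linalg.svd(inlier_pts - centroid, full_matrices=False)
    refined = vt[2]
    if refined @ up < 0:
        refined = -refined
    return GroundPlane(normal=refined, point=centroid)


def above_ground(
    cloud: PointCloud, plane: GroundPlane, clearance: float
) -> PointCloud:
    """Points strictly above the floor (signed distance > clearance)."""
    keep = point_to_plane_distance(cloud.points, plane) > clearance
    return PointCloud(points=cloud.points[keep], pixel_index=cloud.pixel_index[keep])


def _connected_components_by_depth(
    pixels: np.ndarray, depths: np.ndarray, threshold: float
) -> np.ndarray:
    """Label pixels; 4-adjacent pixels connect iff |Δdepth| < threshold."""
    n = len(pixels)
    if n == 0:
        return np.empty(0, dtype=int)
    rows, cols = pixels[:, 0], pixels[:, 1]
    r0, c0 = rows.min(), cols.min()
    grid = -np.ones((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=int)
    grid[rows - r0, cols - c0] = np.arange(n)

    edges_i, edges_j = [], []
    for dr, dc in ((0, 1), (1, 0)):
        a = grid[: grid.shape[0] - dr, : grid.shape[1] - dc]
        b = grid[dr:, dc:]
        ok = (a >= 0) & (b >= 0)
        ia, ib = a[ok], b[ok]
        close = np.abs(depths[ia] - depths[ib]) < threshold
        edges_i.append(ia[close])
        edges_j.append(ib[close])
    ei = np.concatenate(edges_i)
    ej = np.concatenate(edges_j)
    adj = coo_matrix((np.ones(len(ei)), (ei, ej)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def cluster_and_group(
    cloud: PointCloud,
    config: SegmentationConfig,
    prev_centroids: Optional[Tuple[float, float]] = None,
) -> LimbClusterSet:
    """Cluster the above-ground cloud and split clusters into left/right limbs.

    Connected-component labeling on the pixel grid (depth-gated adjacency),
    small components dropped, then 1-D K-means (k=2) on component centroid
    columns.  A single surviving component (legs touching / one limb occluded)
    is reported with ``single_group=True`` so the tracker can fall back to
    contour-segmentation.  ``prev_centroids`` (left, right mean columns of the
    previous frame) breaks exact ties deterministically.
    """
    if len(cloud) == 0:
        return LimbClusterSet(None, None, cluster_count_raw=0, single_group=True)

    labels = _connected_components_by_depth(
        cloud.pixel_index, cloud.points[:, 2], config.cluster_depth_threshold
    )
    uniq, counts = np.unique(labels, return_counts=True)
    keep = uniq[counts >= config.min_cluster_size]
    n_raw = len(keep)
    if n_raw == 0:
        return LimbClusterSet(None, None, cluster_count_raw=0, single_group=True)

    mask_all = np.isin(labels, keep)
    merged = LimbGroup(cloud.points[mask_all], cloud.pixel_index[mask_all])
    if n_raw == 1:
        return LimbClusterSet(
            None, None, cluster_count_raw=1, single_group=True, merged=merged
        )

    centroids = np.array(
        [cloud.pixel_index[labels == u, 1].mean() for u in keep]
    ).reshape(-1, 1)
    if np.ptp(centroids) < 1e-9:
        return LimbClusterSet(
            None, None, cluster_count_raw=n_raw, single_group=True, merged=merged
        )
    km = KMeans(n_clusters=2, n_init=5, random_state=0).fit(centroids)
    g0 = keep[km.labels_ == 0]
    g1 = keep[km.labels_ == 1]
    if len(g0) == 0 or len(g1) == 0:
        return LimbClusterSet(
            None, None, cluster_count_raw=n_raw, single_group=True, merged=merged
        )

    def _group(members) -> LimbGroup:
        m = np.isin(labels, members)
        return LimbGroup(cloud.points[m], cloud.pixel_index[m])

    c0, c1 = km.cluster_centers_.ravel()
    if np.isclose(c0, c1):
        # tie: order by proximity to previous-frame centroids, else keep order
        if prev_centroids is not None and abs(c0 - prev_centroids[0]) > abs(
            c1 - prev_centroids[0]
        ):
            g0, g1 = g1, g0
    elif c0 > c1:
        g0, g1 = g1, g0
        c0, c1 = c1, c0
    if prev_centroids is not None:
        # a lone limb can fragment into two spurious groups: if both group
        # centroids are nearest the same previous-frame limb, report a single
        # group so the tracker falls back to contour-segmentation
        pl, pr = prev_centroids
        side0 = abs(c0 - pl) <= abs(c0 - pr)
        side1 = abs(c1 - pl) <= abs(c1 - pr)
        if side0 == side1:
            return LimbClusterSet(
                None, None, cluster_count_raw=n_raw, single_group=True, merged=merged
            )
    return LimbClusterSet(
        left=_group(g0), right=_group(g1), cluster_count_raw=n_raw, merged=merged
    )


def expansion_segmentation(
    group: LimbGroup,
    optimizer: Callable[[SegmentedObservation], Tuple[FramePose, float]],
    config: SegmentationConfig,
) -> Tuple[SegmentedObservation, FramePose, float]:
    """Foot/shank split by the upward-sweeping separation-line search.

    The first candidate line sits ``r_initial`` rows above the group's lowest
    pixel; pixels at or below the line are foot, above are shank.  The pose
    optimizer is run for each candidate; the sweep stops at the first line
    whose optimized cost strictly exceeds the previous one, and the previous
    (best) labeling and pose are returned.
    """
    rows = group.pixels[:, 0]
    bottom, top = int(rows.max()), int(rows.min())
    line = bottom - config.r_initial

    if line <= top:
        obs = SegmentedObservation(
            foot_points=group.points,
            shank_points=np.empty((0, 3)),
            foot_pixels=group.pixels,
            shank_pixels=np.empty((0, 2), dtype=int),
            method="expansion",
            separation_row=top,
            degenerate=True,
        )
        pose, cost = optimizer(obs)
        return obs, pose, cost

    best: Optional[Tuple[SegmentedObservation, FramePose, float]] = None
    while line > top:
        foot_mask = rows >= line
        obs = SegmentedObservation(
            foot_points=group.points[foot_mask],
            shank_points=group.points[~foot_mask],
            foot_pixels=group.pixels[foot_mask],
            shank_pixels=group.pixels[~foot_mask],
            method="expansion",
            separation_row=line,
        )
        pose, cost = optimizer(obs)
        if best is not None and cost > best[2]:
            break
        best = (obs, pose, cost)
        line -= 1
    return best


def _hull_mask(hull_pixels: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Boolean mask of query pixels inside the convex hull of hull_pixels."""
    if len(hull_pixels) < 3:
        return np.zeros(len(query), dtype=bool)
    try:
        hull = ConvexHull(hull_pixels)
        tri = Delaunay(hull_pixels[hull.vertices])
    except QhullError:
        return np.zeros(len(query), dtype=bool)
    return tri.find_simplex(query) >= 0


def contour_segmentation(
    cloud: PointCloud,
    foot_shape: FootShape,
    shank_shape: ShankShape,
    pose_prev: FramePose,
    intrinsics: CameraIntrinsics,
    config: SegmentationConfig,
) -> SegmentedObservation:
    """Label pixels by projecting the posed models and gating on surface distance.

    One convex hull per model is built from the projected model surface
    samples; pixels inside a hull whose 3D points lie within
    ``surface_tolerance`` of that model's surface are labeled accordingly.
    A pixel inside both hulls goes to the nearer surface.  A degenerate hull
    (model behind the camera) yields an empty, flagged observation.
    """
    empty = lambda: SegmentedObservation(  # noqa: E731
        foot_points=np.empty((0, 3)),
        shank_points=np.empty((0, 3)),
        foot_pixels=np.empty((0, 2), dtype=int),
        shank_pixels=np.empty((0, 2), dtype=int),
        method="contour",
        degenerate=True,
    )
    if len(cloud) == 0:
        return empty()

    rf = pose_prev.foot_matrix()
    rs = pose_prev.shank_matrix()
    t = pose_prev.translation

    foot_cam = sample_foot_surface(foot_shape, spacing=10.0) @ rf.T + t
    shank_cam = sample_shank_surface(shank_shape, spacing=10.0) @ rs.T + t
    foot_px = project(foot_cam, intrinsics)
    shank_px = project(shank_cam, intrinsics)
    foot_px = foot_px[~np.isnan(foot_px).any(axis=1)]
    shank_px = shank_px[~np.isnan(shank_px).any(axis=1)]
    if len(foot_px) < 3 and len(shank_px) < 3:
        return empty()

    q = cloud.pixel_index.astype(float)
    in_foot = _hull_mask(foot_px, q)
    in_shank = _hull_mask(shank_px, q)

    # surface distances in the respective model frames
    d_foot = np.full(len(cloud), np.inf)
    d_shank = np.full(len(cloud), np.inf)
    if in_foot.any():
        pm = (cloud.points[in_foot] - t) @ rf
        d_foot[in_foot] = foot_surface_distance(pm, foot_shape)
    if in_shank.any():
        pm = (cloud.points[in_shank] - t) @ rs
        d_shank[in_shank] = shank_surface_distance(pm, shank_shape)

    near_foot = in_foot & (d_foot < config.surface_tolerance)
    near_shank = in_shank & (d_shank < config.surface_tolerance)
    both = near_foot & near_shank
    near_foot[both] = d_foot[both] <= d_shank[both]
    near_shank[both] = ~near_foot[both]

    return SegmentedObservation(
        foot_points=cloud.points[near_foot],
        shank_points=cloud.points[near_shank],
        foot_pixels=cloud.pixel_index[near_foot],
        shank_pixels=cloud.pixel_index[near_shank],
        method="contour",
        degenerate=not (near_foot.any() or near_shank.any()),
    )
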