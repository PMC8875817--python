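"""Depth-frame I/O and pinhole camera geometry.

Camera frame convention: x right, y down, z forward along the optical axis —
consistent with depth-image row/column order.  Depth maps are stored as 16-bit
grayscale PNGs (raw value × ``depth_scale`` = millimetres, 0 = invalid) with a
YAML sidecar holding intrinsics, frame rate and timestamps.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import List, Sequence

import imageio.v2 as iio
import numpy as np
import yaml

__all__ = [
    "CameraIntrinsics",
    "DepthFrame",
    "PointCloud",
    "DEFAULT_INTRINSICS",
    "deproject",
    "project",
    "read_depth_sequence",
    "write_depth_sequence",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    depth_scale: float = 1.0  # mm per raw unit

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    def scaled(self, factor: float) -> "CameraIntrinsics":
        """Intrinsics for the same camera at ``factor``× the resolution."""
        return CameraIntrinsics(
            fx=self.fx * factor,
            fy=self.fy * factor,
            cx=self.cx * factor,
            cy=self.cy * factor,
            width=int(round(self.width * factor)),
            height=int(round(self.height * factor)),
            depth_scale=self.depth_scale,
        )


#: Default fixture approximating an Intel RealSense D415-class depth camera.
DEFAULT_INTRINSICS = CameraIntrinsics(
    fx=460.0, fy=460.0, cx=320.0, cy=180.0, width=640, height=360, depth_scale=1.0
)


@dataclass
class DepthFrame:
    """One depth map (mm, 0 = invalid) + timestamp (s) + intrinsics."""

    depth: np.ndarray
    timestamp: float
    intrinsics: CameraIntrinsics

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (self.intrinsics.height, self.intrinsics.width):
            raise ValueError("depth map shape does not match intrinsics")


@dataclass
class PointCloud:
    """3D points (N×3, mm, camera frame) with their source pixels (N×2, row/col)."""

    points: np.ndarray
    pixel_index: np.ndarray

    def __len__(self) -> int:
        return len(self.points)


def deproject(frame: DepthFrame) -> PointCloud:
    """Back-project every valid depth pixel to a 3D point (camera frame, mm)."""
    k = frame.intrinsics
    rows, cols = np.nonzero(frame.depth > 0)
    z = frame.depth[rows, cols]
    x = (cols - k.cx) * z / k.fx
    y = (rows - k.cy) * z / k.fy
    return PointCloud(
        points=np.column_stack([x, y, z]),
        pixel_index=np.column_stack([rows, cols]),
    )


def project(points: np.ndarray, intrinsics: CameraIntrinsics) -> np.ndarray:
    """Pinhole projection to (row, col) pixel coordinates; no clipping.

    Entries with non-positive depth are returned as NaN (flagged invalid).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    z = pts[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        col = pts[:, 0] * intrinsics.fx / z + intrinsics.cx
        row = pts[:, 1] * intrinsics.fy / z + intrinsics.cy
    out = np.column_stack([row, col])
    out[z <= 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# sequence files

_SIDECAR = "sequence.yaml"


class DepthFormatError(ValueError):
    """Raised on malformed depth sequences (missing sidecar, wrong bit depth)."""


def write_depth_sequence(frames: Sequence[DepthFrame], path: str) -> None:
    """Write frames as zero-padded 16-bit PNGs + a YAML sidecar (lossless)."""
    os.makedirs(path, exist_ok=True)
    k = frames[0].intrinsics
    names = []
    for i, frame in enumerate(frames):
        raw = np.round(frame.depth / k.depth_scale).astype(np.uint16)
        name = f"frame_{i:06d}.png"
        iio.imwrite(os.path.join(path, name), raw)
        names.append(name)
    meta = {
        "intrinsics": {
            "fx": k.fx,
            "fy": k.fy,
            "cx": k.cx,
            "cy": k.cy,
            "width": k.width,
            "height": k.height,
            "depth_scale": k.depth_scale,
        },
        "timestamps": [float(f.timestamp) for f in frames],
        "frames": names,
    }
    with open(os.path.join(path, _SIDECAR), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_depth_sequence(path: str) -> List[DepthFrame]:
    """Read a PNG + sidecar sequence written by :func:`write_depth_sequence`."""
    sidecar = os.path.join(path, _SIDECAR)
    if not os.path.exists(sidecar):
        raise DepthFormatError(f"missing sidecar file {sidecar}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    k = CameraIntrinsics(**meta["intrinsics"])
    frames = []
    for name, ts in zip(meta["frames"], meta["timestamps"]):
        raw = iio.imread(os.path.join(path, name))
        if raw.dtype != np.uint16:
            raise DepthFormatError(
                f"{name}: expected 16-bit depth PNG, got dtype {raw.dtype}"
            )
        frames.append(
            DepthFrame(depth=raw.astype(float) * k.depth_scale, timestamp=ts, intrinsics=k)
        )
    return frames
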