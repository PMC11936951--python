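"""RGB-D geometry: pinhole back-projection and density-based cloud denoising.

A depth camera observing the torso yields, per view, a color raster and a
pixel-aligned depth raster in millimeters.  Back-projecting every valid-depth
pixel through the pinhole intrinsics produces a colored 3D point cloud in
that view's camera frame (x right, y down, z along the optical axis).  The
raw cloud also contains points from the surrounding room; density clustering
(DBSCAN) keeps only the largest connected high-density region, which for a
torso acquisition at ~60 cm is the subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .errors import ConfigError, EmptyClusterError, InvalidInputError

__all__ = [
    "CameraIntrinsics",
    "RGBDFrame",
    "ColoredPointCloud",
    "DenoiseConfig",
    "backproject_frame",
    "project_points",
    "denoise_cloud",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole camera parameters, all in pixel units.

    ``(u, v) = (column, row)`` with the origin at the top-left pixel (0, 0).
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise InvalidInputError("focal lengths must be positive")
        if not (0 <= self.cx < self.width) or not (0 <= self.cy < self.height):
            raise InvalidInputError("principal point must lie inside the image")

    def as_dict(self) -> dict:
        return {
            "fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
            "width": self.width, "height": self.height,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"],
                   width=int(d["width"]), height=int(d["height"]))


@dataclass
class RGBDFrame:
    """One view: 8-bit RGB raster plus depth raster in millimeters.

    Depth 0 marks an invalid pixel (no return).  Depth is held as float
    millimeters in memory; the 16-bit integer-mm quantization applies only to
    the on-disk PNG representation.
    """

    rgb: np.ndarray
    depth: np.ndarray
    intrinsics: CameraIntrinsics
    view_index: int = 0

    def __post_init__(self):
        self.rgb = np.asarray(self.rgb)
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise InvalidInputError("rgb must be H x W x 3")
        if self.depth.shape != self.rgb.shape[:2]:
            raise InvalidInputError("rgb and depth rasters disagree in size")
        if self.depth.shape != (self.intrinsics.height, self.intrinsics.width):
            raise InvalidInputError("raster size does not match intrinsics")
        if np.any(self.depth < 0):
            raise InvalidInputError("depth values must be >= 0")


@dataclass
class ColoredPointCloud:
    """3D points (millimeters) with parallel RGB colors in [0, 1]."""

    points: np.ndarray
    colors: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.colors = np.asarray(self.colors, dtype=np.float64).reshape(-1, 3)
        if len(self.points) != len(self.colors):
            raise InvalidInputError("points and colors must be parallel")
        if not np.all(np.isfinite(self.points)):
            raise InvalidInputError("point coordinates must be finite")

    @property
    def size(self) -> int:
        return len(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def take(self, index) -> "ColoredPointCloud":
        return ColoredPointCloud(self.points[index], self.colors[index])


@dataclass(frozen=True)
class DenoiseConfig:
    """DBSCAN parameters: neighborhood radius (mm) and core-point count."""

    eps: float = 20.0
    min_points: int = 10

    def __post_init__(self):
        if self.eps <= 0:
            raise ConfigError("eps must be > 0")
        if self.min_points < 1:
            raise ConfigError("min_points must be >= 1")


def backproject_frame(frame: RGBDFrame, stride: int = 1) -> ColoredPointCloud:
    """Back-project every valid-depth pixel of ``frame`` to a 3D point.

    A pixel (u, v) with depth d > 0 maps to
    ``x = (u - cx) d / fx, y = (v - cy) d / fy, z = d`` in the camera frame.
    Output order is row-major over contributing pixels.  ``stride`` optionally
    subsamples the pixel grid (stride 2 keeps every second row/column), which
    bounds downstream clustering and registration cost.
    """
    if stride < 1:
        raise InvalidInputError("stride must be >= 1")
    intr = frame.intrinsics
    depth = frame.depth[::stride, ::stride]
    rgb = frame.rgb[::stride, ::stride]
    v_idx, u_idx = np.nonzero(depth > 0)
    d = depth[v_idx, u_idx]
    u = u_idx * stride
    v = v_idx * stride
    x = (u - intr.cx) * d / intr.fx
    y = (v - intr.cy) * d / intr.fy
    points = np.column_stack([x, y, d])
    colors = rgb[v_idx, u_idx].astype(np.float64) / 255.0
    return ColoredPointCloud(points, colors)


def project_points(points: np.ndarray, intrinsics: CameraIntrinsics) -> np.ndarray:
    """Project camera-frame points to (u, v) pixel coordinates (float).

    Points must have z > 0; the caller is responsible for culling.
    """
    p = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    z = p[:, 2]
    u = intrinsics.fx * p[:, 0] / z + intrinsics.cx
    v = intrinsics.fy * p[:, 1] / z + intrinsics.cy
    return np.column_stack([u, v])


def denoise_cloud(cloud: ColoredPointCloud, config: DenoiseConfig = DenoiseConfig()) -> ColoredPointCloud:
    """Keep exactly the largest density cluster of ``cloud``.

    DBSCAN labels low-density points as noise; all noise points and every
    cluster other than the one of maximal cardinality are dropped, colors
    traveling with their points.  Ties in cluster size break toward the lowest
    cluster index, which under scikit-learn's deterministic point ordering
    makes repeated runs reproducible.

    Raises
    ------
    EmptyClusterError
        If every point is labeled noise (eps/min_points mis-set).
    """
    if cloud.size == 0:
        raise InvalidInputError("cannot denoise an empty cloud")
    labels = DBSCAN(eps=config.eps, min_samples=config.min_points).fit(cloud.points).labels_
    clustered = labels >= 0
    if not np.any(clustered):
        raise EmptyClusterError(
            f"no density cluster found (eps={config.eps}, min_points={config.min_points})"
        )
    counts = np.bincount(labels[clustered])
    keep = labels == int(np.argmax(counts))  # argmax -> lowest index on ties
    return cloud.take(keep)
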