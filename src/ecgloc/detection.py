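"""Electrode detections, 3D center extraction, and multi-view fusion.

Strip electrodes come in four color classes (A brown, B red, C orange,
D yellow).  A per-view detector supplies class-labeled bounding boxes; each
box's valid-depth pixels are back-projected and averaged to one 3D center in
that view's camera frame.  Centers from all views are mapped into the frame
of view 0 with the reconstruction transforms and fused: same-class centers
within a merge radius are grouped by single linkage and averaged, the group
size becoming the electrode's view support.

The bundled reference detector handles only synthetic phantom renderings
(uniform background, saturated class-colored disks); a trained detector for
real imagery plugs in through the same ``Detection`` records, e.g. loaded
from a JSON-lines file.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label, regionprops

from .errors import ConfigError, InvalidInputError
from .geometry import RGBDFrame
from .registration import RigidTransform

__all__ = [
    "ElectrodeClass",
    "CLASS_COLORS",
    "Detection",
    "ElectrodeCloud",
    "detect_electrodes_reference",
    "extract_centers_3d",
    "fuse_views",
]


class ElectrodeClass(Enum):
    """The four electrode color classes of the 118-channel strip set."""

    A = "brown"
    B = "red"
    C = "orange"
    D = "yellow"

    @property
    def label(self) -> str:
        return self.name

    @property
    def color_name(self) -> str:
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "ElectrodeClass":
        try:
            return cls[label]
        except KeyError as exc:
            raise InvalidInputError(f"unknown electrode class {label!r}") from exc


#: Render/reference-detector RGB prototypes, one saturated color per class.
CLASS_COLORS: dict[ElectrodeClass, tuple[int, int, int]] = {
    ElectrodeClass.A: (121, 64, 18),    # brown
    ElectrodeClass.B: (225, 30, 30),    # red
    ElectrodeClass.C: (255, 140, 0),    # orange
    ElectrodeClass.D: (250, 222, 40),   # yellow
}


@dataclass(frozen=True)
class Detection:
    """One electrode bounding box, half-open pixel interval, in one view."""

    bbox: tuple[float, float, float, float]  # (u_min, v_min, u_max, v_max)
    cls: ElectrodeClass
    confidence: float = 1.0
    view_index: int = 0

    def __post_init__(self):
        u0, v0, u1, v1 = self.bbox
        if not (u0 < u1 and v0 < v1):
            raise InvalidInputError("bbox must satisfy u_min < u_max, v_min < v_max")
        if not (0.0 <= self.confidence <= 1.0):
            raise InvalidInputError("confidence must be in [0, 1]")


@dataclass
class ElectrodeCloud:
    """Fused 3D electrodes in the frame of view 0.

    ``support`` counts contributing views per electrode; ``members`` keeps the
    per-group source centers so that the mean-conservation property can be
    re-asserted from stored membership.
    """

    positions: np.ndarray
    classes: list
    support: np.ndarray
    members: list | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        self.support = np.asarray(self.support, dtype=int).reshape(-1)
        if not (len(self.positions) == len(self.classes) == len(self.support)):
            raise InvalidInputError("positions, classes and support must be parallel")
        if len(self.support) and self.support.min() < 1:
            raise InvalidInputError("support must be >= 1")

    def __len__(self) -> int:
        return len(self.positions)


def detect_electrodes_reference(
    rgb: np.ndarray,
    min_area: int = 20,
    color_tol: float = 60.0,
) -> list[Detection]:
    """Reference detector for synthetic renders: connected class-colored blobs.

    Pixels within ``color_tol`` (Euclidean RGB) of a class prototype are
    masked per class; 8-connected components with at least ``min_area`` pixels
    become detections with tight bounding boxes.  A blank image yields an
    empty list.  This is a stand-in for a trained object detector and assumes
    flat, saturated disk colors on a non-matching background.
    """
    img = np.asarray(rgb, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidInputError("rgb must be H x W x 3")
    detections: list[Detection] = []
    for cls, proto in CLASS_COLORS.items():
        dist = np.linalg.norm(img - np.asarray(proto, dtype=np.float64), axis=2)
        mask = dist < color_tol
        if not mask.any():
            continue
        labeled = cc_label(mask, connectivity=2)
        for region in regionprops(labeled):
            if region.area < min_area:
                continue
            v0, u0, v1, u1 = region.bbox  # skimage bbox is half-open
            detections.append(Detection(bbox=(u0, v0, u1, v1), cls=cls))
    detections.sort(key=lambda d: (d.bbox[1], d.bbox[0], d.cls.name))
    return detections


def extract_centers_3d(
    detections: Sequence[Detection],
    frame: RGBDFrame,
) -> tuple[np.ndarray, list, list]:
    """Average each detection's back-projected valid-depth pixels to a 3D center.

    Pixels inside the bounding box with depth > 0 are back-projected through
    the frame's intrinsics; their arithmetic mean is the electrode center in
    this view's camera frame.  Detections without any valid depth are dropped.

    Returns
    -------
    (centers, classes, dropped) : centers is (n, 3); ``dropped`` lists the
    indices (into ``detections``) of boxes containing no valid depth.
    """
    intr = frame.intrinsics
    centers = []
    classes = []
    dropped = []
    for i, det in enumerate(detections):
        if det.view_index != frame.view_index:
            raise InvalidInputError(
                f"detection view {det.view_index} does not match frame {frame.view_index}"
            )
        u0, v0, u1, v1 = det.bbox
        u0i, v0i = max(int(np.floor(u0)), 0), max(int(np.floor(v0)), 0)
        u1i = min(int(np.ceil(u1)), intr.width)
        v1i = min(int(np.ceil(v1)), intr.height)
        patch = frame.depth[v0i:v1i, u0i:u1i]
        vv, uu = np.nonzero(patch > 0)
        if len(vv) == 0:
            dropped.append(i)
            continue
        d = patch[vv, uu]
        u = uu + u0i
        v = vv + v0i
        x = (u - intr.cx) * d / intr.fx
        y = (v - intr.cy) * d / intr.fy
        centers.append(np.array([x.mean(), y.mean(), d.mean()]))
        classes.append(det.cls)
    centers_arr = np.asarray(centers, dtype=np.float64).reshape(-1, 3)
    return centers_arr, classes, dropped


def fuse_views(
    per_view_centers: Sequence[tuple[np.ndarray, Sequence[ElectrodeClass]]],
    transforms: Sequence[RigidTransform],
    merge_radius: float = 14.0,
    nominal_spacing: float = 30.0,
) -> ElectrodeCloud:
    """Fuse per-view electrode centers into one cloud in the frame of view 0.

    Centers are mapped through their view's transform; same-class centers
    within ``merge_radius`` are grouped by single linkage (connected
    components of the radius graph) and each group is replaced by its
    arithmetic mean, with support equal to the group size.  Groups never span
    classes.  The output ordering is deterministic: by class, then
    lexicographically by fused position.

    Raises
    ------
    ConfigError
        If ``merge_radius`` is not positive or reaches half the nominal
        inter-electrode spacing (adjacent electrodes could merge).
    """
    if merge_radius <= 0:
        raise ConfigError("merge_radius must be > 0")
    if merge_radius >= nominal_spacing / 2:
        raise ConfigError(
            f"merge_radius {merge_radius} >= half the nominal spacing "
            f"{nominal_spacing}; neighboring electrodes would merge"
        )
    if len(per_view_centers) != len(transforms):
        raise InvalidInputError("one transform per view is required")
    all_pos = []
    all_cls = []
    for (centers, classes), transform in zip(per_view_centers, transforms):
        centers = np.asarray(centers, dtype=np.float64).reshape(-1, 3)
        if len(centers) != len(classes):
            raise InvalidInputError("centers and classes must be parallel per view")
        if len(centers):
            all_pos.append(transform.apply(centers))
            all_cls.extend(classes)
    if not all_pos:
        return ElectrodeCloud(np.empty((0, 3)), [], np.empty(0, dtype=int), members=[])
    pos = np.vstack(all_pos)
    cls_arr = np.asarray([c.name for c in all_cls])

    fused_pos, fused_cls, fused_support, members = [], [], [], []
    for cls in ElectrodeClass:
        idx = np.nonzero(cls_arr == cls.name)[0]
        if len(idx) == 0:
            continue
        pts = pos[idx]
        pairs = cKDTree(pts).query_pairs(merge_radius, output_type="ndarray")
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
            shape=(len(pts), len(pts)),
        )
        n_comp, comp = connected_components(graph, directed=False)
        for c in range(n_comp):
            group = pts[comp == c]
            fused_pos.append(group.mean(axis=0))
            fused_cls.append(cls)
            fused_support.append(len(group))
            members.append(group)
    order = np.lexsort(
        (
            [p[2] for p in fused_pos],
            [p[1] for p in fused_pos],
            [p[0] for p in fused_pos],
            [c.name for c in fused_cls],
        )
    )
    return ElectrodeCloud(
        positions=np.asarray(fused_pos)[order],
        classes=[fused_cls[i] for i in order],
        support=np.asarray(fused_support, dtype=int)[order],
        members=[members[i] for i in order],
    )
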