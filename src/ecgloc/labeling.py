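"""Sequential channel labeling of fused electrodes by strip growing.

Strip electrodes are wired in fixed acquisition order: channels run from the
first electrode of class A to the last of class D, strip by strip.  Given
fused 3D electrode positions, the labeler reproduces that order

* seeding the first strip of each class from the two electrodes of that class
  whose image projections in a chosen seed view lie closest to pixel (0, 0),
* growing a strip by repeatedly taking, among unlabeled same-class
  electrodes within 35 mm Euclidean distance and 15 mm along the x-axis of
  the current electrode, the one closest (perpendicular distance) to the line
  through the previous two — so strips extend collinearly,
* terminating a strip when no candidate passes both gates, and seeding the
  next strip of the class from the nearest unlabeled same-class pair to the
  previous strip's start.

All tie-breaks are lexicographic (smaller v then u in the image, smaller
x, y, z in 3D), making the labeling deterministic and invariant to the input
ordering of the electrode cloud.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detection import ElectrodeCloud, ElectrodeClass
from .errors import ConfigError, InvalidInputError, SeedingError
from .geometry import RGBDFrame, project_points
from .registration import RigidTransform

__all__ = [
    "LabelingConfig",
    "LabeledElectrodeMap",
    "seed_first_pair",
    "next_in_strip",
    "label_all",
    "project_visible",
]

_DEFAULT_ORDER = (ElectrodeClass.A, ElectrodeClass.B, ElectrodeClass.C, ElectrodeClass.D)


@dataclass(frozen=True)
class LabelingConfig:
    """Gates of the strip-growing rule.

    ``max_step_dist``: admissible Euclidean distance (mm) between consecutive
    electrodes of a strip (nominal spacing is 30 mm).
    ``max_x_dev``: admissible |Δx| (mm) between consecutive electrodes;
    strips run roughly vertically, so a large lateral step signals a jump to
    a neighboring strip.
    """

    max_step_dist: float = 35.0
    max_x_dev: float = 15.0
    class_order: tuple = _DEFAULT_ORDER

    def __post_init__(self):
        if not (self.max_step_dist > self.max_x_dev > 0):
            raise ConfigError("require max_step_dist > max_x_dev > 0")


@dataclass
class LabeledElectrodeMap:
    """Ordered electrode map: positions with class, channel and strip index.

    Channels are consecutive integers 1..n with no repeats, non-decreasing in
    class order; strip indices count strips in discovery order.
    """

    positions: np.ndarray
    classes: list
    channels: np.ndarray
    strips: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        self.channels = np.asarray(self.channels, dtype=int).reshape(-1)
        self.strips = np.asarray(self.strips, dtype=int).reshape(-1)
        n = len(self.positions)
        if not (n == len(self.classes) == len(self.channels) == len(self.strips)):
            raise InvalidInputError("map fields must be parallel")
        if n and sorted(self.channels) != list(range(1, n + 1)):
            raise InvalidInputError("channels must be a permutation of 1..n")

    def __len__(self) -> int:
        return len(self.positions)

    def in_channel_order(self) -> "LabeledElectrodeMap":
        order = np.argsort(self.channels)
        return LabeledElectrodeMap(
            self.positions[order],
            [self.classes[i] for i in order],
            self.channels[order],
            self.strips[order],
        )

    def scaled(self, factor: float) -> "LabeledElectrodeMap":
        return LabeledElectrodeMap(
            self.positions * factor, list(self.classes), self.channels.copy(), self.strips.copy()
        )


def seed_first_pair(image_centers: Sequence[tuple[float, float, int]]):
    """Two electrode ids whose pixel centers lie closest to pixel (0, 0).

    ``image_centers`` holds (u, v, electrode_id) for the seeding class in the
    chosen view.  Returns (first_id, second_id) ordered by distance to the
    image origin; ties break by smaller v, then smaller u.

    Raises
    ------
    SeedingError
        If fewer than two centers are supplied.
    """
    if len(image_centers) < 2:
        raise SeedingError(
            f"need >= 2 visible electrodes of the seeding class, got {len(image_centers)}",
            cls="?", view_index=-1,
        )
    ranked = sorted(image_centers, key=lambda c: (np.hypot(c[0], c[1]), c[1], c[0]))
    return ranked[0][2], ranked[1][2]


def next_in_strip(
    prev: np.ndarray,
    curr: np.ndarray,
    candidates: Sequence[tuple[np.ndarray, int]],
    config: LabelingConfig = LabelingConfig(),
):
    """Next electrode of the strip, or None when the strip terminates.

    Candidates must pass both gates relative to ``curr`` (Euclidean distance
    < max_step_dist and |Δx| < max_x_dev); among those, the one minimizing
    perpendicular distance to the line through ``prev`` and ``curr`` wins,
    with lexicographic position tie-break.
    """
    prev = np.asarray(prev, dtype=np.float64)
    curr = np.asarray(curr, dtype=np.float64)
    direction = curr - prev
    norm = np.linalg.norm(direction)
    axis = direction / norm if norm > 0 else None
    best = None
    for pos, cand_id in candidates:
        pos = np.asarray(pos, dtype=np.float64)
        delta = pos - curr
        if np.linalg.norm(delta) >= config.max_step_dist:
            continue
        if abs(delta[0]) >= config.max_x_dev:
            continue
        if axis is None:
            perp = float(np.linalg.norm(delta))
        else:
            perp = float(np.linalg.norm(delta - np.dot(delta, axis) * axis))
        key = (perp, pos[0], pos[1], pos[2])
        if best is None or key < best[0]:
            best = (key, cand_id)
    return None if best is None else best[1]


def project_visible(
    positions: np.ndarray,
    frame: RGBDFrame,
    map_to_camera: RigidTransform = None,
    depth_tol: float = 10.0,
) -> list[tuple[float, float, int]]:
    """Project map-frame positions into ``frame`` and keep the visible ones.

    A position is visible when it projects inside the image with positive
    depth and the frame's depth at that pixel agrees with the projected depth
    within ``depth_tol`` mm (occlusion / back-face test against the rendered
    or sensed surface).  Returns (u, v, index) triples.
    """
    if map_to_camera is None:
        map_to_camera = RigidTransform.identity()
    cam = map_to_camera.apply(np.asarray(positions, dtype=np.float64).reshape(-1, 3))
    out = []
    intr = frame.intrinsics
    for i, p in enumerate(cam):
        if p[2] <= 0:
            continue
        uv = project_points(p[None, :], intr)[0]
        u, v = float(uv[0]), float(uv[1])
        ui, vi = int(round(u)), int(round(v))
        if not (0 <= ui < intr.width and 0 <= vi < intr.height):
            continue
        d = frame.depth[vi, ui]
        if d <= 0 or abs(d - p[2]) > depth_tol:
            continue
        out.append((u, v, i))
    return out


def label_all(
    cloud: ElectrodeCloud,
    seed_frame: RGBDFrame,
    config: LabelingConfig = LabelingConfig(),
    map_to_seed_camera: RigidTransform = None,
) -> LabeledElectrodeMap:
    """Assign sequential channel indices to every electrode of ``cloud``.

    Classes are processed in ``config.class_order``.  The first strip of each
    class is seeded from the two class electrodes closest to pixel (0, 0) of
    the seed view (``seed_frame``; positions are mapped into its camera frame
    by ``map_to_seed_camera``, identity when the cloud already lives in that
    frame).  Subsequent strips seed from the unlabeled same-class strip
    endpoint (an electrode with at most one gated unlabeled neighbor, i.e. a
    strip end rather than an interior electrode) nearest to the previous
    strip's start, paired with its gated nearest neighbor.  Strips grow with the gated
    collinearity rule until termination.  Channels are numbered sequentially
    in discovery order across the whole map.

    Electrodes that cannot be paired (no same-class partner within the gates)
    are labeled as singleton strips and reported in a completeness warning.
    """
    if len(cloud) == 0:
        raise InvalidInputError("electrode cloud is empty")
    pos = cloud.positions
    cls_names = np.asarray([c.name for c in cloud.classes])
    channels = np.zeros(len(pos), dtype=int)
    strips = np.zeros(len(pos), dtype=int)
    channel = 0
    strip = 0
    orphans: list[int] = []

    for cls in config.class_order:
        remaining = set(np.nonzero(cls_names == cls.name)[0].tolist())
        if not remaining:
            continue
        first_strip_of_class = True
        strip_start = None
        while remaining:
            rem_sorted = sorted(remaining)
            if first_strip_of_class:
                visible = [
                    (u, v, i)
                    for (u, v, i) in project_visible(pos, seed_frame, map_to_seed_camera)
                    if i in remaining
                ]
                if len(visible) < 2:
                    raise SeedingError(
                        f"class {cls.name}: {len(visible)} visible electrode(s) in "
                        f"seed view {seed_frame.view_index}, need 2",
                        cls=cls.name,
                        view_index=seed_frame.view_index,
                    )
                first, second = seed_first_pair(visible)
                first_strip_of_class = False
            else:
                # Seed from a strip endpoint: interior electrodes have two
                # gated neighbors, strip ends at most one.  Seeding from an
                # interior electrode would split its strip and reverse part
                # of the traversal order.
                def gated_degree(i):
                    deg = 0
                    for j in rem_sorted:
                        if j == i:
                            continue
                        delta = pos[j] - pos[i]
                        if (np.linalg.norm(delta) < config.max_step_dist
                                and abs(delta[0]) < config.max_x_dev):
                            deg += 1
                    return deg

                endpoints = [i for i in rem_sorted if gated_degree(i) <= 1]
                pool = endpoints if endpoints else rem_sorted
                first = min(
                    pool,
                    key=lambda i: (np.linalg.norm(pos[i] - strip_start), *pos[i]),
                )
                second = None
                best_key = None
                for i in rem_sorted:
                    if i == first:
                        continue
                    delta = pos[i] - pos[first]
                    dist = np.linalg.norm(delta)
                    if dist >= config.max_step_dist or abs(delta[0]) >= config.max_x_dev:
                        continue
                    key = (dist, *pos[i])
                    if best_key is None or key < best_key:
                        best_key, second = key, i
            strip += 1
            strip_start = pos[first].copy()
            channel += 1
            channels[first], strips[first] = channel, strip
            remaining.discard(first)
            if second is None:
                orphans.append(int(first))
                continue
            channel += 1
            channels[second], strips[second] = channel, strip
            remaining.discard(second)
            prev_i, curr_i = first, second
            while True:
                cands = [(pos[i], i) for i in sorted(remaining)]
                nxt = next_in_strip(pos[prev_i], pos[curr_i], cands, config)
                if nxt is None:
                    break
                channel += 1
                channels[nxt], strips[nxt] = channel, strip
                remaining.discard(nxt)
                prev_i, curr_i = curr_i, nxt

    if orphans:
        warnings.warn(
            f"{len(orphans)} electrode(s) could not be paired into a strip and were "
            f"labeled as singleton strips: indices {orphans}",
            stacklevel=2,
        )
    return LabeledElectrodeMap(pos, list(cloud.classes), channels, strips)
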