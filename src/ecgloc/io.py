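"""Readers and writers for the pipeline's on-disk formats.

PNG (8-bit RGB, 16-bit integer-millimeter depth with 0 = invalid),
intrinsics JSON, detections JSON-lines, electrode maps and fused clouds as
CSV, transforms as JSON 4x4 row-major homogeneous matrices, and point clouds
as binary little-endian PLY with per-vertex color (written by hand; no PLY
library is assumed).
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .detection import Detection, ElectrodeClass, ElectrodeCloud
from .errors import InvalidInputError
from .geometry import CameraIntrinsics, ColoredPointCloud
from .labeling import LabeledElectrodeMap
from .registration import RigidTransform

__all__ = [
    "write_rgb_png", "read_rgb_png", "write_depth_png", "read_depth_png",
    "write_intrinsics", "read_intrinsics",
    "write_detections_jsonl", "read_detections_jsonl",
    "write_ply", "read_ply",
    "write_labeled_map_csv", "read_labeled_map_csv",
    "write_fused_csv",
    "write_transforms_json", "read_transforms_json",
]


def write_rgb_png(path, rgb: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(rgb, dtype=np.uint8))


def read_rgb_png(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))[..., :3]


def write_depth_png(path, depth_mm: np.ndarray) -> None:
    """Quantize float millimeters to 16-bit integer millimeters (0 = invalid)."""
    q = np.clip(np.round(np.asarray(depth_mm, dtype=np.float64)), 0, 65535).astype(np.uint16)
    iio.imwrite(Path(path), q)


def read_depth_png(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))).astype(np.float64)


def write_intrinsics(path, intrinsics: CameraIntrinsics) -> None:
    Path(path).write_text(json.dumps(intrinsics.as_dict(), indent=1))


def read_intrinsics(path) -> CameraIntrinsics:
    return CameraIntrinsics.from_dict(json.loads(Path(path).read_text()))


def write_detections_jsonl(path, detections) -> None:
    """One JSON object per line: view, bbox corners, class, confidence."""
    with open(path, "w") as fh:
        for d in detections:
            u0, v0, u1, v1 = d.bbox
            fh.write(json.dumps({
                "view": d.view_index,
                "u_min": u0, "v_min": v0, "u_max": u1, "v_max": v1,
                "class": d.cls.name, "confidence": d.confidence,
            }) + "\n")


def read_detections_jsonl(path) -> list[Detection]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            out.append(Detection(
                bbox=(rec["u_min"], rec["v_min"], rec["u_max"], rec["v_max"]),
                cls=ElectrodeClass.from_label(rec["class"]),
                confidence=rec.get("confidence", 1.0),
                view_index=int(rec["view"]),
            ))
        except (KeyError, ValueError, json.JSONDecodeError) as exc:
            raise InvalidInputError(f"{path}: bad detection on line {lineno}: {exc}") from exc
    return out


def write_ply(path, cloud: ColoredPointCloud) -> None:
    """Binary little-endian PLY: float32 xyz + uchar rgb per vertex."""
    n = cloud.size
    header = (
        "ply\nformat binary_little_endian 1.0\n"
        f"element vertex {n}\n"
        "property float x\nproperty float y\nproperty float z\n"
        "property uchar red\nproperty uchar green\nproperty uchar blue\n"
        "end_header\n"
    )
    rec = np.empty(n, dtype=[("xyz", "<f4", 3), ("rgb", "u1", 3)])
    rec["xyz"] = cloud.points.astype(np.float32)
    rec["rgb"] = np.clip(np.round(cloud.colors * 255.0), 0, 255).astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(rec.tobytes())


def read_ply(path) -> ColoredPointCloud:
    raw = Path(path).read_bytes()
    end = raw.find(b"end_header\n")
    if end < 0:
        raise InvalidInputError(f"{path}: not a PLY file")
    header = raw[:end].decode("ascii").splitlines()
    n = None
    for line in header:
        if line.startswith("element vertex"):
            n = int(line.split()[-1])
        if line.startswith("format") and "binary_little_endian" not in line:
            raise InvalidInputError(f"{path}: only binary little-endian PLY is supported")
    if n is None:
        raise InvalidInputError(f"{path}: missing vertex element")
    body = raw[end + len(b"end_header\n"):]
    rec = np.frombuffer(body, dtype=[("xyz", "<f4", 3), ("rgb", "u1", 3)], count=n)
    return ColoredPointCloud(rec["xyz"].astype(np.float64),
                             rec["rgb"].astype(np.float64) / 255.0)


_MAP_COLUMNS = ["channel", "strip", "class", "x_mm", "y_mm", "z_mm"]


def write_labeled_map_csv(path, emap: LabeledElectrodeMap) -> None:
    m = emap.in_channel_order()
    pd.DataFrame({
        "channel": m.channels,
        "strip": m.strips,
        "class": [c.name for c in m.classes],
        "x_mm": m.positions[:, 0],
        "y_mm": m.positions[:, 1],
        "z_mm": m.positions[:, 2],
    }).to_csv(path, index=False, float_format="%.6f")


def read_labeled_map_csv(path) -> LabeledElectrodeMap:
    df = pd.read_csv(path)
    missing = [c for c in _MAP_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    return LabeledElectrodeMap(
        positions=df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        classes=[ElectrodeClass.from_label(str(c)) for c in df["class"]],
        channels=df["channel"].to_numpy(dtype=int),
        strips=df["strip"].to_numpy(dtype=int),
    )


def write_fused_csv(path, cloud: ElectrodeCloud) -> None:
    pd.DataFrame({
        "x_mm": cloud.positions[:, 0],
        "y_mm": cloud.positions[:, 1],
        "z_mm": cloud.positions[:, 2],
        "class": [c.name for c in cloud.classes],
        "support": cloud.support,
    }).to_csv(path, index=False, float_format="%.6f")


def write_transforms_json(path, transforms) -> None:
    Path(path).write_text(json.dumps(
        [t.as_matrix().reshape(-1).tolist() for t in transforms], indent=1
    ))


def read_transforms_json(path) -> list[RigidTransform]:
    data = json.loads(Path(path).read_text())
    return [RigidTransform.from_matrix(np.asarray(m, dtype=float).reshape(4, 4)) for m in data]
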