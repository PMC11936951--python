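"""Pipeline orchestration: simulate, localize + label, calibrate, evaluate.

``localize_frames`` is the in-memory core: back-projection, density
denoising, sequential two-stage ICP reconstruction, per-view electrode
extraction, cross-view fusion, and channel labeling.  ``run_localize`` wraps
it with dataset-directory I/O; ``simulate_dataset`` writes a phantom
rendering in the exact layout ``run_localize`` consumes; ``run_evaluate``
compares two labeled maps and writes an error report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .detection import (Detection, ElectrodeCloud, detect_electrodes_reference,
                        extract_centers_3d, fuse_views)
from .errors import InvalidInputError
from .evaluation import CalibrationConfig, ErrorReport, calibrate_scale, localization_errors
from .geometry import (ColoredPointCloud, DenoiseConfig, RGBDFrame,
                       backproject_frame, denoise_cloud)
from .labeling import LabeledElectrodeMap, LabelingConfig, label_all
from .phantom import (CameraPath, NoiseConfig, PhantomScene, RespirationConfig,
                      build_phantom, render_views)
from .registration import IcpConfig, RigidTransform, reconstruct_torso

__all__ = [
    "FusionConfig", "PipelineConfig", "LocalizeResult",
    "localize_frames", "run_localize", "run_evaluate", "simulate_dataset",
]

log = logging.getLogger("ecgloc")


@dataclass(frozen=True)
class FusionConfig:
    merge_radius: float = 14.0
    nominal_spacing: float = 30.0


@dataclass(frozen=True)
class PipelineConfig:
    """Fully resolved pipeline configuration (nested stage configs)."""

    seed: int = 0
    log_level: str = "INFO"
    stride: int = 2
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    icp: IcpConfig = field(default_factory=IcpConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    respiration: RespirationConfig | None = None

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return [enc(x) for x in obj]
            if hasattr(obj, "name") and obj.__class__.__name__ == "ElectrodeClass":
                return obj.name
            return obj
        return enc(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        from .detection import ElectrodeClass

        data = dict(data or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")

        def sub(key, klass):
            if key not in data:
                return
            val = data[key]
            if val is None:
                data[key] = None
                return
            allowed = {f.name for f in dataclasses.fields(klass)}
            bad = set(val) - allowed
            if bad:
                raise InvalidInputError(f"unknown keys under '{key}': {sorted(bad)}")
            if key == "labeling" and "class_order" in val:
                val = dict(val)
                val["class_order"] = tuple(
                    ElectrodeClass.from_label(c) for c in val["class_order"]
                )
            data[key] = klass(**val)

        sub("denoise", DenoiseConfig)
        sub("icp", IcpConfig)
        sub("fusion", FusionConfig)
        sub("labeling", LabelingConfig)
        sub("calibration", CalibrationConfig)
        sub("noise", NoiseConfig)
        sub("respiration", RespirationConfig)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class LocalizeResult:
    labeled_map: LabeledElectrodeMap
    transforms: list
    fused: ElectrodeCloud
    merged_cloud: ColoredPointCloud
    dropped_detections: int
    stage_seconds: dict


def localize_frames(
    frames: list[RGBDFrame],
    detections_per_view: list[list[Detection]],
    config: PipelineConfig = PipelineConfig(),
) -> LocalizeResult:
    """Full localization from in-memory frames and detections.

    Stages: back-project each frame (pixel stride bounds cluster/ICP cost) ->
    keep the largest density cluster -> chain pairwise ICP into the frame of
    view 0 -> average each detection's depth region to a 3D center at full
    resolution -> fuse same-class centers across views -> label channels by
    strip growing, seeded in view 0.
    """
    if len(frames) != len(detections_per_view):
        raise InvalidInputError("need one detection list per frame")
    if not frames:
        raise InvalidInputError("no frames supplied")
    timings = {}

    t0 = time.perf_counter()
    clouds = [backproject_frame(f, stride=config.stride) for f in frames]
    timings["backproject"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    clouds = [denoise_cloud(c, config.denoise) for c in clouds]
    timings["denoise"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    merged, transforms = reconstruct_torso(clouds, config.icp)
    timings["reconstruct"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    per_view = []
    dropped_total = 0
    for frame, dets in zip(frames, detections_per_view):
        centers, classes, dropped = extract_centers_3d(dets, frame)
        dropped_total += len(dropped)
        per_view.append((centers, classes))
    timings["extract"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fused = fuse_views(
        per_view, transforms,
        merge_radius=config.fusion.merge_radius,
        nominal_spacing=config.fusion.nominal_spacing,
    )
    timings["fuse"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    labeled = label_all(fused, frames[0], config.labeling,
                        map_to_seed_camera=RigidTransform.identity())
    timings["label"] = time.perf_counter() - t0

    for stage, secs in timings.items():
        log.info("stage %-12s %6.2f s", stage, secs)
    return LocalizeResult(
        labeled_map=labeled,
        transforms=transforms,
        fused=fused,
        merged_cloud=merged,
        dropped_detections=dropped_total,
        stage_seconds=timings,
    )


# ---------------------------------------------------------------------------
# dataset directory layout


def simulate_dataset(out_dir, scene: PhantomScene | None = None) -> Path:
    """Render a phantom scene into the dataset layout the pipeline consumes.

    Writes rgb/view_XX.png, depth/view_XX.png (16-bit integer mm),
    intrinsics.json, detections.jsonl, ground_truth.csv and scene.yaml.
    """
    scene = scene or build_phantom()
    out = Path(out_dir)
    (out / "rgb").mkdir(parents=True, exist_ok=True)
    (out / "depth").mkdir(parents=True, exist_ok=True)
    rendered = render_views(scene)
    all_dets = []
    for i, (frame, dets) in enumerate(rendered):
        eio.write_rgb_png(out / "rgb" / f"view_{i:02d}.png", frame.rgb)
        eio.write_depth_png(out / "depth" / f"view_{i:02d}.png", frame.depth)
        all_dets.extend(dets)
    eio.write_intrinsics(out / "intrinsics.json", scene.path.intrinsics)
    eio.write_detections_jsonl(out / "detections.jsonl", all_dets)
    eio.write_labeled_map_csv(out / "ground_truth.csv", scene.ground_truth)
    (out / "scene.yaml").write_text(yaml.safe_dump({
        "n_views": scene.path.n_views,
        "angle_step_deg": scene.path.angle_step,
        "standoff_mm": scene.path.standoff,
        "n_electrodes": len(scene.ground_truth),
        "spacing_mm": scene.layout.spacing,
        "noise": dataclasses.asdict(scene.noise),
        "respiration": dataclasses.asdict(scene.respiration) if scene.respiration else None,
    }))
    return out


def load_dataset(dataset_dir) -> tuple[list[RGBDFrame], list[list[Detection]]]:
    """Load frames (+ per-view detections) from the simulate layout."""
    root = Path(dataset_dir)
    for required in ("rgb", "depth", "intrinsics.json"):
        if not (root / required).exists():
            raise InvalidInputError(f"dataset is missing required input: {required}")
    intr = eio.read_intrinsics(root / "intrinsics.json")
    rgb_files = sorted((root / "rgb").glob("view_*.png"))
    if not rgb_files:
        raise InvalidInputError("dataset has no rgb/view_*.png frames")
    frames = []
    for i, rgb_path in enumerate(rgb_files):
        depth_path = root / "depth" / rgb_path.name
        if not depth_path.exists():
            raise InvalidInputError(f"dataset is missing depth image {depth_path.name}")
        frames.append(RGBDFrame(
            rgb=eio.read_rgb_png(rgb_path),
            depth=eio.read_depth_png(depth_path),
            intrinsics=intr,
            view_index=i,
        ))
    det_path = root / "detections.jsonl"
    per_view: list[list[Detection]] = [[] for _ in frames]
    if det_path.exists():
        for det in eio.read_detections_jsonl(det_path):
            if 0 <= det.view_index < len(frames):
                per_view[det.view_index].append(det)
    else:  # no external detections: fall back to the reference blob detector
        for i, frame in enumerate(frames):
            per_view[i] = [
                Detection(bbox=d.bbox, cls=d.cls, confidence=d.confidence, view_index=i)
                for d in detect_electrodes_reference(frame.rgb)
            ]
    return frames, per_view


def run_localize(
    dataset_dir,
    out_dir,
    config: PipelineConfig = PipelineConfig(),
    calibrate: bool = False,
) -> LocalizeResult:
    """Disk-to-disk localization: load a dataset, localize, write artifacts.

    Writes electrodes.csv, fused.csv, transforms.json, merged.ply, run.log
    and the fully resolved config (provenance) into ``out_dir``.  With
    ``calibrate`` the output map is rescaled so mean within-strip spacing
    matches the calibration config's known spacing.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    try:
        frames, per_view = load_dataset(dataset_dir)
        result = localize_frames(frames, per_view, config)
        labeled = result.labeled_map
        if calibrate:
            labeled, factor = calibrate_scale(labeled, config.calibration)
            log.info("scale calibration factor %.6f", factor)
            result.labeled_map = labeled
        eio.write_labeled_map_csv(out / "electrodes.csv", labeled)
        eio.write_fused_csv(out / "fused.csv", result.fused)
        eio.write_transforms_json(out / "transforms.json", result.transforms)
        eio.write_ply(out / "merged.ply", result.merged_cloud)
        (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
        log.info("labeled %d electrodes (%d detections dropped)",
                 len(labeled), result.dropped_detections)
        return result
    finally:
        log.removeHandler(handler)
        handler.close()


def run_evaluate(
    recon_csv,
    reference_csv,
    out_dir,
    with_scale: bool = False,
) -> ErrorReport:
    """Compare two labeled maps; write report.json and per_electrode.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recon = eio.read_labeled_map_csv(recon_csv)
    reference = eio.read_labeled_map_csv(reference_csv)
    report = localization_errors(recon, reference, with_scale=with_scale)
    (out / "report.json").write_text(json.dumps(report.summary(), indent=1))
    pd.DataFrame({
        "channel": report.channels,
        "err_3d_mm": report.per_electrode_3d,
        "err_x_mm": report.per_axis[:, 0],
        "err_y_mm": report.per_axis[:, 1],
        "err_z_mm": report.per_axis[:, 2],
        "region": report.regions,
    }).to_csv(out / "per_electrode.csv", index=False, float_format="%.6f")
    return report
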