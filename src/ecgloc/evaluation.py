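"""Scale calibration and localization-error metrics for electrode maps.

A reconstruction from an uncalibrated (e.g. monocular-video) source is
metrically ambiguous; since strip electrodes sit exactly 30 mm apart, the
mean adjacent within-strip distance calibrates the global scale.  Accuracy
against a reference map (CT, electromagnetic tracking, or simulator ground
truth) is quantified after least-squares alignment of the two maps: 3D
Euclidean distance per electrode, per-axis absolute differences, their
means +/- SD (n-1 denominator), and a breakdown over torso regions (chest,
abdomen, sides).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InvalidInputError
from .labeling import LabeledElectrodeMap
from .registration import umeyama_align

__all__ = [
    "CalibrationConfig",
    "ErrorReport",
    "mean_adjacent_spacing",
    "calibrate_scale",
    "localization_errors",
    "assign_regions",
]

REGIONS = ("chest", "abdomen", "sides")


@dataclass(frozen=True)
class CalibrationConfig:
    """Known inter-electrode spacing within a strip, millimeters."""

    known_spacing: float = 30.0

    def __post_init__(self):
        if self.known_spacing <= 0:
            raise ConfigError("known_spacing must be > 0")


@dataclass
class ErrorReport:
    """Per-electrode and summary localization errors, all in millimeters."""

    channels: np.ndarray
    per_electrode_3d: np.ndarray
    per_axis: np.ndarray              # (n, 3) |dx|, |dy|, |dz|
    regions: list
    mean_3d: float
    sd_3d: float
    axis_means: np.ndarray
    axis_sds: np.ndarray
    region_stats: dict                # region -> {"mean","sd","n"}

    def summary(self) -> dict:
        return {
            "n": int(len(self.per_electrode_3d)),
            "mean_3d_mm": float(self.mean_3d),
            "sd_3d_mm": float(self.sd_3d),
            "axis_mean_mm": {k: float(v) for k, v in zip("xyz", self.axis_means)},
            "axis_sd_mm": {k: float(v) for k, v in zip("xyz", self.axis_sds)},
            "regions": {
                r: {
                    "mean_mm": float(s["mean"]) if s["n"] else None,
                    "sd_mm": float(s["sd"]) if s["n"] > 1 else None,
                    "n": int(s["n"]),
                }
                for r, s in self.region_stats.items()
            },
        }


def _strip_segments(emap: LabeledElectrodeMap) -> list[np.ndarray]:
    """Consecutive-channel position pairs within each strip."""
    ordered = emap.in_channel_order()
    segs = []
    for strip in np.unique(ordered.strips):
        pts = ordered.positions[ordered.strips == strip]
        if len(pts) >= 2:
            segs.append(np.linalg.norm(np.diff(pts, axis=0), axis=1))
    return segs


def mean_adjacent_spacing(emap: LabeledElectrodeMap) -> float:
    """Mean Euclidean distance over consecutive-channel pairs within strips.

    Raises
    ------
    InvalidInputError
        If no strip holds at least two electrodes.
    """
    segs = _strip_segments(emap)
    if not segs:
        raise InvalidInputError("no strip with >= 2 electrodes")
    return float(np.concatenate(segs).mean())


def calibrate_scale(
    emap: LabeledElectrodeMap,
    config: CalibrationConfig = CalibrationConfig(),
) -> tuple[LabeledElectrodeMap, float]:
    """Rescale ``emap`` so mean adjacent spacing equals the known spacing.

    Returns the scaled map and the applied factor
    ``known_spacing / mean_adjacent_spacing(emap)``.  Idempotent: an
    already-calibrated map yields factor 1.
    """
    factor = config.known_spacing / mean_adjacent_spacing(emap)
    return emap.scaled(factor), float(factor)


def assign_regions(emap: LabeledElectrodeMap) -> list[str]:
    """Label each electrode chest / abdomen / sides.

    Assumes the map frame has Y vertical and Z anterior.  Electrodes within
    +/-60 degrees azimuth of the anterior axis are "front", split at the
    map's median Y into chest (above) and abdomen (at or below); everything
    else is "sides".
    """
    pos = emap.positions
    azimuth = np.degrees(np.arctan2(pos[:, 0], pos[:, 2]))
    front = np.abs(azimuth) <= 60.0
    median_y = np.median(pos[:, 1])
    out = []
    for i in range(len(pos)):
        if not front[i]:
            out.append("sides")
        elif pos[i, 1] > median_y:
            out.append("chest")
        else:
            out.append("abdomen")
    return out


def localization_errors(
    recon: LabeledElectrodeMap,
    reference: LabeledElectrodeMap,
    with_scale: bool = False,
) -> ErrorReport:
    """Channel-matched localization errors after least-squares alignment.

    The reconstruction is aligned to the reference with the Umeyama estimator
    (rigid by default; similarity when ``with_scale``), matching electrodes
    by channel label — a mislabeled electrode therefore shows up as a large
    error instead of being absorbed by nearest-neighbor matching.  Region
    statistics are computed on the reference map's geometry (its frame is
    assumed torso-aligned: Y vertical, Z anterior).

    Raises
    ------
    InvalidInputError
        If fewer than 3 channels are common to both maps.
    """
    rec = recon.in_channel_order()
    ref = reference.in_channel_order()
    common = np.intersect1d(rec.channels, ref.channels)
    if len(common) < 3:
        raise InvalidInputError(f"only {len(common)} common channels; need >= 3")
    ri = np.searchsorted(rec.channels, common)
    fi = np.searchsorted(ref.channels, common)
    src = rec.positions[ri]
    tgt = ref.positions[fi]
    aligned = umeyama_align(src, tgt, with_scale=with_scale).apply(src)
    diff = aligned - tgt
    per_axis = np.abs(diff)
    dist = np.linalg.norm(diff, axis=1)

    ref_common = LabeledElectrodeMap(
        tgt,
        [ref.classes[i] for i in fi],
        np.arange(1, len(common) + 1),
        ref.strips[fi],
    )
    regions = assign_regions(ref_common)
    region_stats = {}
    for r in REGIONS:
        mask = np.asarray([x == r for x in regions])
        n = int(mask.sum())
        region_stats[r] = {
            "mean": float(dist[mask].mean()) if n else float("nan"),
            "sd": float(dist[mask].std(ddof=1)) if n > 1 else float("nan"),
            "n": n,
        }
    return ErrorReport(
        channels=common,
        per_electrode_3d=dist,
        per_axis=per_axis,
        regions=regions,
        mean_3d=float(dist.mean()),
        sd_3d=float(dist.std(ddof=1)) if len(dist) > 1 else 0.0,
        axis_means=per_axis.mean(axis=0),
        axis_sds=per_axis.std(axis=0, ddof=1) if len(dist) > 1 else np.zeros(3),
        region_stats=region_stats,
    )
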