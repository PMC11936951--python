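"""Rigid/similarity transforms, Umeyama alignment, and two-stage ICP.

Per-view torso point clouds (consecutive views ~10 degrees apart) are fused
into one reconstruction by sequentially aligning each view to its predecessor
with iterative closest point: a point-to-plane stage for fast convergence on
the smooth torso surface, refined by a point-to-point stage, with distance
thresholds excluding irrelevant correspondences.  The closed-form Umeyama
estimator provides least-squares similarity (or rigid) alignment between
corresponded point sets and is also used by the evaluation module.

No registration library is assumed: correspondence search uses a KD-tree,
normals come from local PCA planes, and the minimizers are written out
explicitly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import InvalidInputError, NoOverlapError, ReconstructionError, ConfigError
from .geometry import ColoredPointCloud

__all__ = [
    "RigidTransform",
    "SimilarityTransform",
    "IcpConfig",
    "umeyama_align",
    "icp_point_to_plane",
    "icp_point_to_point",
    "reconstruct_torso",
    "estimate_normals",
    "voxel_downsample",
]


def _project_rotation(m: np.ndarray) -> np.ndarray:
    """Nearest proper rotation to ``m`` (polar decomposition via SVD)."""
    u, _, vt = np.linalg.svd(m)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u = u.copy()
        u[:, -1] *= -1
        r = u @ vt
    return r


def _check_rotation(r: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    r = np.asarray(r, dtype=np.float64)
    if r.shape != (3, 3):
        raise InvalidInputError("rotation must be 3x3")
    if not np.allclose(r @ r.T, np.eye(3), atol=tol):
        raise InvalidInputError("rotation is not orthonormal")
    if not np.isclose(np.linalg.det(r), 1.0, atol=tol):
        raise InvalidInputError("rotation must have determinant +1")
    return r


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R p + t`` (millimeters)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        r = _project_rotation(self.rotation @ other.rotation)
        t = self.rotation @ other.translation + self.translation
        return RigidTransform(r, t)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64)
        return cls(m[:3, :3], m[:3, 3])


@dataclass(frozen=True)
class SimilarityTransform:
    """Similarity ``p -> s R p + t`` with positive scale."""

    scale: float
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        if self.scale <= 0:
            raise InvalidInputError("scale must be positive")
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64)
        return self.scale * (p @ self.rotation.T) + self.translation

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.scale * self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass(frozen=True)
class IcpConfig:
    """ICP thresholds and stopping rule.

    ``max_corr_dist_plane``/``max_corr_dist_point`` bound the correspondence
    search radius of the two stages (mm); iteration stops when the relative
    RMS improvement drops below ``convergence_tol`` or after
    ``max_iterations``.  ``voxel_size`` is the grid pitch (mm) used to thin
    clouds before correspondence search; the resulting transform is applied
    to the full-resolution clouds.

    ``trim_fraction`` discards that fraction of worst-residual
    correspondences each iteration (trimmed ICP).  Consecutive views of a
    rotating camera overlap only partially; points visible in one view but
    not the other still find correspondences at the overlap boundary and
    would otherwise bias the minimum away from the true pose.
    """

    max_corr_dist_plane: float = 50.0
    max_corr_dist_point: float = 20.0
    max_iterations: int = 50
    convergence_tol: float = 1e-6
    voxel_size: float = 4.0
    trim_fraction: float = 0.2

    def __post_init__(self):
        if min(self.max_corr_dist_plane, self.max_corr_dist_point, self.voxel_size) <= 0:
            raise ConfigError("distances must be > 0")
        if self.max_iterations < 1 or self.convergence_tol <= 0:
            raise ConfigError("max_iterations >= 1 and convergence_tol > 0 required")
        if not (0.0 <= self.trim_fraction < 1.0):
            raise ConfigError("trim_fraction must be in [0, 1)")


def umeyama_align(
    source_points: np.ndarray,
    target_points: np.ndarray,
    with_scale: bool = True,
) -> SimilarityTransform:
    """Closed-form least-squares similarity (or rigid) alignment.

    Returns the transform minimizing ``sum ||s R x_i + t - y_i||^2`` over all
    proper rotations R, translations t and (if ``with_scale``) scales s > 0.
    When the unconstrained optimum would be a reflection, the sign of the
    smallest singular vector is flipped, the standard correction that keeps
    det(R) = +1.

    Raises
    ------
    InvalidInputError
        On length mismatch, fewer than 3 points, or a degenerate (rank < 2,
        e.g. collinear) source configuration.
    """
    src = np.asarray(source_points, dtype=np.float64).reshape(-1, 3)
    tgt = np.asarray(target_points, dtype=np.float64).reshape(-1, 3)
    if len(src) != len(tgt):
        raise InvalidInputError("source and target must have equal length")
    if len(src) < 3:
        raise InvalidInputError("at least 3 point pairs are required")
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    xs = src - mu_s
    ys = tgt - mu_t
    cov = ys.T @ xs / len(src)
    u, s, vt = np.linalg.svd(cov)
    if s[1] <= max(1e-12 * max(s[0], 1.0), 0.0) or s[0] == 0.0:
        raise InvalidInputError("degenerate (rank < 2) point configuration")
    d = np.ones(3)
    if np.linalg.det(u) * np.linalg.det(vt) < 0:
        d[2] = -1.0
    rot = u @ np.diag(d) @ vt
    if with_scale:
        var_s = (xs ** 2).sum() / len(src)
        scale = float((s * d).sum() / var_s)
    else:
        scale = 1.0
    t = mu_t - scale * rot @ mu_s
    return SimilarityTransform(scale, _project_rotation(rot), t)


def _rigid_fit(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    sim = umeyama_align(source, target, with_scale=False)
    return RigidTransform(sim.rotation, sim.translation)


def estimate_normals(
    points: np.ndarray,
    k: int = 30,
    viewpoint: Sequence[float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Unit normals from k-nearest-neighbor PCA planes.

    Each normal is the smallest-eigenvalue eigenvector of its neighborhood's
    covariance, with sign flipped to point toward ``viewpoint`` (for clouds in
    a camera frame the camera sits at the origin, giving outward-consistent
    orientation on the visible surface).
    """
    pts = np.asarray(points, dtype=np.float64)
    n = len(pts)
    k = min(k, n)
    if k < 3:
        raise InvalidInputError("normal estimation needs at least 3 points")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k)
    nbr = pts[idx]  # (n, k, 3)
    centered = nbr - nbr.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / k
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]
    to_view = np.asarray(viewpoint, dtype=np.float64) - pts
    flip = np.einsum("ij,ij->i", normals, to_view) < 0
    normals[flip] *= -1.0
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    return normals / np.clip(norms, 1e-30, None)


def voxel_downsample(points: np.ndarray, voxel_size: float) -> np.ndarray:
    """Average points falling in the same cubic voxel (deterministic order)."""
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) == 0:
        return pts
    keys = np.floor(pts / voxel_size).astype(np.int64)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    sums = np.zeros((len(counts), 3))
    np.add.at(sums, inverse, pts)
    return sums / counts[:, None]


def _as_points(cloud) -> np.ndarray:
    if isinstance(cloud, ColoredPointCloud):
        return cloud.points
    return np.asarray(cloud, dtype=np.float64).reshape(-1, 3)


def _icp(
    source,
    target,
    init: RigidTransform,
    config: IcpConfig,
    variant: str,
    callback: Callable[[int, float], None] | None,
    target_viewpoint: Sequence[float],
) -> RigidTransform:
    src = _as_points(source)
    tgt = _as_points(target)
    if len(src) < 10 or len(tgt) < 10:
        raise InvalidInputError("ICP requires clouds of at least 10 points")
    max_dist = config.max_corr_dist_plane if variant == "plane" else config.max_corr_dist_point
    tree = cKDTree(tgt)
    normals = estimate_normals(tgt, viewpoint=target_viewpoint) if variant == "plane" else None

    def evaluate(transform: RigidTransform):
        p = transform.apply(src)
        dist, j = tree.query(p, distance_upper_bound=max_dist)
        mask = np.isfinite(dist)
        if not np.any(mask):
            return np.inf, p, j, mask
        if variant == "plane":
            resid = np.abs(np.einsum(
                "ij,ij->i", p[mask] - tgt[j[mask]], normals[j[mask]]
            ))
        else:
            resid = dist[mask]
        if config.trim_fraction > 0 and mask.sum() > 10:
            cutoff = np.quantile(resid, 1.0 - config.trim_fraction)
            keep = resid <= cutoff
            trimmed = np.zeros_like(mask)
            trimmed[np.nonzero(mask)[0][keep]] = True
            mask = trimmed
            resid = resid[keep]
        obj = float(np.sqrt(np.mean(resid ** 2)))
        return obj, p, j, mask

    transform = init
    obj, p, j, mask = evaluate(transform)
    if not np.isfinite(obj):
        raise NoOverlapError(
            f"zero correspondences within {max_dist} mm at the initial alignment"
        )
    if callback is not None:
        callback(0, obj)

    for it in range(1, config.max_iterations + 1):
        ps = p[mask]
        qs = tgt[j[mask]]
        if len(ps) < 3:
            break
        if variant == "plane":
            ns = normals[j[mask]]
            resid = np.einsum("ij,ij->i", ps - qs, ns)
            a = np.hstack([np.cross(ps, ns), ns])
            x, *_ = np.linalg.lstsq(a, -resid, rcond=None)
            omega, dt = x[:3], x[3:]
        else:
            try:
                delta = _rigid_fit(ps, qs)
            except InvalidInputError:
                break
            omega = Rotation.from_matrix(delta.rotation).as_rotvec()
            dt = delta.translation

        # Step-halving keeps the recorded objective non-increasing even when
        # correspondences churn between iterations.
        accepted = False
        step = 1.0
        for _ in range(8):
            rot = Rotation.from_rotvec(step * omega).as_matrix()
            trial = RigidTransform(_project_rotation(rot), step * np.asarray(dt)).compose(transform)
            obj2, p2, j2, mask2 = evaluate(trial)
            if obj2 <= obj + 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        rel_improve = (obj - obj2) / max(obj, 1e-30)
        transform, obj, p, j, mask = trial, obj2, p2, j2, mask2
        if callback is not None:
            callback(it, obj)
        if rel_improve < config.convergence_tol:
            break
    return transform


def icp_point_to_plane(
    source,
    target,
    init: RigidTransform = None,
    config: IcpConfig = IcpConfig(),
    callback: Callable[[int, float], None] | None = None,
    target_viewpoint: Sequence[float] = (0.0, 0.0, 0.0),
) -> RigidTransform:
    """Point-to-plane ICP: minimizes distances to target surface tangent planes.

    ``callback(iteration, rms)`` (optional) observes the per-iteration
    objective, which is non-increasing by construction.

    Raises
    ------
    NoOverlapError
        If no correspondence lies within ``max_corr_dist_plane`` at ``init``.
    """
    if init is None:
        init = RigidTransform.identity()
    return _icp(source, target, init, config, "plane", callback, target_viewpoint)


def icp_point_to_point(
    source,
    target,
    init: RigidTransform = None,
    config: IcpConfig = IcpConfig(),
    callback: Callable[[int, float], None] | None = None,
) -> RigidTransform:
    """Point-to-point ICP: minimizes distances between corresponding points."""
    if init is None:
        init = RigidTransform.identity()
    return _icp(source, target, init, config, "point", callback, (0.0, 0.0, 0.0))


def _plane_consistency_rms(
    src: np.ndarray,
    tgt: np.ndarray,
    normals: np.ndarray,
    transform: RigidTransform,
    max_dist: float,
    trim_fraction: float,
) -> float:
    """Trimmed RMS of point-to-plane residuals of ``src`` against ``tgt``."""
    p = transform.apply(src)
    dist, j = cKDTree(tgt).query(p, distance_upper_bound=max_dist)
    mask = np.isfinite(dist)
    if not np.any(mask):
        return np.inf
    resid = np.abs(np.einsum("ij,ij->i", p[mask] - tgt[j[mask]], normals[j[mask]]))
    if trim_fraction > 0 and len(resid) > 10:
        resid = resid[resid <= np.quantile(resid, 1.0 - trim_fraction)]
    return float(np.sqrt(np.mean(resid ** 2)))


def reconstruct_torso(
    clouds: Sequence[ColoredPointCloud],
    config: IcpConfig = IcpConfig(),
) -> tuple[ColoredPointCloud, list[RigidTransform]]:
    """Chain pairwise two-stage ICP alignments into one torso reconstruction.

    View k is aligned to view k-1 (point-to-plane, then point-to-point
    refinement) on voxel-thinned copies; compositions map every cloud into
    the frame of view 0.  The merged cloud is the concatenation of all
    transformed full-resolution clouds.

    The point-to-point refinement is verification-gated: on smooth,
    feature-poor surfaces its objective is nearly degenerate along
    within-surface sliding modes and can wander millimeters from the true
    pose while still lowering its own RMS.  The refined pose is therefore
    accepted only when it does not degrade the point-to-plane consistency of
    the pair; otherwise the plane-stage pose stands.

    Returns
    -------
    (merged, transforms) where ``transforms[0]`` is the identity and
    ``transforms[k]`` maps cloud k into the frame of cloud 0.

    Raises
    ------
    ReconstructionError
        If any consecutive pair has no overlap; carries the failing pair index.
    """
    if len(clouds) == 0:
        raise InvalidInputError("at least one cloud is required")
    transforms = [RigidTransform.identity()]
    thinned = [voxel_downsample(c.points, config.voxel_size) for c in clouds]
    normals = [estimate_normals(t) for t in thinned]
    for k in range(1, len(clouds)):
        try:
            plane = icp_point_to_plane(thinned[k], thinned[k - 1], config=config)
            point = icp_point_to_point(thinned[k], thinned[k - 1], init=plane, config=config)
        except NoOverlapError as exc:
            raise ReconstructionError(
                f"views {k - 1} and {k} do not overlap: {exc}", pair=(k - 1, k)
            ) from exc
        rms_plane, rms_point = (
            _plane_consistency_rms(
                thinned[k], thinned[k - 1], normals[k - 1], t,
                config.max_corr_dist_plane, config.trim_fraction,
            )
            for t in (plane, point)
        )
        pair = point if rms_point <= rms_plane * 1.05 + 1e-12 else plane
        transforms.append(transforms[k - 1].compose(pair))
    merged_points = np.vstack([t.apply(c.points) for t, c in zip(transforms, clouds)])
    merged_colors = np.vstack([c.colors for c in clouds])
    return ColoredPointCloud(merged_points, merged_colors), transforms
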