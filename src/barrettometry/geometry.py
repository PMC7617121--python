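"""Back-projection of depth maps, surface path lengths and patch areas in mm,
rigid pose estimation between depth frames, and multi-frame surface fusion.

Depth maps store the camera-frame z coordinate per pixel (mm); a pixel
``(u, v)`` with depth ``d`` back-projects to ``((u-u0) d/f, (v-v0) d/f, d)``.
Lengths are geodesic along the imaged surface: a 2D pixel path is rasterized,
back-projected, and consecutive 3D steps are summed, because esophageal
lengths are distances along the mucosal wall, not chords through the lumen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage.draw import line as _draw_line

from .phantom import CameraModel, Pose


class RegistrationError(RuntimeError):
    """Raised when rigid registration between two clouds fails."""


@dataclass
class PointCloud:
    """3D points (mm) in camera coordinates with their source pixels."""

    points: np.ndarray                      # (N, 3)
    pixel_index: np.ndarray | None = None   # (N, 2) as (row, col)
    colors: np.ndarray | None = None        # (N, 3) in [0, 1]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.pixel_index is not None:
            self.pixel_index = np.asarray(self.pixel_index).reshape(-1, 2)
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.float64).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, pose: Pose) -> "PointCloud":
        return PointCloud(pose.transform(self.points), self.pixel_index, self.colors)


# ---------------------------------------------------------------------------
# Back-projection
# ---------------------------------------------------------------------------


def backproject_pixel(u: float, v: float, d: float, camera: CameraModel) -> np.ndarray:
    """Back-project pixel (col ``u``, row ``v``) with z-depth ``d`` (mm)."""
    if d <= 0:
        raise ValueError("depth must be positive")
    u0, v0 = camera.principal_point
    f = camera.focal_length
    return np.array([(u - u0) * d / f, (v - v0) * d / f, d])


def project_point(p: np.ndarray, camera: CameraModel) -> tuple[float, float]:
    """Pinhole projection of a camera-frame point to (u, v) pixel coordinates."""
    p = np.asarray(p, dtype=float)
    if p[2] <= 0:
        raise ValueError("point must be in front of the camera")
    u0, v0 = camera.principal_point
    f = camera.focal_length
    return (u0 + f * p[0] / p[2], v0 + f * p[1] / p[2])


def _pixel_points(depth: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Back-project every pixel; invalid (depth<=0) pixels become NaN. (H,W,3)."""
    depth = np.asarray(depth, dtype=np.float64)
    h, w = depth.shape
    u0, v0 = camera.principal_point
    f = camera.focal_length
    uu, vv = np.meshgrid(np.arange(w, dtype=np.float64), np.arange(h, dtype=np.float64))
    d = np.where(depth > 0, depth, np.nan)
    return np.stack([(uu - u0) * d / f, (vv - v0) * d / f, d], axis=-1)


def backproject_depthmap(depth: np.ndarray, camera: CameraModel,
                         rgb: np.ndarray | None = None) -> PointCloud:
    """One 3D point per valid pixel; zero-depth pixels are skipped."""
    depth = np.asarray(depth, dtype=np.float64)
    valid = depth > 0
    if not valid.any():
        warnings.warn("depth map has no valid pixels; returning empty cloud")
        return PointCloud(np.empty((0, 3)), np.empty((0, 2), dtype=int))
    pts = _pixel_points(depth, camera)[valid]
    rows, cols = np.nonzero(valid)
    colors = rgb[valid] if rgb is not None else None
    return PointCloud(pts, np.stack([rows, cols], axis=1), colors)


# ---------------------------------------------------------------------------
# Pixel paths and surface measurements
# ---------------------------------------------------------------------------


def rasterize_path(p0: tuple[int, int], p1: tuple[int, int]) -> np.ndarray:
    """8-connected pixel polyline between two (row, col) endpoints, inclusive."""
    r0, c0 = int(round(p0[0])), int(round(p0[1]))
    r1, c1 = int(round(p1[0])), int(round(p1[1]))
    rr, cc = _draw_line(r0, c0, r1, c1)
    return np.stack([rr, cc], axis=1)


def surface_path_length(depth: np.ndarray, camera: CameraModel,
                        path: np.ndarray) -> float:
    """Geodesic length (mm) along the imaged surface under a pixel path.

    Consecutive path pixels are back-projected and their 3D Euclidean steps
    summed.  Raises ``ValueError`` naming the first pixel with invalid depth.
    """
    path = np.asarray(path)
    if path.ndim != 2 or path.shape[1] != 2 or len(path) == 0:
        raise ValueError("path must be a non-empty (N, 2) array of (row, col)")
    depth = np.asarray(depth, dtype=np.float64)
    d = depth[path[:, 0], path[:, 1]]
    bad = np.nonzero(d <= 0)[0]
    if bad.size:
        r, c = path[bad[0]]
        raise ValueError(f"path crosses invalid depth at pixel (row={r}, col={c})")
    if len(path) == 1:
        return 0.0
    u0, v0 = camera.principal_point
    f = camera.focal_length
    pts = np.stack([(path[:, 1] - u0) * d / f, (path[:, 0] - v0) * d / f, d], axis=1)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def patch_surface_area(depth: np.ndarray, camera: CameraModel,
                       mask: np.ndarray) -> float:
    """Surface area (mm^2) of the masked region of the imaged surface.

    Each masked pixel contributes the area of its 3D footprint, estimated from
    the local surface tangents (central differences of the back-projected
    pixel grid; one-sided at boundaries or next to invalid pixels).
    """
    mask = np.asarray(mask, dtype=bool)
    depth = np.asarray(depth, dtype=np.float64)
    if mask.shape != depth.shape:
        raise ValueError("mask and depth shapes differ")
    if not mask.any():
        return 0.0
    if np.any(depth[mask] <= 0):
        raise ValueError("mask covers pixels with invalid depth")
    pts = _pixel_points(depth, camera)

    def _diff(axis: int) -> np.ndarray:
        fwd = np.roll(pts, -1, axis=axis) - pts
        bwd = pts - np.roll(pts, 1, axis=axis)
        # forward/backward validity (rolled-in edges are invalid)
        fv = np.isfinite(fwd).all(axis=-1)
        bv = np.isfinite(bwd).all(axis=-1)
        idx = np.arange(pts.shape[axis])
        if axis == 0:
            fv[-1, :] = False
            bv[0, :] = False
        else:
            fv[:, -1] = False
            bv[:, 0] = False
        central = 0.5 * (fwd + bwd)
        out = np.where((fv & bv)[..., None], central,
                       np.where(fv[..., None], fwd,
                                np.where(bv[..., None], bwd, np.nan)))
        return out

    du = _diff(1)
    dv = _diff(0)
    cell = np.linalg.norm(np.cross(du, dv), axis=-1)
    vals = cell[mask]
    vals = vals[np.isfinite(vals)]
    return float(vals.sum())


# ---------------------------------------------------------------------------
# Rigid registration (point-to-point ICP) and fusion
# ---------------------------------------------------------------------------


@dataclass
class RegistrationResult:
    pose: Pose
    residual: float
    success: bool
    n_iterations: int = 0


def _kabsch(src: np.ndarray, dst: np.ndarray) -> Pose:
    """Least-squares rigid transform mapping src -> dst."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    S = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ S @ U.T
    return Pose(R, cd - R @ cs)


def estimate_relative_pose(
    cloud_a: PointCloud,
    cloud_b: PointCloud,
    max_iterations: int = 60,
    tolerance: float = 1e-6,
    max_residual: float = 1.0,
    max_points: int = 4000,
    seed: int = 0,
) -> RegistrationResult:
    """Rigid transform T with ``T(cloud_a) ~ cloud_b`` by closest-point iteration.

    Initialized at the identity (consecutive endoscopy frames overlap heavily).
    ``success`` is False when the final mean closest-point residual exceeds
    ``max_residual`` mm -- a silent bad pose is never returned.
    """
    a, b = cloud_a.points, cloud_b.points
    if len(a) < 3 or len(b) < 3:
        raise ValueError("registration needs at least 3 points per cloud")
    rng = np.random.default_rng(seed)
    if len(a) > max_points:
        a = a[rng.choice(len(a), max_points, replace=False)]
    if len(b) > max_points:
        b = b[rng.choice(len(b), max_points, replace=False)]

    tree = cKDTree(b)
    pose = Pose.identity()
    prev = np.inf
    it = 0
    for it in range(1, max_iterations + 1):
        moved = pose.transform(a)
        dist, idx = tree.query(moved, workers=-1)
        # trim the worst correspondences for robustness to partial overlap
        keep = dist <= np.quantile(dist, 0.9)
        pose = _kabsch(a[keep], b[idx[keep]])
        resid = float(dist.mean())
        if abs(prev - resid) < tolerance:
            break
        prev = resid
    resid = float(cKDTree(b).query(pose.transform(a), workers=-1)[0].mean())
    return RegistrationResult(pose=pose, residual=resid,
                              success=resid <= max_residual, n_iterations=it)


def voxel_downsample(points: np.ndarray, voxel: float,
                     colors: np.ndarray | None = None):
    """Average points (and colors) falling into the same cubic voxel."""
    keys = np.floor(points / voxel).astype(np.int64)
    _, inv, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    out = np.zeros((len(counts), 3))
    np.add.at(out, inv, points)
    out /= counts[:, None]
    if colors is None:
        return out, None
    cout = np.zeros((len(counts), colors.shape[1]))
    np.add.at(cout, inv, colors)
    cout /= counts[:, None]
    return out, cout


def fuse_surfaces(
    frames,
    camera: CameraModel,
    poses: list[Pose] | None = None,
    voxel: float = 0.5,
    max_residual: float = 1.0,
    ply_path=None,
) -> PointCloud:
    """Fuse the clouds of consecutive frames into the first frame's coordinates.

    If ``poses`` is None, pairwise rigid transforms are estimated from the
    depth clouds and chained; a pairwise failure aborts with the failing pair
    named.  ``poses``, when given, are relative transforms T_i mapping frame i
    into frame i-1 (T_0 is ignored).  Optionally exports a binary PLY.
    """
    if len(frames) == 0:
        raise ValueError("no frames to fuse")
    clouds = [
        backproject_depthmap(f.depth, camera, rgb=getattr(f, "rgb", None))
        for f in frames
    ]
    chained = [Pose.identity()]
    for i in range(1, len(clouds)):
        if poses is not None:
            rel = poses[i]
        else:
            res = estimate_relative_pose(clouds[i], clouds[i - 1],
                                         max_residual=max_residual)
            if not res.success:
                raise RegistrationError(
                    f"registration failed for frame pair ({i - 1}, {i}): "
                    f"residual {res.residual:.2f} mm"
                )
            rel = res.pose
        chained.append(chained[i - 1].compose(rel))

    pts = np.concatenate([T.transform(c.points) for T, c in zip(chained, clouds)])
    cols = None
    if all(c.colors is not None for c in clouds):
        cols = np.concatenate([c.colors for c in clouds])
    pts, cols = voxel_downsample(pts, voxel, cols)
    fused = PointCloud(pts, colors=cols)
    if ply_path is not None:
        export_ply(fused, ply_path)
    return fused


def export_ply(cloud: PointCloud, path) -> None:
    """Write a point cloud as binary little-endian PLY."""
    import trimesh

    colors = None
    if cloud.colors is not None:
        colors = np.clip(cloud.colors * 255, 0, 255).astype(np.uint8)
    trimesh.PointCloud(cloud.points, colors=colors).export(str(path))
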