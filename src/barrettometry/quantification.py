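"""Prague C&M scores, island diameters and Barrett's epithelium area (BEA)
from segmentation masks + a depth map + camera intrinsics.

The measurement follows the convex-hull construction: all pixels of the main
Barrett's segment are fitted with a convex polygon; geodesic distances along
the imaged surface are taken from the center of the gastric junction to every
hull vertex.  The smallest such distance is the circumferential extent C (the
collar of Barrett's epithelium present all around), the largest is the maximal
extent M.  Areas integrate the 3D footprint of every pixel enclosed by the
hull (A_b) and of the gastric-fold region (A_fold); the final BEA is
``A_b - A_fold`` when ``A_fold`` exceeds 1 cm^2, else ``A_b``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree
from skimage.draw import polygon as _draw_polygon

from .geometry import patch_surface_area, rasterize_path, surface_path_length
from .masks import SegMasks
from .phantom import CameraModel

PRAGUE_BINS = (0.0, 1.0, 3.0, 5.0, 7.0, 9.0, 11.0)
PRAGUE_LABELS = ("0-1", "1-3", "3-5", "5-7", "7-9", "9-11", ">11")

FOLD_AREA_THRESHOLD_CM2 = 1.0   # subtract A_fold only when it exceeds 1 cm^2
MAX_JUNCTION_OBLIQUITY_DEG = 30.0


def to_prague_category(length_cm: float) -> str:
    """Prague length category; half-open lower-inclusive bins in cm."""
    if length_cm < 0:
        raise ValueError("length must be non-negative")
    idx = int(np.searchsorted(PRAGUE_BINS, length_cm, side="right")) - 1
    return PRAGUE_LABELS[idx]


@dataclass(frozen=True)
class Hull2D:
    """Convex polygon in pixel space, vertices (row, col), counterclockwise."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 2)
        if len(v) < 3:
            raise ValueError("a hull needs at least 3 vertices")
        # signed area in (col, row) coordinates; enforce CCW
        x, y = v[:, 1], v[:, 0]
        area2 = np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
        if area2 < 0:
            v = v[::-1]
        object.__setattr__(self, "vertices", v)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized point-in-convex-polygon test (boundary inclusive)."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        v = self.vertices
        nxt = np.roll(v, -1, axis=0)
        ex, ey = nxt[:, 1] - v[:, 1], nxt[:, 0] - v[:, 0]
        px = pts[:, None, 1] - v[None, :, 1]
        py = pts[:, None, 0] - v[None, :, 0]
        cross = ex[None, :] * py - ey[None, :] * px
        return np.all(cross >= -1e-9, axis=1)


def fit_convex_hull(mask: np.ndarray) -> Hull2D:
    """Minimal convex polygon containing all masked pixel centers."""
    pts = np.argwhere(np.asarray(mask, dtype=bool)).astype(float)
    if len(pts) < 3:
        raise ValueError("mask has fewer than 3 pixels")
    try:
        hull = ConvexHull(pts[:, ::-1])  # (x=col, y=row)
    except QhullError as exc:
        raise ValueError("mask pixels are collinear; no 2D hull") from exc
    return Hull2D(pts[hull.vertices])


def junction_center(junction_mask: np.ndarray,
                    valid: np.ndarray | None = None) -> tuple[tuple[int, int], bool]:
    """Centroid of the gastric-junction mask, snapped to a valid-depth pixel.

    Returns ``((row, col), relocated)`` where ``relocated`` flags that the
    centroid fell on an invalid pixel (e.g. inside an annular fold region) and
    was moved to the nearest pixel with valid depth.
    """
    junction_mask = np.asarray(junction_mask, dtype=bool)
    if not junction_mask.any():
        raise ValueError("junction mask is empty (gastric folds not visible)")
    rows, cols = np.nonzero(junction_mask)
    centroid = np.array([rows.mean(), cols.mean()])
    r, c = int(round(centroid[0])), int(round(centroid[1]))
    if valid is None:
        return (r, c), False
    valid = np.asarray(valid, dtype=bool)
    if valid[r, c]:
        return (r, c), False
    vpix = np.argwhere(valid)
    if len(vpix) == 0:
        raise ValueError("no valid-depth pixels in frame")
    nearest = vpix[cKDTree(vpix).query(centroid)[1]]
    return (int(nearest[0]), int(nearest[1])), True


def extrema_distances(
    center: tuple[int, int],
    hull: Hull2D,
    depth: np.ndarray,
    camera: CameraModel,
) -> tuple[list[tuple[np.ndarray, float]], list[np.ndarray]]:
    """Geodesic surface distance from the junction center to each hull vertex.

    Vertices whose center->vertex pixel path crosses invalid depth are skipped
    and returned separately.
    """
    results: list[tuple[np.ndarray, float]] = []
    skipped: list[np.ndarray] = []
    for vertex in hull.vertices:
        path = rasterize_path(center, (vertex[0], vertex[1]))
        try:
            dist = surface_path_length(depth, camera, path)
        except ValueError:
            skipped.append(vertex)
            continue
        results.append((vertex, dist))
    return results, skipped


def measure_prague(
    masks: SegMasks,
    depth: np.ndarray,
    camera: CameraModel,
) -> tuple[float, float, dict]:
    """(C, M) in mm from the main-segment hull's junction-center extrema.

    Returns ``(C, M, info)`` where ``info`` carries the hull, center and flags.
    """
    info: dict = {"flags": []}
    if not masks.bea.any():
        return 0.0, 0.0, info
    valid = masks.valid if masks.valid is not None else np.asarray(depth) > 0
    center, relocated = junction_center(masks.junction, valid)
    if relocated:
        info["flags"].append("junction_center_relocated")
    hull = fit_convex_hull(masks.bea)
    dists, skipped = extrema_distances(center, hull, depth, camera)
    if skipped:
        info["flags"].append("vertex_paths_skipped")
    if not dists:
        info["flags"].append("no_measurable_vertices")
        return 0.0, 0.0, info
    values = np.array([d for _, d in dists])
    info.update(center=center, hull=hull, distances=dists, skipped=skipped)
    return float(values.min()), float(values.max()), info


def measure_island_diameter(island_mask: np.ndarray, depth: np.ndarray,
                            camera: CameraModel) -> float:
    """Maximal geodesic distance between hull vertices of one island (mm).

    Geodesics run along the island's own surface (shortest 8-neighbor paths
    through the masked pixels, weighted by 3D step lengths): an island of the
    size seen after ablation can wrap a substantial arc of the esophageal
    wall, so straight pixel lines between its extrema would cut across the
    lumen instead of following the mucosa.
    """
    island_mask = np.asarray(island_mask, dtype=bool)
    if not island_mask.any():
        raise ValueError("island mask is empty")
    depth = np.asarray(depth, dtype=np.float64)
    island_mask = island_mask & (depth > 0)
    pts = np.argwhere(island_mask)
    if len(pts) <= 1:
        return 0.0
    try:
        verts = fit_convex_hull(island_mask).vertices
    except ValueError:
        verts = pts.astype(float)  # 2 pixels or collinear: use the pixels

    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra as _dijkstra

    from .geometry import _pixel_points

    h, w = island_mask.shape
    idx = -np.ones((h, w), dtype=np.int64)
    idx[island_mask] = np.arange(len(pts))
    p3 = _pixel_points(depth, camera)[island_mask]
    # neighborhood offsets out to radius 3: the wall is imaged obliquely, so
    # the pixel->3D metric is anisotropic and plain 8-connectivity would
    # overestimate geodesics by tens of percent
    offsets = [(dr, dc) for dr in range(0, 5) for dc in range(-4, 5)
               if (dr, dc) > (0, 0) and math.gcd(dr, abs(dc)) == 1]
    rows_i, cols_i, weights = [], [], []
    for dr, dc in offsets:
        r2 = pts[:, 0] + dr
        c2 = pts[:, 1] + dc
        ok = (r2 >= 0) & (r2 < h) & (c2 >= 0) & (c2 < w)
        ok[ok] &= island_mask[r2[ok], c2[ok]]
        a = idx[pts[ok, 0], pts[ok, 1]]
        b = idx[r2[ok], c2[ok]]
        wgt = np.linalg.norm(p3[a] - p3[b], axis=1)
        rows_i.append(a)
        cols_i.append(b)
        weights.append(wgt)
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows_i), np.concatenate(cols_i))),
        shape=(len(pts), len(pts)),
    )
    vert_ids = idx[verts[:, 0].astype(int), verts[:, 1].astype(int)]
    vert_ids = np.unique(vert_ids[vert_ids >= 0])
    dist = _dijkstra(graph, directed=False, indices=vert_ids)
    dist = dist[:, vert_ids]
    finite = dist[np.isfinite(dist)]
    return float(finite.max()) if finite.size else 0.0


def hull_pixel_mask(hull: Hull2D, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of all pixels enclosed by (or on) the hull."""
    rr, cc = _draw_polygon(hull.vertices[:, 0], hull.vertices[:, 1], shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def measure_area(
    masks: SegMasks,
    depth: np.ndarray,
    camera: CameraModel,
) -> tuple[float, float, float, list[float]]:
    """(A_b, A_fold, BEA, island_areas) in cm^2.

    A_b integrates the 3D pixel footprints over the region enclosed by the
    main-segment hull (every enclosed valid pixel contributes); A_fold over
    the gastric-fold mask.  BEA = A_b - A_fold when A_fold > 1 cm^2, else A_b.
    """
    depth = np.asarray(depth, dtype=np.float64)
    valid = masks.valid if masks.valid is not None else depth > 0
    valid = valid & (depth > 0)
    island_areas = [patch_surface_area(depth, camera, m & valid) / 100.0
                    for m in masks.islands]
    if not masks.bea.any():
        return 0.0, 0.0, 0.0, island_areas
    hull = fit_convex_hull(masks.bea)
    region = hull_pixel_mask(hull, masks.shape) & valid
    a_b = patch_surface_area(depth, camera, region) / 100.0
    a_fold = 0.0
    if masks.junction is not None and masks.junction.any():
        a_fold = patch_surface_area(depth, camera, masks.junction & valid) / 100.0
    bea = a_b - a_fold if a_fold > FOLD_AREA_THRESHOLD_CM2 else a_b
    return a_b, a_fold, max(bea, 0.0), island_areas


def _enclosing_ellipse(hull: Hull2D) -> dict:
    """Moment-based enclosing ellipse of the hull region (display only)."""
    v = hull.vertices
    c = v.mean(axis=0)
    cov = np.cov((v - c).T)
    evals, evecs = np.linalg.eigh(cov)
    angle = math.degrees(math.atan2(evecs[0, 1], evecs[1, 1]))
    return {
        "center_row": float(c[0]),
        "center_col": float(c[1]),
        "axes_px": (2.0 * math.sqrt(max(evals[1], 0.0)),
                    2.0 * math.sqrt(max(evals[0], 0.0))),
        "angle_deg": angle,
    }


@dataclass
class Measurements:
    """Automated Barrett's measurements for one frame (lengths mm, areas cm^2)."""

    C: float = 0.0
    M: float = 0.0
    island_diameters: list[float] = field(default_factory=list)
    A_b: float = 0.0
    A_fold: float = 0.0
    BEA: float = 0.0
    island_areas: list[float] = field(default_factory=list)
    prague_C_category: str | None = None
    prague_M_category: str | None = None
    quality_flags: list[str] = field(default_factory=list)
    display_ellipse: dict | None = None
    frame_id: int = 0

    @property
    def bea_with_islands(self) -> float:
        """Total Barrett's area including islands (reported separately too)."""
        return self.BEA + sum(self.island_areas)

    def to_dict(self) -> dict:
        return {
            "frame_id": self.frame_id,
            "C_mm": self.C,
            "M_mm": self.M,
            "island_diameters_mm": list(self.island_diameters),
            "A_b_cm2": self.A_b,
            "A_fold_cm2": self.A_fold,
            "BEA_cm2": self.BEA,
            "island_areas_cm2": list(self.island_areas),
            "BEA_with_islands_cm2": self.bea_with_islands,
            "prague_C_category": self.prague_C_category,
            "prague_M_category": self.prague_M_category,
            "quality_flags": list(self.quality_flags),
        }


def _junction_obliquity_deg(masks: SegMasks, depth: np.ndarray,
                            camera: CameraModel) -> float | None:
    """Angle between the camera axis and the junction-plane normal (degrees)."""
    if masks.junction is None or masks.junction.sum() < 10:
        return None
    from .geometry import _pixel_points

    pts = _pixel_points(depth, camera)[masks.junction & (depth > 0)]
    pts = pts[np.isfinite(pts).all(axis=1)]
    if len(pts) < 10:
        return None
    pts = pts - pts.mean(axis=0)
    normal = np.linalg.svd(pts, full_matrices=False)[2][-1]
    cosang = abs(normal[2])  # camera axis is +z
    return math.degrees(math.acos(np.clip(cosang, 0.0, 1.0)))


def measure_frame(
    frame,
    camera: CameraModel,
    use_gt_masks: bool = True,
    colors=None,
) -> Measurements:
    """Full per-frame measurement: Prague C&M, island diameters, areas.

    Assumption violations (junction not visible, oblique camera) never raise;
    they set quality flags and leave the affected quantities at zero.
    """
    m = Measurements(frame_id=getattr(frame, "frame_id", 0))
    depth = np.asarray(frame.depth, dtype=np.float64)
    if use_gt_masks and frame.gt_masks is not None:
        masks = frame.gt_masks
    else:
        from .segmentation import segment_phantom_colors

        masks = segment_phantom_colors(frame.rgb, colors=colors,
                                       valid=depth > 0)

    if not masks.bea.any() and not any(i.any() for i in masks.islands):
        m.quality_flags.append("no_barretts")

    obliq = _junction_obliquity_deg(masks, depth, camera)
    if obliq is not None and obliq > MAX_JUNCTION_OBLIQUITY_DEG:
        m.quality_flags.append("camera_oblique")

    junction_visible = masks.junction is not None and masks.junction.any()
    if not junction_visible:
        m.quality_flags.append("junction_not_visible")
    elif masks.bea.any():
        try:
            C, M, info = measure_prague(masks, depth, camera)
            m.C, m.M = C, M
            m.quality_flags.extend(info["flags"])
            if "hull" in info:
                m.display_ellipse = _enclosing_ellipse(info["hull"])
            m.prague_C_category = to_prague_category(C / 10.0)
            m.prague_M_category = to_prague_category(M / 10.0)
        except ValueError as exc:
            m.quality_flags.append(f"prague_failed: {exc}")

    for isl in masks.islands:
        try:
            m.island_diameters.append(measure_island_diameter(isl, depth, camera))
        except ValueError:
            m.quality_flags.append("island_unmeasurable")

    try:
        a_b, a_fold, bea, island_areas = measure_area(masks, depth, camera)
        m.A_b, m.A_fold, m.BEA = a_b, a_fold, bea
        m.island_areas = island_areas
    except ValueError as exc:
        m.quality_flags.append(f"area_failed: {exc}")
    return m
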