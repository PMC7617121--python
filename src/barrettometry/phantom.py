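"""Digital esophagus phantom: tube geometry, painted Barrett's regions,
camera trajectories and an analytic ray-casting renderer.

The phantom is a straight tube of configurable length and internal radius whose
inner wall carries painted regions in cylindrical ``(theta, z)`` coordinates:
a light-pink squamous background, dark-pink Barrett's epithelium (circumferential
bands, tongues and separate islands) and a distinct gastric-fold / junction
landmark region.  The axial origin for Prague C&M ground truth is the explicit
``z_folds`` parameter (the simulated top of the gastric folds).

Rendering casts one pinhole ray per pixel and intersects it with the tube wall
analytically, so rendered depth is exact up to floating point and every ground
truth quantity (C, M, island diameters, painted areas) has a closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .masks import SegMasks

TWO_PI = 2.0 * math.pi

# Flat paint colors (RGB in [0, 1]).  The phantom uses a light pink for normal
# squamous mucosa, a clearly separable dark pink for columnar Barrett's
# epithelium and a darker red for the gastric folds / junction landmark.
SQUAMOUS_COLOR = (1.00, 0.78, 0.80)
BARRETT_COLOR = (0.82, 0.29, 0.45)
JUNCTION_COLOR = (0.55, 0.10, 0.12)


def _wrap(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into [0, 2*pi)."""
    return np.mod(theta, TWO_PI)


# ---------------------------------------------------------------------------
# Camera / pose / light models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera. ``u`` is the column, ``v`` the row, origin top-left."""

    focal_length: float = 128.0
    principal_point: tuple[float, float] | None = None
    image_size: tuple[int, int] = (256, 256)  # (H, W)

    def __post_init__(self) -> None:
        if self.focal_length <= 0:
            raise ValueError("focal_length must be positive")
        h, w = self.image_size
        if self.principal_point is None:
            object.__setattr__(self, "principal_point", ((w - 1) / 2.0, (h - 1) / 2.0))
        u0, v0 = self.principal_point
        if not (0 <= u0 < w and 0 <= v0 < h):
            raise ValueError("principal point outside image bounds")

    def ray_directions(self) -> np.ndarray:
        """Unit ray direction per pixel in camera coordinates, shape (H, W, 3)."""
        h, w = self.image_size
        u0, v0 = self.principal_point
        f = self.focal_length
        uu, vv = np.meshgrid(np.arange(w, dtype=np.float64), np.arange(h, dtype=np.float64))
        d = np.stack([(uu - u0) / f, (vv - v0) / f, np.ones_like(uu)], axis=-1)
        return d / np.linalg.norm(d, axis=-1, keepdims=True)


@dataclass(frozen=True)
class Pose:
    """Rigid camera pose: ``p_world = rotation @ p_camera + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not math.isclose(
            float(np.linalg.det(R)), 1.0, abs_tol=1e-8
        ):
            raise ValueError("rotation must be orthonormal with determinant +1")

    @staticmethod
    def identity() -> "Pose":
        return Pose(np.eye(3), np.zeros(3))

    def transform(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "Pose":
        return Pose(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "Pose") -> "Pose":
        """Pose mapping: first ``other``, then ``self``."""
        return Pose(self.rotation @ other.rotation,
                    self.rotation @ other.translation + self.translation)


def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _rot_axis(axis: np.ndarray, a: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = math.cos(a), math.sin(a)
    C = 1 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


class LightTier:
    LOW = 0.55
    MEDIUM = 0.85
    BRIGHT = 1.25


@dataclass(frozen=True)
class LightModel:
    """Point light co-located with the camera, quadratic fall-off ``1/(1+k d^2)``.

    ``intensity`` is a brightness tier (see :class:`LightTier`), ``attenuation``
    the quadratic coefficient in 1/mm^2, ``ambient`` a small floor so distal
    pixels never render pure black.
    """

    intensity: float = LightTier.BRIGHT
    attenuation: float = 4.0e-4
    ambient: float = 0.06

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")
        if self.attenuation < 0:
            raise ValueError("attenuation must be non-negative")


# ---------------------------------------------------------------------------
# Paint regions
# ---------------------------------------------------------------------------

PAINT_KINDS = ("band", "tongue", "island", "junction")
BARRETT_KINDS = ("band", "tongue")


@dataclass(frozen=True)
class PaintRegion:
    """A painted region on the tube wall in ``(theta, z)`` coordinates.

    ``theta_range`` is half-open ``[theta0, theta1)`` with ``theta1`` possibly
    beyond 2*pi to express wrap-around; ``z_range`` is half-open in mm.
    ``band``/``tongue``/``junction`` fill the rectangle; an ``island`` with no
    ``shape_fn`` is the ellipse inscribed in its bounding rectangle (a disk on
    the unrolled wall when built via :meth:`disk_island`).  ``shape_fn`` takes
    vectorized ``(theta, z)`` and returns a boolean membership modulation.
    """

    kind: str
    theta_range: tuple[float, float]
    z_range: tuple[float, float]
    shape_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in PAINT_KINDS:
            raise ValueError(f"unknown paint kind {self.kind!r}")
        t0, t1 = self.theta_range
        if not (0 < t1 - t0 <= TWO_PI + 1e-12):
            raise ValueError("theta width must be in (0, 2*pi]")
        z0, z1 = self.z_range
        if not z1 > z0:
            raise ValueError("z_range must be increasing")

    @property
    def theta_width(self) -> float:
        return self.theta_range[1] - self.theta_range[0]

    @property
    def full_circumference(self) -> bool:
        return self.theta_width >= TWO_PI - 1e-9

    @classmethod
    def disk_island(cls, theta_center: float, z_center: float, diameter: float,
                    tube_radius: float, name: str = "") -> "PaintRegion":
        """A circular island of the given diameter (mm) on the unrolled wall."""
        half_arc = diameter / (2.0 * tube_radius)
        return cls(
            "island",
            (theta_center - half_arc, theta_center + half_arc),
            (z_center - diameter / 2.0, z_center + diameter / 2.0),
            name=name,
        )

    def contains(self, theta: np.ndarray, z: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        z = np.asarray(z, dtype=float)
        t0, t1 = self.theta_range
        z0, z1 = self.z_range
        dtheta = _wrap(theta - t0)
        inside = (dtheta < self.theta_width) & (z >= z0) & (z < z1)
        if self.kind == "island" and self.shape_fn is None:
            tc = (t0 + t1) / 2.0
            zc = (z0 + z1) / 2.0
            a = self.theta_width / 2.0
            b = (z1 - z0) / 2.0
            dt = _wrap(theta - tc)
            dt = np.where(dt > math.pi, dt - TWO_PI, dt)
            inside &= (dt / a) ** 2 + ((z - zc) / b) ** 2 <= 1.0
        if self.shape_fn is not None:
            inside &= np.asarray(self.shape_fn(theta, z), dtype=bool)
        return inside


@dataclass(frozen=True)
class FoldSpec:
    """Sinusoidal inward radial ridges near the distal end (gastric folds)."""

    amplitude: float = 1.0  # mm, inward
    extent: float = 15.0  # mm of axial extent at the distal end
    n_ridges: int = 3

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.extent <= 0:
            raise ValueError("fold amplitude must be >= 0 and extent > 0")


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Phantom:
    """Straight tubular esophagus phantom with painted wall regions."""

    length: float
    radius: float
    paint_regions: tuple[PaintRegion, ...] = ()
    fold_spec: FoldSpec | None = None
    z_folds: float | None = None
    squamous_color: tuple[float, float, float] = SQUAMOUS_COLOR
    barrett_color: tuple[float, float, float] = BARRETT_COLOR
    junction_color: tuple[float, float, float] = JUNCTION_COLOR

    def __post_init__(self) -> None:
        if self.length <= 0 or self.radius <= 0:
            raise ValueError("length and radius must be positive")
        object.__setattr__(self, "paint_regions", tuple(self.paint_regions))
        if self.z_folds is not None and not (0 <= self.z_folds <= self.length):
            raise ValueError("z_folds must lie within [0, length]")
        for reg in self.paint_regions:
            z0, z1 = reg.z_range
            if z0 < -1e-9 or z1 > self.length + 1e-9:
                raise ValueError(f"region {reg.name or reg.kind} outside phantom domain")
        self._check_disjoint()

    def _check_disjoint(self) -> None:
        """Islands must not overlap bands/tongues; junction paint is exclusive."""
        regions = self.paint_regions
        if len(regions) < 2:
            return
        theta = np.linspace(0.0, TWO_PI, 720, endpoint=False)
        for i, a in enumerate(regions):
            for b in regions[i + 1:]:
                pair = {a.kind, b.kind}
                if pair <= set(BARRETT_KINDS):
                    continue  # band/tongue may abut or overlap each other
                z0 = max(a.z_range[0], b.z_range[0])
                z1 = min(a.z_range[1], b.z_range[1])
                if z1 <= z0:
                    continue
                z = np.linspace(z0, z1, max(8, int((z1 - z0) * 4)), endpoint=False)
                tt, zz = np.meshgrid(theta, z)
                if np.any(a.contains(tt, zz) & b.contains(tt, zz)):
                    raise ValueError(
                        f"paint regions overlap: {a.name or a.kind} / {b.name or b.kind}"
                    )

    # -- geometry -----------------------------------------------------------

    @property
    def fold_origin(self) -> float:
        """Axial origin for C/M: ``z_folds`` if set, else the distal edge of
        the Barrett's paint (the top of the gastric folds abuts the segment)."""
        if self.z_folds is not None:
            return float(self.z_folds)
        edges = [r.z_range[1] for r in self.paint_regions if r.kind in BARRETT_KINDS]
        return float(max(edges)) if edges else float(self.length)

    def radius_at(self, z: np.ndarray | float) -> np.ndarray | float:
        """Inner wall radius at axial position z (mm)."""
        if self.fold_spec is None:
            return np.broadcast_to(np.float64(self.radius), np.shape(z)).copy() \
                if np.ndim(z) else float(self.radius)
        z = np.asarray(z, dtype=float)
        fs = self.fold_spec
        zs = self.length - fs.extent
        phase = (z - zs) / fs.extent
        ridge = 0.5 * (1.0 - np.cos(TWO_PI * fs.n_ridges * phase))
        r = self.radius - fs.amplitude * ridge * (z >= zs)
        return r if r.ndim else float(r)

    def barrett_regions(self) -> tuple[PaintRegion, ...]:
        return tuple(r for r in self.paint_regions if r.kind in BARRETT_KINDS)

    def island_regions(self) -> tuple[PaintRegion, ...]:
        return tuple(r for r in self.paint_regions if r.kind == "island")

    def junction_regions(self) -> tuple[PaintRegion, ...]:
        return tuple(r for r in self.paint_regions if r.kind == "junction")

    def color_of(self, kind: str) -> tuple[float, float, float]:
        if kind in BARRETT_KINDS or kind == "island":
            return self.barrett_color
        if kind == "junction":
            return self.junction_color
        return self.squamous_color


def build_phantom(
    length: float,
    diameter: float,
    paint_regions: Sequence[PaintRegion] = (),
    fold_spec: FoldSpec | None = None,
    z_folds: float | None = None,
    **kwargs,
) -> Phantom:
    """Construct a tubular phantom of given length and internal diameter (mm)."""
    if length <= 0 or diameter <= 0:
        raise ValueError("length and diameter must be positive")
    return Phantom(length=length, radius=diameter / 2.0,
                   paint_regions=tuple(paint_regions), fold_spec=fold_spec,
                   z_folds=z_folds, **kwargs)


# ---------------------------------------------------------------------------
# Analytic ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruth:
    """Configured (analytic) measurements of a phantom, the reference for
    everything the measurement pipeline recovers.  Lengths in mm, areas cm^2,
    C and M measured axially from ``z_folds`` toward the proximal end."""

    C: float
    M: float
    island_diameters: tuple[float, ...]
    barrett_area: float
    island_areas: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.C > self.M + 1e-9:
            raise ValueError("C must not exceed M")


def region_area_mm2(region: PaintRegion, tube_radius: float,
                    n_grid: int = 1500) -> float:
    """Painted area of one region on a constant-radius tube, in mm^2.

    Rectangular regions and inscribed-ellipse islands are closed-form; regions
    with a custom ``shape_fn`` are integrated on a fine local grid.
    """
    z0, z1 = region.z_range
    if region.shape_fn is None:
        if region.kind == "island":
            a = region.theta_width / 2.0 * tube_radius
            b = (z1 - z0) / 2.0
            return math.pi * a * b
        return region.theta_width * tube_radius * (z1 - z0)
    t0, t1 = region.theta_range
    theta = t0 + (np.arange(n_grid) + 0.5) / n_grid * (t1 - t0)
    z = z0 + (np.arange(n_grid) + 0.5) / n_grid * (z1 - z0)
    tt, zz = np.meshgrid(theta, z)
    frac = float(np.mean(region.contains(tt, zz)))
    return frac * region.theta_width * tube_radius * (z1 - z0)


def region_axial_extent(phantom: Phantom, region: PaintRegion) -> float:
    """Axial extent of a region measured from the phantom's fold origin (mm)."""
    return float(phantom.fold_origin - region.z_range[0])


def _island_diameter_mm(region: PaintRegion, tube_radius: float) -> float:
    """Maximal geodesic extent of an island on the unrolled wall."""
    z0, z1 = region.z_range
    if region.shape_fn is None:
        return max(region.theta_width * tube_radius, z1 - z0) \
            if region.kind != "island" else max(region.theta_width * tube_radius, z1 - z0)
    # grid fallback: max pairwise distance between boundary samples
    n = 600
    t0, t1 = region.theta_range
    theta = np.linspace(t0, t1, n)
    z = np.linspace(z0, z1, n)
    tt, zz = np.meshgrid(theta, z)
    m = region.contains(tt, zz)
    if not m.any():
        return 0.0
    xs = tt[m] * tube_radius
    ys = zz[m]
    pts = np.stack([xs, ys], axis=1)
    from scipy.spatial import ConvexHull

    hull = pts[ConvexHull(pts).vertices]
    d2 = ((hull[:, None, :] - hull[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def ground_truth_measurements(phantom: Phantom, dz: float = 0.02) -> GroundTruth:
    """Analytic C/M/area ground truth for a phantom (constant-radius wall).

    C is the axial length, measured from ``z_folds`` toward the proximal end,
    over which Barrett's paint (bands/tongues) covers the full circumference;
    M is the maximal axial Barrett's extent from the same origin.  Junction
    paint between the Barrett's segment and ``z_folds`` counts toward coverage
    (the segment starts at the top of the folds by definition).
    """
    main = phantom.barrett_regions()
    islands = phantom.island_regions()
    r = phantom.radius
    if not main and not islands:
        return GroundTruth(0.0, 0.0, (), 0.0, ())

    M = max((region_axial_extent(phantom, reg) for reg in main), default=0.0)
    M = max(M, 0.0)

    # Circumferential extent: scan z from z_folds downward; a z-level counts as
    # covered if Barrett's or junction paint fills all theta there.
    C = 0.0
    if main:
        z_lo = min(reg.z_range[0] for reg in main)
        origin = phantom.fold_origin
        n = max(4, int(math.ceil((origin - z_lo) / dz)))
        z = origin - (np.arange(n) + 0.5) * dz
        z = z[z >= 0]
        theta = np.linspace(0.0, TWO_PI, 1440, endpoint=False)
        tt, zz = np.meshgrid(theta, z)
        covered = np.zeros_like(tt, dtype=bool)
        for reg in main + phantom.junction_regions():
            covered |= reg.contains(tt, zz)
        full = covered.all(axis=1)
        # contiguous full-coverage run starting at the fold origin
        run = 0
        for flag in full:
            if flag:
                run += 1
            else:
                break
        C = run * dz
        C = min(C, M)

    barrett_area = sum(region_area_mm2(reg, r) for reg in main) / 100.0
    island_areas = tuple(region_area_mm2(reg, r) / 100.0 for reg in islands)
    island_diams = tuple(_island_diameter_mm(reg, r) for reg in islands)
    return GroundTruth(C=C, M=M, island_diameters=island_diams,
                       barrett_area=barrett_area, island_areas=island_areas)


# ---------------------------------------------------------------------------
# Camera trajectories
# ---------------------------------------------------------------------------

TRAJECTORY_KINDS = ("straight", "spiral", "zigzag")


def sample_trajectory(
    kind: str,
    n_frames: int,
    rotation_deg_range: tuple[float, float] = (1.0, 45.0),
    inclination_deg_range: tuple[float, float] = (1.0, 30.0),
    direction: str = "forward",
    seed: int = 0,
    tube_length: float = 187.5,
    tube_radius: float = 10.0,
    z_range: tuple[float, float] | None = None,
    lateral_amplitude: float = 3.0,
) -> list[Pose]:
    """Sample a deterministic camera trajectory inside the tube lumen.

    ``rotation`` is the endoscope roll about the viewing axis, ``inclination``
    the tilt of the viewing axis off the tube axis (both degrees, sampled
    uniformly in the given ranges).  ``forward`` advances toward the distal
    end (+z) looking distally, ``reverse`` withdraws looking proximally.
    """
    if kind not in TRAJECTORY_KINDS:
        raise ValueError(f"unknown trajectory kind {kind!r}")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    r0, r1 = rotation_deg_range
    i0, i1 = inclination_deg_range
    if not (0 <= r0 <= r1 <= 45):
        raise ValueError("rotation range must lie within [0, 45] degrees")
    if not (0 <= i0 <= i1 <= 30):
        raise ValueError("inclination range must lie within [0, 30] degrees")
    if lateral_amplitude >= tube_radius:
        raise ValueError("lateral amplitude must keep the camera inside the lumen")

    rng = np.random.default_rng(seed)
    if z_range is None:
        z_range = (0.08 * tube_length, 0.55 * tube_length)
    z0, z1 = z_range
    zs = np.linspace(z0, z1, n_frames) if n_frames > 1 else np.array([(z0 + z1) / 2.0])
    if direction == "reverse":
        zs = zs[::-1]

    base = np.eye(3) if direction == "forward" else _rot_x(math.pi)
    poses: list[Pose] = []
    for i, z in enumerate(zs):
        if kind == "straight":
            x = y = 0.0
        elif kind == "spiral":
            phase = TWO_PI * i / max(n_frames - 1, 1)
            x = lateral_amplitude * math.cos(phase)
            y = lateral_amplitude * math.sin(phase)
        else:  # zigzag
            x = lateral_amplitude * (1.0 if i % 2 == 0 else -1.0)
            y = 0.0
        roll = math.radians(rng.uniform(r0, r1))
        incl = math.radians(rng.uniform(i0, i1))
        azim = rng.uniform(0.0, TWO_PI)
        tilt_axis = np.array([-math.sin(azim), math.cos(azim), 0.0])
        R = base @ _rot_axis(tilt_axis, incl) @ _rot_z(roll)
        poses.append(Pose(R, np.array([x, y, float(z)])))
    return poses


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


@dataclass
class Frame:
    """One rendered endoscopic frame: RGB, z-depth map (mm), pose and GT masks.

    ``depth`` stores the camera-frame z coordinate of the surface point seen by
    each pixel (the convention of monocular depth estimators); 0 marks rays
    that exit the tube without hitting the wall.  ``label_map`` holds the
    1-based paint-region index per pixel (0 = squamous background, -1 = no hit).
    """

    rgb: np.ndarray
    depth: np.ndarray
    pose: Pose
    gt_masks: SegMasks
    frame_id: int = 0
    label_map: np.ndarray | None = None


def _intersect_tube(phantom: Phantom, origins: np.ndarray, dirs: np.ndarray):
    """Ray-tube intersection. Returns (ray_length s, valid) for unit ``dirs``.

    Closed form for the constant-radius wall; a vectorized bisection refines
    hits inside the fold zone when a ``FoldSpec`` perturbs the radius.
    """
    ox, oy, oz = origins[..., 0], origins[..., 1], origins[..., 2]
    dx, dy, dz = dirs[..., 0], dirs[..., 1], dirs[..., 2]
    a = dx * dx + dy * dy
    b = 2.0 * (ox * dx + oy * dy)
    c = ox * ox + oy * oy - phantom.radius ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = b * b - 4.0 * a * c
        s = (-b + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * a)
    axial = a < 1e-14
    s = np.where(axial, np.inf, s)

    if phantom.fold_spec is not None and phantom.fold_spec.amplitude > 0:
        fs = phantom.fold_spec
        zs_fold = phantom.length - fs.extent
        # solve again for the minimal fold radius to bracket the true root
        c_in = ox * ox + oy * oy - (phantom.radius - fs.amplitude) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            disc_in = b * b - 4.0 * a * c_in
            s_in = (-b + np.sqrt(np.maximum(disc_in, 0.0))) / (2.0 * a)
        s_in = np.where(axial | (disc_in < 0), s, s_in)
        z_hi = oz + s * dz
        needs = (~axial) & (np.maximum(z_hi, oz + s_in * dz) >= zs_fold)
        if needs.any():
            lo = np.where(needs, np.minimum(s_in, s), s)
            hi = np.where(needs, np.maximum(s_in, s), s)

            def g(sv):
                px = ox + sv * dx
                py = oy + sv * dy
                pz = oz + sv * dz
                return np.hypot(px, py) - np.asarray(phantom.radius_at(pz))

            # radial distance increases along the outgoing ray, so g is
            # monotone on [lo, hi]; 60 bisection steps give ~1e-12 mm
            glo = g(lo)
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                gm = g(mid)
                take_lo = (gm * glo) > 0
                lo = np.where(needs & take_lo, mid, lo)
                glo = np.where(needs & take_lo, gm, glo)
                hi = np.where(needs & ~take_lo, mid, hi)
            s = np.where(needs, 0.5 * (lo + hi), s)

    z_hit = oz + s * dz
    valid = (~axial) & np.isfinite(s) & (s > 1e-9) & (z_hit >= 0.0) & (z_hit <= phantom.length)
    return np.where(valid, s, 0.0), valid


def render_frame(
    phantom: Phantom,
    pose: Pose,
    camera: CameraModel,
    light: LightModel | None = None,
    frame_id: int = 0,
) -> Frame:
    """Ray-cast one frame: RGB + ground-truth z-depth map + GT masks."""
    light = light or LightModel()
    o = pose.translation
    r_here = float(np.atleast_1d(phantom.radius_at(float(np.clip(o[2], 0, phantom.length))))[0])
    if not (0.0 <= o[2] <= phantom.length) or math.hypot(o[0], o[1]) >= r_here - 0.25:
        raise ValueError("camera must be inside the tube lumen")

    dirs_cam = camera.ray_directions()  # (H, W, 3) unit
    dirs = dirs_cam @ pose.rotation.T
    origins = np.broadcast_to(o, dirs.shape)

    s, valid = _intersect_tube(phantom, origins, dirs)
    if not valid.any():
        raise ValueError("camera points fully away from the tube surface")

    pts = origins + s[..., None] * dirs
    theta = _wrap(np.arctan2(pts[..., 1], pts[..., 0]))
    z = pts[..., 2]

    # z-depth (camera-frame z), the quantity stored in depth maps
    depth = np.where(valid, s * dirs_cam[..., 2], 0.0)

    label = np.full(s.shape, -1, dtype=np.int16)
    label[valid] = 0
    region_masks: list[np.ndarray] = []
    for idx, reg in enumerate(phantom.paint_regions, start=1):
        m = valid & reg.contains(theta, z)
        region_masks.append(m)
        label[m] = idx

    # Lambertian shading, point light at the camera with quadratic attenuation
    if phantom.fold_spec is not None:
        eps = 1e-4
        drdz = (np.asarray(phantom.radius_at(z + eps)) - np.asarray(phantom.radius_at(z - eps))) / (2 * eps)
    else:
        drdz = np.zeros_like(z)
    normal = np.stack([-np.cos(theta), -np.sin(theta), drdz], axis=-1)
    normal /= np.linalg.norm(normal, axis=-1, keepdims=True)
    to_light = -dirs  # light co-located with camera
    lambert = np.clip(np.einsum("...k,...k", normal, to_light), 0.0, None)
    shade = light.intensity * lambert / (1.0 + light.attenuation * s * s) + light.ambient
    shade = np.where(valid, shade, 0.0)

    colors = np.empty(s.shape + (3,), dtype=np.float64)
    colors[...] = phantom.squamous_color
    for reg, m in zip(phantom.paint_regions, region_masks):
        colors[m] = phantom.color_of(reg.kind)
    rgb = np.clip(colors * shade[..., None], 0.0, 1.0).astype(np.float32)
    rgb[~valid] = 0.0

    bea = np.zeros(s.shape, dtype=bool)
    junction = np.zeros(s.shape, dtype=bool)
    islands: list[np.ndarray] = []
    for reg, m in zip(phantom.paint_regions, region_masks):
        if reg.kind in BARRETT_KINDS:
            bea |= m
        elif reg.kind == "junction":
            junction |= m
        elif reg.kind == "island":
            islands.append(m)
    gt_masks = SegMasks(bea=bea, islands=islands, junction=junction, valid=valid)
    return Frame(rgb=rgb, depth=depth, pose=pose, gt_masks=gt_masks,
                 frame_id=frame_id, label_map=label)
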