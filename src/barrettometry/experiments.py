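"""Reference in-silico phantom experiments: length (Prague C&M + islands) and
area (BEA + islands) marker recovery on digital phantoms with known geometry.

These mirror the printed-phantom validation protocol: a tube of 18.75 cm
length and 2 cm internal diameter carries painted markers of known extent; the
pipeline measures each marker in five frames taken from slightly different
camera poses and the per-marker means are compared with the configured ground
truth.  Frames are chosen so the method's stated assumptions hold (gastric
folds visible, camera near-perpendicular to the junction, markers in view) --
frame selection matters for this measurement principle, for the simulator as
much as for real endoscopy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .masks import SegMasks
from .metrics import EvalReport, evaluate_dataset
from .phantom import (
    CameraModel,
    FoldSpec,
    LightModel,
    PaintRegion,
    Phantom,
    Pose,
    build_phantom,
    render_frame,
    _rot_axis,
    _rot_z,
)
from .quantification import measure_area, measure_island_diameter, measure_prague

TUBE_LENGTH = 187.5  # mm
TUBE_DIAMETER = 20.0  # mm
R = TUBE_DIAMETER / 2.0

# Length markers (mm): circumferential collar C, two tongues (maximal extents
# Ma, Mb) and two island diameters -- the printed-phantom marker set.
LENGTH_MARKERS = {"Ma": 70.0, "Mb": 65.7, "C": 23.4, "Island 1": 20.3, "Island 2": 14.3}

# Area markers (cm^2): three circumferential Barrett's areas and two islands.
AREA_MARKERS = {
    "Barrett's Area 1": 62.19,
    "Barrett's Area 2": 69.05,
    "Barrett's Area 3": 76.25,
    "Island 1": 2.30,
    "Island 2": 2.90,
}

# Measurement camera: narrower field of view (~53 deg) than the simulator
# default so the junction landmark is resolved at the 9-15 cm working range.
MEASUREMENT_CAMERA = CameraModel(focal_length=256.0)

_FOLD_W = 1.0       # axial extent of the painted fold landmark (mm)
_JUNCTION_ARC = 0.9  # half-arc of the fold patch (rad), around theta = 0


def _tapered_tongue(theta_c: float, half_width: float, z_tip: float,
                    z_top: float, taper_len: float = 15.0,
                    name: str = "") -> PaintRegion:
    """A Barrett's tongue tapering to a point at its proximal tip, the shape
    tongues take in endoscopic views (and it puts the hull extremum at the
    tip rather than at a square corner)."""

    def fn(theta, z):
        import numpy as _np

        dt = _np.abs(_np.mod(theta - theta_c + math.pi, 2 * math.pi) - math.pi)
        frac = _np.clip((z - z_tip) / taper_len, 0.0, 1.0)
        return dt <= half_width * frac

    return PaintRegion("tongue", (theta_c - half_width, theta_c + half_width),
                       (z_tip, z_top), shape_fn=fn, name=name)


def build_length_phantom() -> Phantom:
    """Tube phantom with the length-marker paint layout.

    The gastric-fold landmark is a narrow patch at the distal end around
    theta=0, the side the tongues extend on (converging folds appear as a
    localized ridge patch in endoscopic views); ``z_folds``, the top of the
    folds, is its proximal edge.  The circumferential band and both tapered
    tongues abut the fold paint there; the islands sit on the opposite wall.
    """
    L = TUBE_LENGTH
    z_folds = L - _FOLD_W
    band_top = z_folds
    regions = [
        PaintRegion("junction", (-_JUNCTION_ARC, _JUNCTION_ARC), (z_folds, L),
                    name="folds"),
        PaintRegion("band", (0.0, 2 * math.pi),
                    (z_folds - LENGTH_MARKERS["C"], band_top), name="band"),
        _tapered_tongue(-0.35, 0.25, z_folds - LENGTH_MARKERS["Ma"], band_top,
                        name="tongue_a"),
        _tapered_tongue(0.35, 0.25, z_folds - LENGTH_MARKERS["Mb"], band_top,
                        name="tongue_b"),
        PaintRegion.disk_island(2.2, L - 60.0, LENGTH_MARKERS["Island 1"], R,
                                name="island_1"),
        PaintRegion.disk_island(-2.2, L - 52.0, LENGTH_MARKERS["Island 2"], R,
                                name="island_2"),
    ]
    return build_phantom(L, TUBE_DIAMETER, regions, z_folds=z_folds)


def _measurement_poses(rng: np.random.Generator, n_frames: int,
                       base_z: float, incl_range=(8.0, 12.0)) -> list[Pose]:
    """Frames for junction-referenced measurement: camera on-axis, inclined
    toward the fold patch (theta=0), with roll and axial jitter."""
    poses = []
    for _ in range(n_frames):
        z = base_z + rng.uniform(-4.0, 4.0)
        incl = math.radians(rng.uniform(*incl_range))
        roll = math.radians(rng.uniform(1.0, 45.0))
        # tilt toward +x (theta=0): axis (0, 1, 0)
        Rm = _rot_axis(np.array([0.0, 1.0, 0.0]), incl) @ _rot_z(roll)
        poses.append(Pose(Rm, np.array([0.0, 0.0, z])))
    return poses


def _submask(frame, phantom: Phantom, names: set[str]) -> np.ndarray:
    """Union of GT region masks selected by region name."""
    out = np.zeros(frame.label_map.shape, dtype=bool)
    for idx, reg in enumerate(phantom.paint_regions, start=1):
        if reg.name in names:
            out |= frame.label_map == idx
    return out


@dataclass
class ExperimentResult:
    markers: list[str]
    ground_truth: np.ndarray
    automated_mean: np.ndarray
    automated_std: np.ndarray
    per_frame: dict[str, list[float]]
    report: EvalReport
    n_frames: int

    def summary(self) -> str:
        lines = [f"{'marker':<18}{'ground truth':>14}{'automated':>12}"
                 f"{'abs diff':>10}{'rel err %':>11}"]
        for i, name in enumerate(self.markers):
            lines.append(
                f"{name:<18}{self.ground_truth[i]:>14.2f}"
                f"{self.automated_mean[i]:>12.2f}"
                f"{self.report.abs_difference[i]:>10.2f}"
                f"{self.report.relative_error_pct[i]:>11.2f}"
            )
        lines.append(
            f"{'overall':<18}{'':>14}{'':>12}"
            f"{self.report.mean_abs_difference:>10.2f}"
            f"{self.report.mean_relative_error_pct:>11.2f}"
        )
        return "\n".join(lines)


def run_length_experiment(seed: int = 0, n_frames: int = 5) -> ExperimentResult:
    """Measure the five length markers (Ma, Mb, C, two island diameters).

    Each marker is measured on its own mask, the in-silico analog of putting
    calipers on one painted marker at a time: C on the circumferential collar
    alone (a tongue next to the fold patch would otherwise shadow the collar's
    edge from the convex hull), each tongue's maximal extent on band+tongue,
    island diameters on the island masks.  All measurements use simulator
    ground-truth depth and masks, repeated over ``n_frames`` poses and the
    per-marker means compared against the configured geometry.
    """
    rng = np.random.default_rng(seed)
    phantom = build_length_phantom()
    camera = MEASUREMENT_CAMERA
    base_z = phantom.z_folds - 95.0
    per_frame: dict[str, list[float]] = {k: [] for k in LENGTH_MARKERS}
    for pose in _measurement_poses(rng, n_frames, base_z):
        frame = render_frame(phantom, pose, camera)
        masks = frame.gt_masks
        depth = frame.depth

        def _marker_masks(names: set[str]) -> SegMasks:
            return SegMasks(bea=_submask(frame, phantom, names), islands=[],
                            junction=masks.junction, valid=masks.valid)

        # each printed marker is measured on its own mask, as with calipers:
        # C on the circumferential collar (its hull edge would otherwise be
        # shadowed by the tongues), each tongue's maximal extent on band+tongue
        c, _, _ = measure_prague(_marker_masks({"band"}), depth, camera)
        _, ma, _ = measure_prague(_marker_masks({"band", "tongue_a"}), depth, camera)
        _, mb, _ = measure_prague(_marker_masks({"band", "tongue_b"}), depth, camera)
        i1 = measure_island_diameter(_submask(frame, phantom, {"island_1"}),
                                     depth, camera)
        i2 = measure_island_diameter(_submask(frame, phantom, {"island_2"}),
                                     depth, camera)
        for key, val in zip(per_frame, (ma, mb, c, i1, i2)):
            per_frame[key].append(val)
    return _finalize(per_frame, LENGTH_MARKERS, unit="mm", category_scale=0.1,
                     n_frames=n_frames)


def build_area_band_phantom(area_cm2: float) -> Phantom:
    """Circumferential Barrett's band of the given total area with an annular
    gastric-fold region (A_fold > 1 cm^2, so the subtraction rule applies)."""
    L = TUBE_LENGTH
    h = area_cm2 * 100.0 / (2 * math.pi * R)
    regions = [
        PaintRegion("junction", (0.0, 2 * math.pi), (L - _FOLD_W, L), name="folds"),
        PaintRegion("band", (0.0, 2 * math.pi), (L - _FOLD_W - h, L - _FOLD_W),
                    name="band"),
    ]
    return build_phantom(L, TUBE_DIAMETER, regions, z_folds=L - _FOLD_W)


def build_area_island_phantom() -> Phantom:
    """Two islands with the configured areas on an otherwise squamous tube."""
    L = TUBE_LENGTH
    d1 = 2.0 * math.sqrt(AREA_MARKERS["Island 1"] * 100.0 / math.pi)
    d2 = 2.0 * math.sqrt(AREA_MARKERS["Island 2"] * 100.0 / math.pi)
    regions = [
        PaintRegion("junction", (0.0, 2 * math.pi), (L - _FOLD_W, L), name="folds"),
        PaintRegion.disk_island(1.8, L - 110.0, d1, R, name="island_1"),
        PaintRegion.disk_island(-1.8, L - 101.0, d2, R, name="island_2"),
    ]
    return build_phantom(L, TUBE_DIAMETER, regions, z_folds=L - _FOLD_W)


def run_area_experiment(seed: int = 0, n_frames: int = 5) -> ExperimentResult:
    """Measure the five area markers: three band BEAs and two island areas.

    Band frames view the whole band head-on from the proximal side; the BEA is
    the hull-enclosed area minus the gastric-fold area (A_fold > 1 cm^2 here).
    Island areas integrate each island's own mask in closer frames.
    """
    rng = np.random.default_rng(seed)
    camera = MEASUREMENT_CAMERA
    per_frame: dict[str, list[float]] = {k: [] for k in AREA_MARKERS}

    for name in ("Barrett's Area 1", "Barrett's Area 2", "Barrett's Area 3"):
        phantom = build_area_band_phantom(AREA_MARKERS[name])
        band_bottom = min(r.z_range[0] for r in phantom.barrett_regions())
        for _ in range(n_frames):
            z = band_bottom - 25.0 + rng.uniform(-2.0, 2.0)
            incl = math.radians(rng.uniform(0.5, 2.0))
            roll = math.radians(rng.uniform(1.0, 45.0))
            azim = rng.uniform(0, 2 * math.pi)
            Rm = _rot_axis(np.array([-math.sin(azim), math.cos(azim), 0.0]), incl)
            pose = Pose(Rm @ _rot_z(roll), np.array([0.0, 0.0, z]))
            frame = render_frame(phantom, pose, camera)
            _, _, bea, _ = measure_area(frame.gt_masks, frame.depth, camera)
            per_frame[name].append(bea)

    phantom = build_area_island_phantom()
    for _ in range(n_frames):
        z = TUBE_LENGTH - 145.0 + rng.uniform(-3.0, 3.0)
        incl = math.radians(rng.uniform(0.5, 2.0))
        roll = math.radians(rng.uniform(1.0, 45.0))
        azim = rng.uniform(0, 2 * math.pi)
        Rm = _rot_axis(np.array([-math.sin(azim), math.cos(azim), 0.0]), incl)
        pose = Pose(Rm @ _rot_z(roll), np.array([0.0, 0.0, z]))
        frame = render_frame(phantom, pose, camera)
        _, _, _, island_areas = measure_area(frame.gt_masks, frame.depth, camera)
        per_frame["Island 1"].append(island_areas[0])
        per_frame["Island 2"].append(island_areas[1])

    return _finalize(per_frame, AREA_MARKERS, unit="cm^2", category_scale=1.0,
                     n_frames=n_frames)


def _finalize(per_frame: dict[str, list[float]], truth: dict[str, float],
              unit: str, category_scale: float, n_frames: int) -> ExperimentResult:
    markers = list(truth)
    gt = np.array([truth[k] for k in markers])
    mean = np.array([np.mean(per_frame[k]) for k in markers])
    std = np.array([np.std(per_frame[k], ddof=1) if len(per_frame[k]) > 1 else 0.0
                    for k in markers])
    report = evaluate_dataset(mean, gt, labels=markers, unit=unit,
                              category_scale=category_scale)
    return ExperimentResult(markers=markers, ground_truth=gt,
                            automated_mean=mean, automated_std=std,
                            per_frame=per_frame, report=report,
                            n_frames=n_frames)
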