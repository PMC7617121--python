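"""Dataset generation and on-disk format: rendered frames as PNG (RGB, masks),
32-bit float TIFF (depth, mm) and a JSON manifest with poses, ground truth and
the generating config (hashed for reproducibility)."""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .masks import SegMasks
from .phantom import (
    CameraModel,
    FoldSpec,
    LightModel,
    LightTier,
    PaintRegion,
    Phantom,
    Pose,
    build_phantom,
    ground_truth_measurements,
    render_frame,
    sample_trajectory,
)

LIGHT_TIERS = {"low": LightTier.LOW, "medium": LightTier.MEDIUM,
               "bright": LightTier.BRIGHT}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def phantom_from_config(cfg: dict) -> Phantom:
    regions = []
    radius = cfg["diameter"] / 2.0
    for rc in cfg.get("regions", []):
        if "theta_center" in rc:  # disk island shorthand
            regions.append(
                PaintRegion.disk_island(rc["theta_center"], rc["z_center"],
                                        rc["diameter"], radius,
                                        name=rc.get("name", ""))
            )
        else:
            regions.append(
                PaintRegion(rc["kind"], tuple(rc["theta_range"]),
                            tuple(rc["z_range"]), name=rc.get("name", ""))
            )
    fold = None
    if "fold_spec" in cfg:
        fold = FoldSpec(**cfg["fold_spec"])
    return build_phantom(cfg["length"], cfg["diameter"], regions,
                         fold_spec=fold, z_folds=cfg.get("z_folds"))


def camera_from_config(cfg: dict | None) -> CameraModel:
    cfg = cfg or {}
    kwargs = {}
    if "focal_length" in cfg:
        kwargs["focal_length"] = float(cfg["focal_length"])
    if "image_size" in cfg:
        kwargs["image_size"] = tuple(cfg["image_size"])
    if "principal_point" in cfg:
        kwargs["principal_point"] = tuple(cfg["principal_point"])
    return CameraModel(**kwargs)


def _pose_to_json(pose: Pose) -> dict:
    return {"rotation": [float(x) for x in pose.rotation.ravel()],  # row-major
            "translation": [float(x) for x in pose.translation]}


def pose_from_json(d: dict) -> Pose:
    return Pose(np.array(d["rotation"]).reshape(3, 3), np.array(d["translation"]))


def _write_masks(masks: SegMasks, stem: Path) -> dict:
    files = {}
    iio.imwrite(f"{stem}_mask_bea.png",
                (masks.bea * 255).astype(np.uint8))
    files["mask_bea"] = f"{stem.name}_mask_bea.png"
    if masks.junction is not None:
        iio.imwrite(f"{stem}_mask_junction.png",
                    (masks.junction * 255).astype(np.uint8))
        files["mask_junction"] = f"{stem.name}_mask_junction.png"
    if masks.islands:
        lab = np.zeros(masks.bea.shape, dtype=np.uint8)
        for i, isl in enumerate(masks.islands, start=1):
            lab[isl] = i
        iio.imwrite(f"{stem}_mask_islands.png", lab)
        files["mask_islands"] = f"{stem.name}_mask_islands.png"
    return files


def generate_dataset(config: dict, out_dir: str | Path) -> dict:
    """Render every trajectory x lighting-tier combination and write it out.

    Returns the manifest (also written to ``manifest.json``): one record per
    frame with file names, pose and trajectory/lighting provenance, plus the
    phantom's analytic ground-truth measurements, the seed and a config hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    phantom = phantom_from_config(config["phantom"])
    camera = camera_from_config(config.get("camera"))
    tiers = config.get("lighting", ["bright"])
    gt = ground_truth_measurements(phantom)

    records = []
    fid = 0
    for t_idx, traj_cfg in enumerate(config["trajectories"]):
        tc = dict(traj_cfg)
        kind = tc.pop("kind")
        n_frames = tc.pop("n_frames")
        poses = sample_trajectory(
            kind, n_frames,
            rotation_deg_range=tuple(tc.get("rotation_deg_range", (1, 45))),
            inclination_deg_range=tuple(tc.get("inclination_deg_range", (1, 30))),
            direction=tc.get("direction", "forward"),
            seed=seed + t_idx,
            tube_length=phantom.length,
            tube_radius=phantom.radius,
            z_range=tuple(tc["z_range"]) if "z_range" in tc else None,
        )
        for tier in tiers:
            light = LightModel(intensity=LIGHT_TIERS[tier])
            for pose in poses:
                frame = render_frame(phantom, pose, camera, light, frame_id=fid)
                stem = out / f"frame_{fid:05d}"
                iio.imwrite(f"{stem}_rgb.png",
                            (frame.rgb * 255).round().astype(np.uint8))
                tifffile.imwrite(f"{stem}_depth.tif",
                                 frame.depth.astype(np.float32))
                files = {"rgb": f"{stem.name}_rgb.png",
                         "depth": f"{stem.name}_depth.tif"}
                files.update(_write_masks(frame.gt_masks, stem))
                records.append({
                    "frame_id": fid,
                    "trajectory": {"kind": kind, "index": t_idx},
                    "lighting": tier,
                    "pose": _pose_to_json(pose),
                    "files": files,
                })
                fid += 1

    manifest = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "camera": {
            "focal_length": camera.focal_length,
            "principal_point": list(camera.principal_point),
            "image_size": list(camera.image_size),
        },
        "ground_truth": {
            "C_mm": gt.C,
            "M_mm": gt.M,
            "island_diameters_mm": list(gt.island_diameters),
            "barrett_area_cm2": gt.barrett_area,
            "island_areas_cm2": list(gt.island_areas),
        },
        "n_frames": len(records),
        "frames": records,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_manifest(dataset_dir: str | Path) -> dict:
    path = Path(dataset_dir) / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.json in {dataset_dir}")
    with open(path) as fh:
        return json.load(fh)


def load_frame(dataset_dir: str | Path, record: dict):
    """Rebuild a Frame (rgb, depth, gt masks, pose) from its manifest record."""
    from .phantom import Frame

    d = Path(dataset_dir)
    files = record["files"]
    rgb = iio.imread(d / files["rgb"]).astype(np.float64) / 255.0
    depth = tifffile.imread(d / files["depth"]).astype(np.float64)
    bea = iio.imread(d / files["mask_bea"]) > 0
    junction = None
    if "mask_junction" in files:
        junction = iio.imread(d / files["mask_junction"]) > 0
    islands = []
    if "mask_islands" in files:
        lab = iio.imread(d / files["mask_islands"])
        islands = [lab == k for k in range(1, int(lab.max()) + 1)]
    masks = SegMasks(bea=bea, islands=islands, junction=junction,
                     valid=depth > 0)
    return Frame(rgb=rgb, depth=depth, pose=pose_from_json(record["pose"]),
                 gt_masks=masks, frame_id=record["frame_id"])
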