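"""Color-based segmentation of phantom frames and mask hygiene utilities.

The phantom paints tissue classes with flat colors under varying illumination,
so pixels are classified by their nearest reference color in hue-saturation
space (brightness-invariant).  The quantification module consumes masks only
through :class:`~barrettometry.masks.SegMasks`, so a learned segmenter can be
swapped in behind the same interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor
from skimage import measure, morphology
from scipy import ndimage

from .masks import SegMasks
from . import phantom as ph


@dataclass(frozen=True)
class ColorConfig:
    """Reference RGB colors (in [0, 1]) for the three phantom tissue classes."""

    squamous: tuple[float, float, float] = ph.SQUAMOUS_COLOR
    barrett: tuple[float, float, float] = ph.BARRETT_COLOR
    junction: tuple[float, float, float] = ph.JUNCTION_COLOR
    value_floor: float = 0.02  # pixels darker than this are unclassifiable
    min_component_px: int = 25


def _hs_coords(rgb: np.ndarray) -> np.ndarray:
    """Map RGB to points on the hue circle scaled by saturation (2D)."""
    hsv = skcolor.rgb2hsv(rgb.reshape(-1, 1, 3)).reshape(-1, 3)
    ang = hsv[:, 0] * 2 * np.pi
    return np.stack([hsv[:, 1] * np.cos(ang), hsv[:, 1] * np.sin(ang)], axis=1)


def clean_mask(mask: np.ndarray, min_area_px: int = 25) -> np.ndarray:
    """Morphological closing followed by small-component removal; idempotent."""
    mask = np.asarray(mask, dtype=bool)
    closed = morphology.closing(mask, footprint=morphology.disk(1))
    labels = measure.label(closed, connectivity=2)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_area_px
    keep[0] = False
    return keep[labels]


def split_islands(bea_all: np.ndarray,
                  junction: np.ndarray | None) -> tuple[np.ndarray, list[np.ndarray]]:
    """Split a Barrett's mask into the main segment and separate islands.

    8-connected components; the component adjacent to the junction mask is the
    main segment (the one rooted at the gastric folds), falling back to the
    largest component when none touches the junction.
    """
    bea_all = np.asarray(bea_all, dtype=bool)
    labels = measure.label(bea_all, connectivity=2)
    n = labels.max()
    if n == 0:
        return np.zeros_like(bea_all), []
    main_label = 0
    if junction is not None and np.asarray(junction).any():
        near_junction = ndimage.binary_dilation(np.asarray(junction, dtype=bool),
                                                iterations=2)
        overlaps = ndimage.sum_labels(near_junction, labels, index=np.arange(1, n + 1))
        if overlaps.max() > 0:
            main_label = int(np.argmax(overlaps)) + 1
    if main_label == 0:
        sizes = np.bincount(labels.ravel())[1:]
        main_label = int(np.argmax(sizes)) + 1
    main = labels == main_label
    islands = [labels == k for k in range(1, n + 1) if k != main_label]
    return main, islands


def segment_phantom_colors(
    rgb: np.ndarray,
    colors: ColorConfig | None = None,
    valid: np.ndarray | None = None,
) -> SegMasks:
    """Classify pixels by nearest reference color in hue-saturation space.

    ``valid`` restricts classification to pixels with a surface (e.g. depth>0);
    otherwise pixels brighter than the value floor are considered.
    """
    colors = colors or ColorConfig()
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3 or rgb.min() < -1e-9 or rgb.max() > 1 + 1e-9:
        raise ValueError("rgb must be HxWx3 in [0, 1]")
    h, w = rgb.shape[:2]
    hsv_v = skcolor.rgb2hsv(rgb)[..., 2]
    classifiable = hsv_v > colors.value_floor
    if valid is not None:
        classifiable &= np.asarray(valid, dtype=bool)
    if not classifiable.any():
        warnings.warn("no classifiable pixels in frame; returning empty masks")
        empty = np.zeros((h, w), dtype=bool)
        return SegMasks(bea=empty, islands=[], junction=empty.copy(),
                        valid=classifiable)

    refs = _hs_coords(np.array([colors.squamous, colors.barrett, colors.junction],
                               dtype=np.float64))
    px = _hs_coords(rgb[classifiable])
    d2 = ((px[:, None, :] - refs[None, :, :]) ** 2).sum(-1)
    cls = np.argmin(d2, axis=1)  # 0 squamous, 1 barrett, 2 junction

    barrett = np.zeros((h, w), dtype=bool)
    junction = np.zeros((h, w), dtype=bool)
    barrett[classifiable] = cls == 1
    junction[classifiable] = cls == 2

    barrett = clean_mask(barrett, colors.min_component_px)
    junction_clean = clean_mask(junction, colors.min_component_px)
    # a distant junction landmark may legitimately be only a few pixels
    if not junction_clean.any():
        junction_clean = junction
    main, islands = split_islands(barrett, junction_clean)
    return SegMasks(bea=main, islands=islands, junction=junction_clean,
                    valid=classifiable)
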