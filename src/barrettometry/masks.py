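"""Segmentation mask container shared by the simulator and the segmenter."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SegMasks:
    """Binary masks for one endoscopic frame.

    Attributes
    ----------
    bea:
        Main (contiguous) Barrett's segment, tongues included.
    islands:
        One mask per island component, each disjoint from ``bea``.
    junction:
        Gastric folds / gastroesophageal junction region.
    valid:
        Pixels with valid depth (a surface was hit / depth > 0).
    """

    bea: np.ndarray
    islands: list[np.ndarray] = field(default_factory=list)
    junction: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bea = np.asarray(self.bea, dtype=bool)
        self.islands = [np.asarray(m, dtype=bool) for m in self.islands]
        if self.junction is not None:
            self.junction = np.asarray(self.junction, dtype=bool)
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
        shapes = {self.bea.shape}
        shapes.update(m.shape for m in self.islands)
        if self.junction is not None:
            shapes.add(self.junction.shape)
        if self.valid is not None:
            shapes.add(self.valid.shape)
        if len(shapes) != 1:
            raise ValueError(f"mask shapes differ: {shapes}")
        for i, isl in enumerate(self.islands):
            if np.any(isl & self.bea):
                raise ValueError(f"island {i} overlaps the main Barrett's mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bea.shape

    def all_barretts(self) -> np.ndarray:
        """Union of the main segment and every island."""
        out = self.bea.copy()
        for isl in self.islands:
            out |= isl
        return out
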