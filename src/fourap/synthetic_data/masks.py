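"""Procedural anatomical region masks on the 320x240 camera frame.

Four polygonal sectors mimic the arrangement of the temporal cortex (TC),
perirhinal cortex (PC), entorhinal cortex (EC) and the comparatively small
subiculum (SUB) in a horizontal combined slice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
from matplotlib.path import Path

from .. import REGIONS

__all__ = ["RegionMaskSet", "build_region_masks", "FRAME_SHAPE"]

FRAME_SHAPE = (240, 320)  # (rows, cols)

# polygon vertices as (col, row); SUB deliberately the smallest sector
_POLYGONS: dict[str, list[tuple[float, float]]] = {
    "SUB": [(205, 120), (258, 132), (248, 172), (200, 158)],
    "EC": [(200, 25), (290, 60), (270, 140), (205, 95)],
    "PC": [(110, 25), (200, 25), (205, 95), (130, 95)],
    "TC": [(15, 60), (110, 25), (130, 95), (40, 140)],
}


@dataclass(frozen=True)
class RegionMaskSet(Mapping):
    """Mutually disjoint boolean masks, one per anatomical region."""

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all masks must share one shape")
        total = None
        for label, mask in self.masks.items():
            if not mask.any():
                raise ValueError(f"region {label!r} mask is empty")
            if total is None:
                total = mask.copy()
            else:
                if (total & mask).any():
                    raise ValueError("region masks must be disjoint")
                total |= mask
        if "SUB" in self.masks:
            sub_area = int(self.masks["SUB"].sum())
            for label, mask in self.masks.items():
                if label != "SUB" and int(mask.sum()) <= sub_area:
                    raise ValueError("SUB must be the smallest region")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.masks.values())).shape

    def __getitem__(self, label: str) -> np.ndarray:
        return self.masks[label]

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def __len__(self) -> int:
        return len(self.masks)

    def labels(self) -> tuple[str, ...]:
        return tuple(self.masks)

    def area(self, label: str) -> int:
        return int(self.masks[label].sum())

    def labeled(self) -> np.ndarray:
        """Integer label image: 0 background, 1.. in mask order."""
        out = np.zeros(self.shape, dtype=np.uint8)
        for i, mask in enumerate(self.masks.values(), start=1):
            out[mask] = i
        return out


def _fill_polygon(vertices, shape) -> np.ndarray:
    rows, cols = shape
    cc, rr = np.meshgrid(np.arange(cols) + 0.5, np.arange(rows) + 0.5)
    pts = np.column_stack([cc.ravel(), rr.ravel()])
    inside = Path(vertices).contains_points(pts)
    return inside.reshape(shape)


def build_region_masks(shape: tuple[int, int] = FRAME_SHAPE) -> RegionMaskSet:
    """Draw the four region sectors, scaled to ``shape`` if non-default."""
    sr = shape[0] / FRAME_SHAPE[0]
    sc = shape[1] / FRAME_SHAPE[1]
    masks: dict[str, np.ndarray] = {}
    claimed = np.zeros(shape, dtype=bool)
    for label in REGIONS:  # SUB first so the small sector keeps its pixels
        verts = [(c * sc, r * sr) for c, r in _POLYGONS[label]]
        mask = _fill_polygon(verts, shape) & ~claimed
        claimed |= mask
        masks[label] = mask
    return RegionMaskSet(masks=masks)
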