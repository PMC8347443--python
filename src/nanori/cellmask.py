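"""Delimit one cell from the surrounding medium.

The delimitation threshold sits between the medium RI (~1.333) and the
lowest cellular RI (~1.365), so a global threshold followed by light
morphology recovers the cell body.  Voxel counting is by raw counts, not
physical volume: anisotropy is deliberately ignored so every downstream
"% of pixels" statistic shares the same denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from nanori.stack_io import RIStack

__all__ = ["CellMask", "EmptySegmentationError", "segment_cell", "mask_fraction"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class EmptySegmentationError(ValueError):
    """No voxel survived segmentation."""


@dataclass
class CellMask:
    """A single-cell boolean voxel mask (one 26-connected component)."""

    mask: np.ndarray
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.mask.any():
            raise EmptySegmentationError(f"cell {self.cell_id}: mask is empty")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def segment_cell(
    stack: RIStack,
    ri_threshold: float = 1.36,
    closing_radius_vox: int = 2,
    min_volume_vox: int = 64,
    cell_id: str = "cell",
) -> CellMask:
    """Threshold, close, fill holes, and keep the largest 26-connected component.

    Raises
    ------
    EmptySegmentationError
        If no voxel exceeds ``ri_threshold`` or the largest component is
        smaller than ``min_volume_vox``.
    """
    raw = stack.voxels > ri_threshold
    if not raw.any():
        raise EmptySegmentationError(
            f"cell {cell_id}: no voxel above RI threshold {ri_threshold}"
        )
    if closing_radius_vox > 0:
        closed = ndimage.binary_closing(
            raw, structure=_ball(closing_radius_vox), border_value=0
        )
    else:
        closed = raw
    filled = ndimage.binary_fill_holes(closed)
    labels, n = ndimage.label(filled, structure=_CONN26)
    if n == 0:
        raise EmptySegmentationError(f"cell {cell_id}: nothing labeled")
    sizes = ndimage.sum_labels(filled, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_volume_vox:
        raise EmptySegmentationError(
            f"cell {cell_id}: largest component has {int(sizes[best - 1])} voxels "
            f"(< min_volume_vox={min_volume_vox})"
        )
    return CellMask(labels == best, cell_id=cell_id)


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    z, y, x = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (z * z + y * y + x * x) <= r * r


def mask_fraction(sub: np.ndarray, mask: CellMask) -> float:
    """Fraction of the cell's voxels flagged by ``sub`` (in [0, 1])."""
    sub = np.asarray(sub, bool)
    if sub.shape != mask.mask.shape:
        raise ValueError(f"shape mismatch: {sub.shape} vs {mask.mask.shape}")
    denom = mask.voxel_count
    if denom == 0:  # unreachable through CellMask, guards raw use
        raise ZeroDivisionError("empty cell mask")
    return float(np.count_nonzero(sub & mask.mask)) / denom
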