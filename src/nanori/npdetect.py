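"""Localize nanoparticle candidates as a high-RI band and estimate uptake.

Voxels whose RI lies in the band (endpoints inclusive) are flagged, grouped
into 26-connected components, and counted; the percentage of cell voxels in
the band is the per-cell uptake estimate.  Nuclear voxels above the band
floor (chromatin) are *not* excluded here — disambiguation belongs to the
fluorescence co-localization stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from nanori.cellmask import CellMask, mask_fraction
from nanori.stack_io import RIStack

__all__ = [
    "DetectionParams",
    "Component",
    "DetectionResult",
    "detect_band",
    "render_overlay",
    "uptake_by_dose",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class DetectionParams:
    band_lo: float = 1.39
    band_hi: float = 1.41
    min_component_vox: int = 5
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.band_lo >= self.band_hi:
            raise ValueError("band_lo must be < band_hi")
        if self.connectivity != 26:
            raise ValueError("only 26-connectivity is supported")


@dataclass(frozen=True)
class Component:
    id: int
    voxel_count: int
    centroid: tuple[float, float, float]  # (z, y, x)


@dataclass
class DetectionResult:
    """Band mask, connected accumulations and the pixel-count uptake estimate.

    ``band_voxels`` counts every in-band voxel; ``components`` lists only
    groups of at least ``min_component_vox`` voxels.  ``labels`` is the
    26-connected label volume (0 outside, component ids elsewhere) retained
    for downstream per-component classification.
    """

    band_mask: np.ndarray
    band_voxels: int
    band_percent: float
    components: list[Component]
    labels: np.ndarray = field(repr=False, default=None)


def detect_band(
    stack: RIStack, mask: CellMask, params: DetectionParams = DetectionParams()
) -> DetectionResult:
    """Flag in-cell voxels with ``band_lo <= RI <= band_hi`` and group them."""
    v = stack.voxels
    band = (v >= params.band_lo) & (v <= params.band_hi) & mask.mask
    band_voxels = int(band.sum())
    band_percent = 100.0 * mask_fraction(band, mask)
    labels, n = ndimage.label(band, structure=_CONN26)
    components: list[Component] = []
    if n:
        sizes = ndimage.sum_labels(band, labels, index=np.arange(1, n + 1)).astype(int)
        keep = np.nonzero(sizes >= params.min_component_vox)[0] + 1
        if keep.size:
            centroids = ndimage.center_of_mass(band, labels, index=keep)
            for cid, cent in zip(keep, centroids):
                components.append(
                    Component(int(cid), int(sizes[cid - 1]), tuple(float(c) for c in cent))
                )
    return DetectionResult(band, band_voxels, band_percent, components, labels)


def render_overlay(
    stack: RIStack, band_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Grayscale RI volume with band voxels painted pure red.

    Returns ``(rgb_volume, rgb_projection)``: the volume is (nz, ny, nx, 3)
    float in [0, 1]; the projection is the maximum-intensity projection
    along z with red wherever any voxel in the column is in the band.
    """
    band_mask = np.asarray(band_mask, bool)
    if band_mask.shape != stack.voxels.shape:
        raise ValueError("band mask shape does not match stack")
    v = stack.voxels.astype(np.float64)
    lo, hi = float(v.min()), float(v.max())
    gray = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    rgb = np.repeat(gray[..., np.newaxis], 3, axis=-1)
    rgb[band_mask] = (1.0, 0.0, 0.0)
    mip = np.repeat(gray.max(axis=0)[..., np.newaxis], 3, axis=-1)
    mip[band_mask.any(axis=0)] = (1.0, 0.0, 0.0)
    return rgb, mip


def uptake_by_dose(records) -> pd.DataFrame:
    """Per-dose mean ± SEM of band_percent, ordered by dose.

    ``records`` is an iterable of mappings (or a DataFrame) with at least
    ``dose`` and ``band_percent`` columns; every dose needs >= 2 cells for
    the SEM to exist.
    """
    df = pd.DataFrame(records)
    if df.empty or not {"dose", "band_percent"} <= set(df.columns):
        raise ValueError("records need 'dose' and 'band_percent' fields")
    counts = df.groupby("dose")["band_percent"].count()
    singles = counts[counts < 2]
    if not singles.empty:
        raise ValueError(
            f"SEM undefined for singleton dose group(s): {list(singles.index)}"
        )
    out = (
        df.groupby("dose")["band_percent"]
        .agg(mean_band_percent="mean", sem_band_percent="sem", n="count")
        .reset_index()
        .sort_values("dose", ignore_index=True)
    )
    return out
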