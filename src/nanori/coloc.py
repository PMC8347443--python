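"""Fluorescence co-localization and per-condition group statistics.

The high-RI band localizes nanoparticle *candidates*; the fluorescence
channel arbitrates.  Candidate components that overlap fluorescence-positive
voxels are particles, components without fluorescence (nuclear chromatin)
are not.  Group comparisons follow the study design: pooled-variance t-tests
against control, one-way ANOVA, then Fisher's protected LSD on the pooled
error term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu

from nanori.cellmask import CellMask
from nanori.npdetect import Component, DetectionResult
from nanori.stack_io import FluorStack

__all__ = [
    "CoLocStats",
    "GroupStats",
    "DegenerateThresholdError",
    "binarize_fluorescence",
    "coloc_stats",
    "classify_components",
    "per_cell_fluorescence",
    "group_compare",
]


class DegenerateThresholdError(ValueError):
    """In-mask intensities are constant; no threshold separates them."""


@dataclass(frozen=True)
class CoLocStats:
    """Overlap between the RI band mask and the fluorescence-positive mask."""

    m1: float  # fraction of band voxels that are fluorescence-positive
    dice: float  # 2|A∩B| / (|A| + |B|)
    n_band: int
    n_fluor: int


@dataclass
class GroupStats:
    """Per-dose summary plus pairwise and omnibus tests.

    ``table`` has one row per dose (mean, SEM, n).  ``ttest_vs_control``
    maps dose -> two-sided pooled-variance t-test p-value against the lowest
    dose; ``plsd`` maps (dose_a, dose_b) -> Fisher-PLSD p-value using the
    ANOVA mean square error.
    """

    table: pd.DataFrame
    ttest_vs_control: dict[float, float]
    anova_f: float
    anova_p: float
    plsd: dict[tuple[float, float], float]


def binarize_fluorescence(
    fl: FluorStack, mask: CellMask, min_separability: float = 0.8
) -> np.ndarray:
    """Otsu-threshold the in-mask intensities; returns the positive mask.

    Otsu always returns *some* threshold, even for a background-only cell
    whose histogram is a single Gaussian mode (where it would flag half the
    voxels).  The split is therefore accepted only when the normalized
    between-class variance — Otsu's own criterion, 1 for perfectly separated
    classes, ~0.64 for a pure Gaussian — reaches ``min_separability``;
    otherwise no voxel is fluorescence-positive.
    """
    if fl.voxels.shape != mask.mask.shape:
        raise ValueError("fluorescence grid does not match mask grid")
    inside = fl.voxels[mask.mask]
    if inside.size == 0:
        raise ValueError("empty cell mask")
    if np.ptp(inside) == 0:
        raise DegenerateThresholdError(
            "constant in-mask fluorescence; Otsu threshold undefined"
        )
    thr = threshold_otsu(inside)
    hi = inside > thr
    w1 = hi.mean()
    total_var = inside.var()
    if 0 < w1 < 1 and total_var > 0:
        between = w1 * (1 - w1) * (inside[hi].mean() - inside[~hi].mean()) ** 2
        if between / total_var < min_separability:
            return np.zeros_like(mask.mask)
    return (fl.voxels > thr) & mask.mask


def coloc_stats(band_mask: np.ndarray, fluor_mask: np.ndarray) -> CoLocStats:
    """Manders M1 and Dice by voxel counting; both 0 for an empty band."""
    a = np.asarray(band_mask, bool)
    b = np.asarray(fluor_mask, bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    n_a = int(a.sum())
    n_b = int(b.sum())
    inter = int((a & b).sum())
    m1 = inter / n_a if n_a else 0.0
    dice = 2.0 * inter / (n_a + n_b) if (n_a + n_b) else 0.0
    return CoLocStats(m1=m1, dice=dice, n_band=n_a, n_fluor=n_b)


def classify_components(
    detection: DetectionResult | Sequence[Component],
    fluor_mask: np.ndarray,
    min_overlap: float = 0.5,
    labels: np.ndarray | None = None,
) -> dict[int, str]:
    """Label each band component ``"NP"`` or ``"non-NP"``.

    A component is a nanoparticle accumulation iff the fraction of its
    voxels that are fluorescence-positive is >= ``min_overlap`` (boundary
    inclusive).  Accepts a :class:`DetectionResult` (which carries the label
    volume) or a component list plus an explicit ``labels`` array.
    """
    if isinstance(detection, DetectionResult):
        components = detection.components
        labels = detection.labels
    else:
        components = list(detection)
    if labels is None:
        raise ValueError("a label volume is required to classify components")
    fluor_mask = np.asarray(fluor_mask, bool)
    out: dict[int, str] = {}
    for comp in components:
        votes = int((fluor_mask & (labels == comp.id)).sum())
        frac = votes / comp.voxel_count
        out[comp.id] = "NP" if frac >= min_overlap else "non-NP"
    return out


def per_cell_fluorescence(fl: FluorStack, mask: CellMask) -> float:
    """Arithmetic mean intensity (AU) over the in-mask voxels."""
    if fl.voxels.shape != mask.mask.shape:
        raise ValueError("fluorescence grid does not match mask grid")
    inside = fl.voxels[mask.mask]
    if inside.size == 0:
        raise ValueError("empty cell mask")
    return float(inside.mean())


def group_compare(values_by_dose: Mapping[float, Sequence[float]]) -> GroupStats:
    """Compare per-cell values across dose groups.

    The lowest dose is the control.  Pairwise t-tests against control use
    pooled variance; Fisher PLSD uses the ANOVA pooled mean square error
    with N - k degrees of freedom, so with exactly two groups it reduces to
    the pooled t-test.
    """
    groups = {float(d): np.asarray(v, float) for d, v in values_by_dose.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 dose groups")
    for d, v in groups.items():
        if v.size < 2:
            raise ValueError(f"dose group {d} has fewer than 2 values")
    if all(np.ptp(v) == 0 for v in groups.values()):
        raise ValueError("zero within-group variance in every group; tests degenerate")

    doses = sorted(groups)
    control = doses[0]
    table = pd.DataFrame(
        {
            "dose": doses,
            "mean": [groups[d].mean() for d in doses],
            "sem": [stats.sem(groups[d], ddof=1) for d in doses],
            "n": [groups[d].size for d in doses],
        }
    )

    ttest = {
        d: float(stats.ttest_ind(groups[d], groups[control], equal_var=True).pvalue)
        for d in doses[1:]
    }

    f_stat, f_p = stats.f_oneway(*(groups[d] for d in doses))

    # Fisher PLSD: pooled MSE over all groups, df = N - k
    n_tot = sum(v.size for v in groups.values())
    k = len(groups)
    mse = sum((v.size - 1) * v.var(ddof=1) for v in groups.values()) / (n_tot - k)
    plsd: dict[tuple[float, float], float] = {}
    for i, a in enumerate(doses):
        for b in doses[i + 1 :]:
            va, vb = groups[a], groups[b]
            se = np.sqrt(mse * (1.0 / va.size + 1.0 / vb.size))
            t = (va.mean() - vb.mean()) / se
            plsd[(a, b)] = float(2.0 * stats.t.sf(abs(t), n_tot - k))

    return GroupStats(
        table=table,
        ttest_vs_control=ttest,
        anova_f=float(f_stat),
        anova_p=float(f_p),
        plsd=plsd,
    )
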