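"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive (loops, recursion, closed forms) and share no
code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def brute_histogram_percent(values, bin_width: float, anchor: float) -> dict[float, float]:
    """Tally values into half-open bins [lo, lo+w) one value at a time.

    Follows the package's stated binning convention, including the 1e-4
    bin-width guard that snaps float32 quantization error at bin edges.
    """
    counts: dict[int, int] = {}
    values = list(np.asarray(values, dtype=np.float64).ravel())
    for v in values:
        k = math.floor((v - anchor) / bin_width + 1e-4)
        counts[k] = counts.get(k, 0) + 1
    n = len(values)
    return {anchor + k * bin_width: 100.0 * c / n for k, c in counts.items()}


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int, int]]]:
    """26-connected components by explicit stack-based flood fill."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps: list[set[tuple[int, int, int]]] = []
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    nz, ny, nx = mask.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        stack = [tuple(int(i) for i in start)]
        seen[start] = True
        while stack:
            z, y, x = stack.pop()
            comp.add((z, y, x))
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if 0 <= p[0] < nz and 0 <= p[1] < ny and 0 <= p[2] < nx:
                    if mask[p] and not seen[p]:
                        seen[p] = True
                        stack.append(p)
        comps.append(comp)
    return comps


def pooled_ttest(a, b) -> tuple[float, float]:
    """Two-sided two-sample pooled-variance t-test from the closed form."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * tdist.sf(abs(t), na + nb - 2)
    return t, p
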