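"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with psmavol: pure-Python flood fill for
connected components, naive per-event-time log-rank via lifelines, and an
exhaustive cutoff search.
"""

from __future__ import annotations

import numpy as np
from lifelines.statistics import logrank_test

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int, int]]]:
    """All 26-connected components of a boolean volume, by BFS."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    shape = mask.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        stack = [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for d in NEIGHBORS_26:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[i] < shape[i] for i in range(3)) and mask[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(comp)
    return comps


def brute_force_refine(values: np.ndarray, focus_voxels: set) -> set:
    """50%-of-local-max rule by brute force: find the hottest focus voxel,
    threshold the whole volume at half its value (inclusive), flood-fill
    the component containing that voxel."""
    peak_vox = max(focus_voxels, key=lambda v: values[v])
    half = 0.5 * values[peak_vox]
    for comp in flood_fill_components(values >= half):
        if peak_vox in comp:
            return comp
    raise AssertionError("peak voxel not in its own isocontour")


def logrank_abs_z(t, e, high) -> float:
    """|standardized log-rank| via lifelines' chi-square (independent path)."""
    res = logrank_test(t[high], t[~high], e[high], e[~high])
    return float(np.sqrt(res.test_statistic))


def exhaustive_maxstat(t, e, x, min_prop=0.1):
    """Exhaustive scan of admissible midpoints using the lifelines log-rank."""
    t, e, x = np.asarray(t, float), np.asarray(e, bool), np.asarray(x, float)
    n = x.size
    distinct = np.sort(np.unique(x))
    best_cut, best_stat = None, -1.0
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cut = 0.5 * (lo + hi)
        high = x > cut
        nh = high.sum()
        if nh < min_prop * n or (n - nh) < min_prop * n:
            continue
        z = logrank_abs_z(t, e, high)
        if z > best_stat + 1e-12:
            best_stat, best_cut = z, cut
    return best_cut, best_stat
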