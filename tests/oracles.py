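"""Independent brute-force oracles used by the test suite.

Each function re-derives an expected result by the most direct method
available (exhaustive loops, closed forms, step-through simulation),
deliberately sharing no code with the library implementations it checks.
"""

from __future__ import annotations

import numpy as np


def brute_voxel_counts(points: np.ndarray, voxel: float, anchor) -> int:
    """Number of occupied voxels by direct dict binning."""
    seen = set()
    for p in points:
        key = tuple(int(np.floor((c - a) / voxel)) for c, a in zip(p, anchor))
        seen.add(key)
    return len(seen)


def brute_outlier_mask(points: np.ndarray, k: int, std_ratio: float) -> np.ndarray:
    """O(N²) statistical-outlier survival mask."""
    n = len(points)
    mean_d = np.empty(n)
    for i in range(n):
        d = np.sort(np.linalg.norm(points - points[i], axis=1))
        mean_d[i] = d[1:k + 1].mean()
    thresh = mean_d.mean() + std_ratio * mean_d.std()
    return mean_d <= thresh


def brute_pairwise_diameter_xy(points: np.ndarray) -> float:
    """O(N²) maximum pairwise distance of the xy projection."""
    uv = points[:, :2]
    best = 0.0
    for i in range(len(uv)):
        d = np.linalg.norm(uv[i + 1:] - uv[i], axis=1)
        if len(d):
            best = max(best, d.max())
    return best


def delaunay_hull_volume(points: np.ndarray) -> float:
    """Hull volume as the summed volume of the Delaunay tetrahedra
    (independent of Qhull's own volume accumulation path)."""
    from scipy.spatial import Delaunay

    tri = Delaunay(points)
    vol = 0.0
    for simplex in tri.simplices:
        a, b, c, d = points[simplex]
        vol += abs(np.linalg.det(np.column_stack([b - a, c - a, d - a]))) / 6.0
    return vol


def brute_m3c2(ref: np.ndarray, cmp_: np.ndarray, core: np.ndarray,
               normal_scale: float, proj_radius: float, max_depth: float,
               min_points: int):
    """Direct per-core-point M3C2 with explicit loops.

    Returns (distances, valid); distances NaN where invalid.
    """
    n = len(core)
    out = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        p = core[i]
        d_ref = np.linalg.norm(ref - p, axis=1)
        nb = ref[d_ref <= normal_scale / 2.0]
        if len(nb) < 3:
            continue
        centered = nb - nb.mean(axis=0)
        _, vecs = np.linalg.eigh(centered.T @ centered)
        nrm = vecs[:, 0]
        if nrm[2] < 0:
            nrm = -nrm
        means = []
        ok = True
        for cloud in (ref, cmp_):
            rel = cloud - p
            axial = rel @ nrm
            radial2 = (rel ** 2).sum(axis=1) - axial ** 2
            inside = (np.abs(axial) <= max_depth) & (radial2 <= proj_radius ** 2 + 1e-12)
            if inside.sum() < min_points:
                ok = False
                break
            means.append(axial[inside].mean())
        if ok:
            out[i] = means[1] - means[0]
            valid[i] = True
    return out, valid


def step_through_blade_base(widths, factor: float, warmup: int,
                            trim_fraction: float = 0.5):
    """Hand simulation of the width-jump trigger.

    Sorts the widths seen so far, keeps the central ``trim_fraction``
    (inclusive bounds at the quartile indices, matching a trimmed mean),
    averages them, and fires at the first post-warm-up segment whose
    width exceeds ``factor`` × that average. Returns the segment index or
    None.
    """
    for i in range(warmup, len(widths)):
        seen = sorted(widths[:i])
        cut = int(np.floor(len(seen) * (1.0 - trim_fraction) / 2.0))
        central = seen[cut:len(seen) - cut] if len(seen) > 2 * cut else seen
        baseline = float(np.mean(central))
        if widths[i] > factor * baseline:
            return i
    return None


def numeric_arc_length(fn, a: float, b: float, n: int = 20001) -> float:
    """Arc length of y ↦ fn(y) over [a, b] by fine trapezoid quadrature."""
    y = np.linspace(a, b, n)
    z = fn(y)
    return float(np.sum(np.hypot(np.diff(y), np.diff(z))))
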