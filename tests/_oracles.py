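"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: face counts by
explicit neighbor loops, angle sums by a plain triad loop on math-module
trig, rank-test p-values by explicit permutation/enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_face_count(mask: np.ndarray) -> int:
    """Count exposed voxel faces by looping every voxel and its 6 neighbors."""
    mask = np.asarray(mask, dtype=bool)
    faces = 0
    shape = mask.shape
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if not mask[i, j, k]:
                    continue
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    ni, nj, nk = i + di, j + dj, k + dk
                    if not (0 <= ni < shape[0] and 0 <= nj < shape[1]
                            and 0 <= nk < shape[2]) or not mask[ni, nj, nk]:
                        faces += 1
    return faces


def brute_force_angle_sum(points, n_angles: int) -> float:
    """Sum the first ``n_angles`` interior turning angles by a plain triad loop."""
    pts = [tuple(map(float, p)) for p in points]
    total = 0.0
    for k in range(1, n_angles + 1):
        ax = tuple(pts[k][i] - pts[k - 1][i] for i in range(3))
        bx = tuple(pts[k + 1][i] - pts[k][i] for i in range(3))
        na = math.sqrt(sum(c * c for c in ax))
        nb = math.sqrt(sum(c * c for c in bx))
        if na <= 1e-12 or nb <= 1e-12:
            continue
        c = sum(a * b for a, b in zip(ax, bx)) / (na * nb)
        total += math.acos(max(-1.0, min(1.0, c)))
    return total


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def kw_statistic(groups) -> float:
    """Kruskal-Wallis H from the rank formula with tie correction."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(pooled)
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for sz in sizes:
        r = ranks[start : start + sz]
        h += r.sum() ** 2 / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie_corr if tie_corr > 0 else 0.0


def kw_permutation_p(groups, n_perm: int, rng: np.random.Generator) -> float:
    """Permutation p-value of the Kruskal-Wallis statistic."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    observed = kw_statistic(groups)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts, start = [], 0
        for sz in sizes:
            parts.append(perm[start : start + sz])
            start += sz
        if kw_statistic(parts) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def mww_u_statistic(a, b) -> float:
    """U of sample a: number of (a_i, b_j) pairs with a_i > b_j (+0.5 per tie)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mww_enumeration_p(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all group labelings."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n = len(pooled)
    m = len(a)
    u_obs = mww_u_statistic(a, b)
    us = []
    for idx in itertools.combinations(range(n), m):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        us.append(mww_u_statistic(ga, gb))
    us = np.asarray(us)
    total = len(us)
    p_le = np.count_nonzero(us <= u_obs + 1e-12) / total
    p_ge = np.count_nonzero(us >= u_obs - 1e-12) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def sample_arc_path(radius: float, d_theta_deg: float, sweep_deg: float = 90.0):
    """Ordered points on a circular arc, the analytic total-curvature fixture."""
    thetas = np.deg2rad(np.arange(0.0, sweep_deg + 1e-9, d_theta_deg))
    return np.column_stack(
        [radius * np.cos(thetas), radius * np.sin(thetas), np.zeros_like(thetas)]
    )
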