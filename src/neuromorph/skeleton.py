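"""Centerline skeletonization and path decomposition.

A binary mask is thinned to a one-voxel-wide medial skeleton (Lee's 3D
topology-preserving thinning), turned into a 26-connectivity graph over the
skeleton voxel centers (physical mm), and decomposed into maximal simple
paths terminating at endpoints (degree 1) or junctions (degree >= 3). The
ordered point sequences feed the sum-of-angles tortuosity estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _skimage_skeletonize

from .volumes import BinaryMask

logger = logging.getLogger(__name__)

__all__ = [
    "SkeletonGraph",
    "SkeletonPath",
    "skeletonize",
    "extract_paths",
    "path_length",
    "smooth_path",
    "filter_small_components",
]


@dataclass
class SkeletonGraph:
    """Skeleton voxels as a graph: nodes are voxel centers in mm, edges 26-adjacency."""

    graph: nx.Graph
    spacing: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_points(self) -> np.ndarray:
        """(n, 3) array of node coordinates in physical mm."""
        if self.n_nodes == 0:
            return np.empty((0, 3))
        return np.array([self.graph.nodes[v]["point"] for v in self.graph.nodes])


@dataclass
class SkeletonPath:
    """Ordered point sequence P_0..P_{N-1} in physical mm.

    ``angle_eligible`` marks whether the path is long enough to contribute
    turning angles (N >= min_points); short paths still contribute length.
    """

    points: np.ndarray
    angle_eligible: bool = True
    path_id: int = field(default=0)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {pts.shape}")
        if pts.shape[0] < 1:
            raise ValueError("path must contain at least one point")
        if pts.shape[0] > 1:
            steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            if np.any(steps == 0):
                raise ValueError("consecutive path points must be distinct")
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def filter_small_components(mask: BinaryMask, min_voxels: int = 27) -> BinaryMask:
    """Drop 26-connected components below ``min_voxels`` (isolated-dot removal)."""
    if min_voxels <= 1:
        return mask
    structure = np.ones((3, 3, 3), dtype=bool)
    labeled, n = ndimage.label(mask.data, structure=structure)
    if n == 0:
        return mask
    counts = np.bincount(labeled.ravel())
    keep = np.flatnonzero(counts >= min_voxels)
    keep = keep[keep != 0]
    if len(keep) < n:
        logger.info(
            "filter_small_components: removed %d of %d components below %d voxels",
            n - len(keep), n, min_voxels,
        )
    return BinaryMask(np.isin(labeled, keep), mask.spacing.copy(), mask.affine.copy())


def skeletonize(mask: BinaryMask) -> SkeletonGraph:
    """Medial-axis thinning of a mask into a 26-connected skeleton graph.

    Skeleton voxels are a subset of the mask; nodes carry their physical
    center coordinate (index * spacing) as attribute ``point``.
    """
    if mask.count == 0:
        raise ValueError("cannot skeletonize an empty mask")
    if mask.count == 1:
        skel = mask.data
    else:
        skel = _skimage_skeletonize(mask.data).astype(bool)
        if not skel.any():
            # Thinning can annihilate tiny blobs; keep one representative voxel.
            idx = np.argwhere(mask.data)[0]
            skel = np.zeros_like(mask.data)
            skel[tuple(idx)] = True
    skel &= mask.data  # subset guarantee

    voxels = np.argwhere(skel)
    g = nx.Graph()
    spacing = mask.spacing
    index_of = {}
    for i, v in enumerate(map(tuple, voxels)):
        g.add_node(v, point=np.asarray(v, dtype=float) * spacing)
        index_of[v] = i
    offsets = [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) > (0, 0, 0)  # half the 26-neighborhood, no double edges
    ]
    vox_set = set(map(tuple, voxels))
    for v in vox_set:
        for off in offsets:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if w in vox_set:
                g.add_edge(v, w)
    return SkeletonGraph(graph=g, spacing=np.asarray(spacing, dtype=float))


def _walk(g: nx.Graph, start, first, visited_edges) -> list:
    """Follow a degree-2 chain from ``start`` through ``first`` until a terminal.

    Stops at a node of degree != 2, at an already-visited edge, or when the
    chain closes on itself (pure cycle).
    """
    chain = [start, first]
    local = {frozenset((start, first))}
    prev, cur = start, first
    while g.degree[cur] == 2:
        nxts = [w for w in g.neighbors(cur) if w != prev]
        if not nxts:
            break
        nxt = nxts[0]
        edge = frozenset((cur, nxt))
        if edge in visited_edges or edge in local:
            break
        chain.append(nxt)
        local.add(edge)
        prev, cur = cur, nxt
    return chain


def extract_paths(graph: SkeletonGraph, min_points: int = 4) -> list[SkeletonPath]:
    """Decompose a skeleton graph into maximal simple paths.

    Paths run terminal-to-terminal, where terminals are endpoints (degree 1),
    junctions (degree >= 3) and isolated nodes; every edge lands in exactly
    one path. Pure cycles are emitted as one closed path. Paths shorter than
    ``min_points`` are kept but flagged angle-ineligible.
    """
    g = graph.graph
    paths: list[SkeletonPath] = []
    visited_edges: set[frozenset] = set()
    pid = 0

    terminals = [v for v in g.nodes if g.degree[v] != 2]
    for t in terminals:
        if g.degree[t] == 0:
            paths.append(
                SkeletonPath(
                    np.asarray([g.nodes[t]["point"]]), angle_eligible=False, path_id=pid
                )
            )
            pid += 1
            continue
        for nb in g.neighbors(t):
            edge = frozenset((t, nb))
            if edge in visited_edges:
                continue
            chain = _walk(g, t, nb, visited_edges)
            for a, b in zip(chain[:-1], chain[1:]):
                visited_edges.add(frozenset((a, b)))
            pts = np.asarray([g.nodes[v]["point"] for v in chain])
            paths.append(
                SkeletonPath(pts, angle_eligible=len(chain) >= min_points, path_id=pid)
            )
            pid += 1

    # Remaining components are pure cycles (all degree 2).
    for v in g.nodes:
        if g.degree[v] != 2:
            continue
        unvisited = [w for w in g.neighbors(v) if frozenset((v, w)) not in visited_edges]
        if len(unvisited) < 2:
            continue
        chain = _walk(g, v, unvisited[0], visited_edges)  # closes on itself
        for a, b in zip(chain[:-1], chain[1:]):
            visited_edges.add(frozenset((a, b)))
        pts = np.asarray([g.nodes[w]["point"] for w in chain])
        paths.append(
            SkeletonPath(pts, angle_eligible=len(chain) >= min_points, path_id=pid)
        )
        pid += 1

    return paths


def path_length(path: SkeletonPath) -> float:
    """Arc length: sum of consecutive Euclidean distances |P_k - P_{k-1}| in mm."""
    if path.n_points < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(path.points, axis=0), axis=1).sum())


def smooth_path(path: SkeletonPath, window: int = 1) -> SkeletonPath:
    """Centered moving average of path coordinates; endpoints kept exactly.

    Near the ends the window shrinks symmetrically so it stays centered.
    ``window=1`` is the identity. Voxel skeletons are stair-stepped, so a
    small window tempers quantization angles; the default applies none.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window == 1 or path.n_points <= 2:
        return SkeletonPath(path.points.copy(), path.angle_eligible, path.path_id)
    pts = path.points
    n = path.n_points
    half = window // 2
    out = pts.copy()
    for i in range(1, n - 1):
        h = min(half, i, n - 1 - i)
        out[i] = pts[i - h : i + h + 1].mean(axis=0)
    # Averaging can collapse consecutive duplicates on degenerate zig-zags;
    # nudge them apart is wrong — instead drop exact duplicates.
    keep = np.ones(n, dtype=bool)
    for i in range(1, n):
        if np.array_equal(out[i], out[i - 1]):
            keep[i] = False
    return SkeletonPath(out[keep], path.angle_eligible, path.path_id)


def paths_to_csv(paths: list[SkeletonPath], path) -> None:
    """Write paths as CSV rows (path_id, k, x_mm, y_mm, z_mm) for inspection."""
    import pandas as pd

    rows = []
    for p in paths:
        for k, (x, y, z) in enumerate(p.points):
            rows.append((p.path_id, k, x, y, z))
    pd.DataFrame(rows, columns=["path_id", "k", "x_mm", "y_mm", "z_mm"]).to_csv(
        path, index=False
    )
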