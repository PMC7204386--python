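"""Per-structure morphometric biomarkers.

Four image-derived biomarkers per brain structure:

* **V** — physical volume, voxel count n times the voxel volume (mm^3).
* **NV** — volume normalized by intracranial volume, n / ICV in [0, 1].
* **DC** — discrete compactness, (n - A/6) / (n - n^(2/3)), where A is the
  exposed-face count of the voxel set under 6-connectivity. DC is 1 for a
  solid cube (maximal inter-voxel contact) and 0 for face-disconnected
  scatter (no contact), and is invariant to translation and lattice
  rotations.
* **TR** — sum-of-angles tortuosity of the centerline skeleton: the total
  in-plane turning angle along the ordered skeleton paths divided by total
  skeleton length, in radians per mm. Torsion is deliberately excluded,
  so the per-point total angle reduces to the plane angle.

All metrics are computed on an isotropic lattice (resample first).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .skeleton import (
    SkeletonPath,
    extract_paths,
    filter_small_components,
    path_length,
    skeletonize,
    smooth_path,
)
from .volumes import BinaryMask

logger = logging.getLogger(__name__)

__all__ = [
    "StructureMetrics",
    "MetricsConfig",
    "voxel_count",
    "normalized_volume",
    "exposed_face_area",
    "discrete_compactness",
    "plane_angle",
    "soam_tortuosity",
    "structure_metrics",
]

STRUCTURES = ("GM", "WM", "RTL", "LTL", "RPL", "LPL")
IMAGE_METRICS = ("V", "NV", "DC", "CT", "TR")


@dataclass
class MetricsConfig:
    """Knobs for structure-level metric extraction.

    smoothing_window : odd int, default 1 (off)
        Moving-average window applied to skeleton paths before angle
        computation; 1 applies the published formula to raw skeletons.
    min_component_voxels : int, default 27
        Connected components smaller than this are dropped before
        skeletonization (isolated-dot removal).
    min_path_points : int, default 4
        Paths shorter than this contribute length but no angles, honoring
        the k = 1..N-3 summation window.
    all_interior_angles : bool, default False
        If True, sum all N-2 interior angles per path instead of the
        first N-3 (sensitivity variant).
    """

    smoothing_window: int = 1
    min_component_voxels: int = 27
    min_path_points: int = 4
    all_interior_angles: bool = False

    def provenance(self) -> dict:
        return {
            "smoothing_window": self.smoothing_window,
            "min_component_voxels": self.min_component_voxels,
            "min_path_points": self.min_path_points,
            "all_interior_angles": self.all_interior_angles,
        }


@dataclass
class StructureMetrics:
    """All biomarkers for one structure (or phantom)."""

    structure: str
    n: int
    V: float  # mm^3
    NV: float
    A: int  # exposed faces
    DC: float
    TR: float  # rad/mm
    angle_sum: float  # rad
    skel_length: float  # mm
    provenance: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "structure": self.structure,
            "n": self.n,
            "V_mm3": self.V,
            "NV": self.NV,
            "A_faces": self.A,
            "DC": self.DC,
            "TR_rad_per_mm": self.TR,
            "angle_sum": self.angle_sum,
            "skel_length_mm": self.skel_length,
        }


def voxel_count(mask: BinaryMask) -> int:
    """Number of foreground voxels n; V = n * voxel volume."""
    return mask.count


def normalized_volume(n: int, icv: int) -> float:
    """NV = n / ICV. ICV must be positive; n > ICV warns (inconsistent masks)."""
    if icv <= 0:
        raise ValueError(f"intracranial volume must be > 0, got {icv}")
    if n > icv:
        warnings.warn(
            f"structure voxel count {n} exceeds intracranial volume {icv}",
            stacklevel=2,
        )
    return n / icv


def exposed_face_area(mask: BinaryMask) -> int:
    """Exposed-face count A of the voxel set under 6-connectivity.

    A voxel contributes one face per 6-neighbor that is background (or
    outside the lattice): A = 6n - 2 * (face-adjacent foreground pairs).
    Requires isotropic spacing so faces are congruent squares.
    """
    if not mask.is_isotropic:
        raise ValueError(
            f"exposed_face_area requires isotropic spacing, got {tuple(mask.spacing)}; "
            "resample to an isotropic grid first"
        )
    m = mask.data
    n = int(m.sum())
    pairs = 0
    for axis in range(3):
        a = np.moveaxis(m, axis, 0)
        pairs += int(np.count_nonzero(a[:-1] & a[1:]))
    return 6 * n - 2 * pairs


def discrete_compactness(n: int, A: int) -> float:
    """Discrete compactness DC = (n - A/6) / (n - n^(2/3)).

    The numerator counts contact faces (in units of 6-face voxels); the
    denominator is the contact count of the most compact arrangement (a
    solid cube), so DC is 0 for face-disconnected scatter and 1 for a solid
    cube. For n = 1 the formula is 0/0; a lone voxel has no contacts, so
    DC = 0 by convention.
    """
    if n < 1:
        raise ValueError(f"voxel count must be >= 1, got {n}")
    if A < 0:
        raise ValueError(f"face count must be >= 0, got {A}")
    if n == 1:
        logger.debug("discrete_compactness: n = 1, returning 0 by convention")
        return 0.0
    dc = (n - A / 6.0) / (n - n ** (2.0 / 3.0))
    if not (-1e-6 <= dc <= 1 + 1e-6):
        warnings.warn(
            f"discrete compactness {dc:.6g} outside [0, 1] (n={n}, A={A})",
            stacklevel=2,
        )
    return float(dc)


def plane_angle(p_prev, p, p_next) -> float:
    """In-plane turning angle at P between segments (P - P_prev) and (P_next - P).

    Returns the angle in radians in [0, pi]; 0 means collinear continuation.
    """
    t1 = np.asarray(p, dtype=float) - np.asarray(p_prev, dtype=float)
    t2 = np.asarray(p_next, dtype=float) - np.asarray(p, dtype=float)
    n1 = np.linalg.norm(t1)
    n2 = np.linalg.norm(t2)
    if n1 <= 1e-12 or n2 <= 1e-12:
        raise ValueError("plane_angle requires non-degenerate segments")
    c = float(np.dot(t1, t2) / (n1 * n2))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _path_angles(points: np.ndarray, all_interior: bool) -> float:
    """Sum of eligible plane angles along one ordered path.

    Eligible angles are the first N-3 interior angles (k = 1..N-3), or all
    N-2 interior ones when ``all_interior`` is set. Triads containing a
    zero-length segment are skipped.
    """
    n = points.shape[0]
    n_angles = n - 2 if all_interior else n - 3
    if n_angles <= 0:
        return 0.0
    total = 0.0
    for k in range(1, n_angles + 1):  # angle at interior point P_k
        try:
            total += plane_angle(points[k - 1], points[k], points[k + 1])
        except ValueError:
            continue  # degenerate triad skipped
    return total


def soam_tortuosity(
    paths: list[SkeletonPath], all_interior_angles: bool = False
) -> tuple[float, float, float]:
    """Sum-of-angles tortuosity over a set of skeleton paths.

    TR = (sum of plane angles over all angle-eligible paths) /
    (total arc length of all paths). Lengths of angle-ineligible (short)
    paths still enter the denominator, keeping TR the structure-level
    "total turning / total length" ratio. Returns (TR, angle_sum, length).
    """
    if not paths:
        raise ValueError("soam_tortuosity requires at least one path")
    total_len = sum(path_length(p) for p in paths)
    if total_len <= 0:
        raise ValueError("total skeleton length is zero; tortuosity undefined")
    angle_sum = sum(
        _path_angles(p.points, all_interior_angles) for p in paths if p.angle_eligible
    )
    return angle_sum / total_len, angle_sum, total_len


def structure_metrics(
    mask: BinaryMask,
    icv: int,
    config: MetricsConfig | None = None,
    structure: str = "structure",
) -> StructureMetrics:
    """Compute every biomarker for one structure mask.

    The mask must be non-empty and isotropic. Skeleton-based quantities are
    computed after removing components below the configured voxel threshold;
    if thinning leaves no measurable path length (blob-like structures at
    tiny scale), TR is reported as 0 with a warning.
    """
    if config is None:
        config = MetricsConfig()
    if mask.count == 0:
        raise ValueError(f"structure {structure!r}: mask is empty")
    n = voxel_count(mask)
    V = n * mask.voxel_volume_mm3
    NV = normalized_volume(n, icv)
    A = exposed_face_area(mask)
    DC = discrete_compactness(n, A)

    filtered = filter_small_components(mask, config.min_component_voxels)
    if filtered.count == 0:
        logger.warning(
            "structure %s: all components below %d voxels; skipping skeleton metrics",
            structure, config.min_component_voxels,
        )
        TR, angle_sum, skel_len = 0.0, 0.0, 0.0
    else:
        graph = skeletonize(filtered)
        paths = extract_paths(graph, min_points=config.min_path_points)
        if config.smoothing_window > 1:
            paths = [smooth_path(p, config.smoothing_window) for p in paths]
        try:
            TR, angle_sum, skel_len = soam_tortuosity(
                paths, config.all_interior_angles
            )
        except ValueError:
            logger.warning(
                "structure %s: zero-length skeleton, reporting TR = 0", structure
            )
            TR, angle_sum, skel_len = 0.0, 0.0, 0.0

    return StructureMetrics(
        structure=structure,
        n=n,
        V=V,
        NV=NV,
        A=A,
        DC=DC,
        TR=TR,
        angle_sum=angle_sum,
        skel_length=skel_len,
        provenance=config.provenance(),
    )
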