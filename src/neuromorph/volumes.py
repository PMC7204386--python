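"""Label volumes and binary masks on 3D voxel lattices.

Containers carry the voxel data together with the physical voxel spacing
(mm per axis) and the NIfTI affine, which is propagated untouched: all
morphometric math downstream works on spacing alone, so the metrics are
orientation-invariant by construction.

Conventions: voxel indices are 0-based; the physical coordinate of a voxel
is its center, ``index * spacing``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "LabelVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "extract_mask",
    "intracranial_volume",
]


def _validate_lattice(data: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"lattice must have 3 axes, got {data.ndim}")
    if min(data.shape) < 1:
        raise ValueError(f"every axis must have extent >= 1, got shape {data.shape}")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,):
        raise ValueError(f"spacing must have 3 components, got {spacing.shape}")
    if not np.all(spacing > 0):
        raise ValueError(f"all spacing components must be > 0, got {tuple(spacing)}")
    return data, spacing


@dataclass
class LabelVolume:
    """3D lattice of non-negative integer structure labels.

    Parameters
    ----------
    data : (I, J, K) ndarray of int
        Structure labels; 0 is background.
    spacing : (3,) array-like of float
        Physical voxel size in mm per axis.
    affine : (4, 4) ndarray, optional
        Voxel-to-world transform carried through unchanged. Defaults to a
        diagonal affine built from ``spacing``.
    """

    data: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        data, spacing = _validate_lattice(self.data, self.spacing)
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded, atol=1e-6):
                raise ValueError("label data has non-integer voxel values beyond tolerance")
            data = rounded.astype(np.int32)
        if data.min() < 0:
            raise ValueError("labels must be >= 0")
        self.data = data.astype(np.int32, copy=False)
        self.spacing = spacing
        if self.affine is None:
            self.affine = np.diag([*spacing, 1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels(self) -> np.ndarray:
        """Sorted unique labels present in the volume."""
        return np.unique(self.data)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class BinaryMask:
    """3D boolean lattice with physical spacing; one structure's voxel set."""

    data: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        data, spacing = _validate_lattice(self.data, self.spacing)
        self.data = data.astype(bool)
        self.spacing = spacing
        if self.affine is None:
            self.affine = np.diag([*spacing, 1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def count(self) -> int:
        """Number of foreground voxels (n)."""
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0]))


def read_volume(path) -> LabelVolume:
    """Read a NIfTI-1 file as a :class:`LabelVolume`.

    The lattice must have exactly 3 spatial axes and (near-)integer voxel
    values; spacing is taken from the header zooms, the affine is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file does not exist: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim} axes in {path}")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return LabelVolume(data=data, spacing=spacing, affine=np.asarray(img.affine))


def write_volume(vol: LabelVolume | BinaryMask, path) -> None:
    """Write a volume or mask as NIfTI-1, round-trippable by :func:`read_volume`."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.int32)
    img = nib.Nifti1Image(data, affine=np.asarray(vol.affine, dtype=float))
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))


def resample_isotropic(
    vol: LabelVolume, target: float = 1.0, spline_order: int = 3
) -> LabelVolume:
    """Resample a label volume to an isotropic grid by B-spline interpolation.

    Direct spline interpolation of label ids manufactures labels that never
    existed, so each label is interpolated as a separate indicator field and
    the output voxel takes the argmax label (ties broken by lowest label id).
    Physical voxel centers are mapped exactly, so the physical extent of
    solid structures is preserved up to surface discretization.

    Parameters
    ----------
    target : float
        Output voxel edge in mm (isotropic). Default 1.0 mm.
    spline_order : int
        B-spline order in [0, 5]; cubic by default.
    """
    if target <= 0:
        raise ValueError(f"target spacing must be > 0, got {target}")
    if not (0 <= spline_order <= 5):
        raise ValueError(f"spline_order must be in [0, 5], got {spline_order}")
    spacing = vol.spacing
    if np.allclose(spacing, target):
        return LabelVolume(vol.data.copy(), np.full(3, float(target)), vol.affine.copy())

    out_shape = tuple(
        max(1, int(round(n * s / target))) for n, s in zip(vol.shape, spacing)
    )
    # Output voxel centers in input index coordinates (centers at index*spacing).
    grids = [
        (np.arange(m) * target) / s * np.ones(1)  # phys / spacing
        for m, s in zip(out_shape, spacing)
    ]
    coords = np.meshgrid(*grids, indexing="ij")

    labels = [int(l) for l in np.unique(vol.data)]
    scores = np.empty((len(labels),) + out_shape, dtype=np.float32)
    for i, lab in enumerate(labels):
        indicator = (vol.data == lab).astype(np.float32)
        scores[i] = ndimage.map_coordinates(
            indicator, coords, order=spline_order, mode="nearest"
        )
    # argmax returns the first (lowest-id) label on exact ties
    out = np.asarray(labels, dtype=np.int32)[np.argmax(scores, axis=0)]

    new_spacing = np.full(3, float(target))
    new_affine = vol.affine.copy()
    new_affine[:3, :3] = vol.affine[:3, :3] @ np.diag(target / spacing)
    return LabelVolume(out, new_spacing, new_affine)


def extract_mask(vol: LabelVolume, labels) -> BinaryMask:
    """Binary mask of voxels whose label is in ``labels``; spacing propagated.

    Labels absent from the volume are legal and yield an empty mask, logged
    as a warning rather than raised.
    """
    labels = set(int(l) for l in labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    present = set(int(l) for l in np.unique(vol.data))
    missing = labels - present
    if missing:
        logger.warning(
            "extract_mask: labels %s not present in volume (labels present: %s)",
            sorted(missing), sorted(present),
        )
    mask = np.isin(vol.data, sorted(labels))
    return BinaryMask(mask, vol.spacing.copy(), vol.affine.copy())


def intracranial_volume(gm: BinaryMask, wm: BinaryMask, csf: BinaryMask) -> int:
    """Intracranial volume as the summed voxel counts of GM, WM and CSF.

    The definition is additive: ICV = n_GM + n_WM + n_CSF. If the masks
    overlap, overlapping voxels are counted once per mask they belong to,
    and a warning is emitted (segmentations should be disjoint).
    """
    masks = (gm, wm, csf)
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mask shapes differ: {sorted(shapes)}")
    for a, b in ((gm, wm), (gm, csf), (wm, csf)):
        if not np.allclose(a.spacing, b.spacing):
            raise ValueError("mask spacings differ")
    overlap = (gm.data & wm.data) | (gm.data & csf.data) | (wm.data & csf.data)
    n_overlap = int(overlap.sum())
    if n_overlap:
        warnings.warn(
            f"intracranial_volume: {n_overlap} voxels belong to more than one "
            "tissue mask and are counted once per mask (additive definition)",
            stacklevel=2,
        )
    return gm.count + wm.count + csf.count
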