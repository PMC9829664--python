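"""Voxel-volume data model, NIfTI I/O and mask algebra.

Conventions used throughout the package:

* volumes are rank-3 arrays indexed ``data[x, y, z]`` with 0-based voxel
  indices;
* ``z`` (the last axis) is the vertical / superior–inferior axis that the
  Judet views and the fusion permutation rotate about;
* voxel spacing is given in millimetres per axis (isotropic 1 mm default).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path
import nibabel as nib
import numpy as np
from scipy import ndimage


class VolumeFormatError(ValueError):
    """Raised for files or arrays that violate the 3D volume contract."""


class EmptyMaskError(ValueError):
    """Raised where an operation is undefined on an empty mask."""


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(v) for v in np.atleast_1d(spacing))
    if len(s) == 1:
        s = (s[0], s[0], s[0])
    if len(s) != 3 or any(v <= 0 for v in s):
        raise ValueError(f"spacing must be 3 positive floats, got {spacing!r}")
    return s  # type: ignore[return-value]


@dataclass
class IntensityVolume:
    """Rank-3 grid of Hounsfield-unit intensities."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeFormatError(
                f"expected a rank-3 grid, got shape {self.data.shape}"
            )
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """Rank-3 boolean grid sharing the volume grid conventions."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected a rank-3 grid, got shape {self.data.shape}"
            )
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class FragmentSet:
    """Ordered, pairwise-disjoint binary masks, one per bone fragment."""

    fragments: list[BinaryMask] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.fragments) < 1:
            raise ValueError("a FragmentSet needs at least one fragment")
        shape = self.fragments[0].shape
        acc = np.zeros(shape, dtype=np.int32)
        for f in self.fragments:
            if f.shape != shape:
                raise VolumeFormatError("fragments must share one grid")
            acc += f.data
        if acc.max(initial=0) > 1:
            raise ValueError("fragments must be pairwise disjoint")

    @property
    def n(self) -> int:
        return len(self.fragments)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.fragments[0].spacing

    def union(self) -> BinaryMask:
        out = np.zeros(self.fragments[0].shape, dtype=bool)
        for f in self.fragments:
            out |= f.data
        return BinaryMask(out, self.fragments[0].spacing)


@dataclass
class LabelVolume:
    """Rank-3 grid over {0: background, 1: bone, 2: auxiliary}."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    BACKGROUND = 0
    BONE = 1
    AUXILIARY = 2

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected a rank-3 grid, got shape {self.data.shape}"
            )
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1, 2)).all():
            raise ValueError(f"label values must be in {{0,1,2}}, got {vals}")
        self.data = self.data.astype(np.uint8)
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


Volume = IntensityVolume | BinaryMask | LabelVolume


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> IntensityVolume:
    """Read a 3D NIfTI file as an :class:`IntensityVolume`.

    Orientation is normalised to the closest canonical (RAS) frame so the
    package's ``(x, y, z)`` axis convention holds regardless of how the file
    was written.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.as_closest_canonical(nib.load(str(path)))
    if img.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D image, got {img.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return IntensityVolume(np.asanyarray(img.dataobj).astype(np.float64), spacing)


def read_labels(path: str | Path) -> LabelVolume:
    vol = read_volume(path)
    return LabelVolume(np.rint(vol.data).astype(np.uint8), vol.spacing)


def read_mask(path: str | Path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.data > 0.5, vol.spacing)


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write any volume type as NIfTI; label/mask data is stored as integers."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    data = vol.data
    if isinstance(vol, BinaryMask):
        data = data.astype(np.uint8)
    elif isinstance(vol, LabelVolume):
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float32)
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


# ---------------------------------------------------------------------------
# Connected components and mask algebra
# ---------------------------------------------------------------------------

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def connected_components(mask: BinaryMask, connectivity: int = 26) -> FragmentSet:
    """Split a mask into connected components, largest first.

    Components are ordered by decreasing voxel count; ties are broken by the
    smallest linear (C-order) index of any member voxel, which makes fragment
    labels deterministic across runs.
    """
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTS)}")
    if not mask.data.any():
        raise EmptyMaskError("cannot extract components of an empty mask")
    labelled, n = ndimage.label(mask.data, structure=_STRUCTS[connectivity])
    flat = labelled.ravel()
    order = []
    for lab in range(1, n + 1):
        idx = np.flatnonzero(flat == lab)
        order.append((-idx.size, int(idx[0]), lab))
    heapq.heapify(order)
    fragments = []
    while order:
        _, _, lab = heapq.heappop(order)
        fragments.append(BinaryMask(labelled == lab, mask.spacing))
    return FragmentSet(fragments)


def mask_union(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    _check_same_grid(a, b)
    return BinaryMask(a.data | b.data, a.spacing)


def mask_intersection(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    _check_same_grid(a, b)
    return BinaryMask(a.data & b.data, a.spacing)


def mask_difference(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    _check_same_grid(a, b)
    return BinaryMask(a.data & ~b.data, a.spacing)


_MASK_OPS = {
    "union": mask_union,
    "intersection": mask_intersection,
    "difference": mask_difference,
}


def mask_algebra(a: BinaryMask, b: BinaryMask, op: str) -> BinaryMask:
    """Voxel-wise set operation (``union`` / ``intersection`` / ``difference``)."""
    if op not in _MASK_OPS:
        raise ValueError(f"unknown op {op!r}; expected one of {sorted(_MASK_OPS)}")
    return _MASK_OPS[op](a, b)


def _check_same_grid(a: BinaryMask, b: BinaryMask) -> None:
    if a.shape != b.shape:
        raise VolumeFormatError(f"grid mismatch: {a.shape} vs {b.shape}")
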