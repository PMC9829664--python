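"""Morphological synthesis of the fracture-gap auxiliary class.

Fracture-representative voxels are those lying between nearby bone
fragments: every fragment mask is dilated with a spherical structuring
element of radius ``r`` (default 2 voxels), the pairwise intersections of
the dilations are united, and the bone itself is subtracted.  The result is
the third ("auxiliary") output class that a reconstruction network is
trained on alongside background and bone.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, FragmentSet, LabelVolume


@dataclass(frozen=True)
class StructuringElement:
    """Discrete sphere: all integer offsets with Euclidean norm <= radius."""

    radius: int
    footprint: np.ndarray  # (2r+1)^3 boolean array

    @property
    def offsets(self) -> np.ndarray:
        """Integer offsets (k, 3) relative to the element centre."""
        idx = np.argwhere(self.footprint) - self.radius
        return idx


def spherical_element(r: int) -> StructuringElement:
    """Spherical structuring element of radius ``r`` voxels (r >= 1)."""
    if int(r) != r or r < 1:
        raise ValueError(f"radius must be an integer >= 1, got {r!r}")
    r = int(r)
    grid = np.indices((2 * r + 1,) * 3) - r
    footprint = (grid**2).sum(axis=0) <= r * r
    return StructuringElement(r, footprint)


def dilate(mask: BinaryMask, el: StructuringElement) -> BinaryMask:
    """Minkowski dilation, clipped at the grid boundary (no wrap-around)."""
    if not mask.data.any():
        return BinaryMask(mask.data.copy(), mask.spacing)
    out = ndimage.binary_dilation(mask.data, structure=el.footprint)
    return BinaryMask(out, mask.spacing)


def synthesize_auxiliary(frags: FragmentSet, r: int = 2) -> BinaryMask:
    """Fracture-gap voxels between fragments.

    m_f = [ union over fragment pairs k != l of
            (m_b^(k) dilated) ∩ (m_b^(l) dilated) ]  −  union of fragments.

    An intact bone (single fragment) yields an empty mask, as no fragment
    pair exists.
    """
    el = spherical_element(r)
    spacing = frags.spacing
    shape = frags.fragments[0].shape
    bone = frags.union()
    acc = np.zeros(shape, dtype=bool)
    dilated = [dilate(f, el).data for f in frags.fragments]
    for a, b in combinations(range(frags.n), 2):
        acc |= dilated[a] & dilated[b]
    acc &= ~bone.data
    return BinaryMask(acc, spacing)


def build_labels(frags: FragmentSet, aux: BinaryMask | None = None) -> LabelVolume:
    """Assemble a {background, bone, auxiliary} ground-truth label volume.

    ``aux=None`` builds the two-class variant (no auxiliary voxels).  The
    auxiliary mask must be disjoint from the bone; gap voxels never overwrite
    bone.
    """
    bone = frags.union()
    labels = np.zeros(bone.shape, dtype=np.uint8)
    labels[bone.data] = LabelVolume.BONE
    if aux is not None:
        if aux.shape != bone.shape:
            raise ValueError("auxiliary mask grid does not match fragments")
        if (aux.data & bone.data).any():
            raise ValueError("auxiliary mask overlaps bone fragments")
        labels[aux.data] = LabelVolume.AUXILIARY
    return LabelVolume(labels, frags.spacing)
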