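"""Simulated biplanar radiographs (digitally reconstructed radiographs).

Parallel-beam geometry: the volume is rotated about the vertical (z) axis
and attenuation (HU + 1000, clamped at 0) is integrated along the y axis.
The Judet pair consists of the −45° and +45° views; an optional rotational
error on the second view supports the view-misalignment sensitivity
protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import IntensityVolume


@dataclass
class Radiograph:
    """2D line-integral image, min–max normalised to [0, 1].

    ``data`` is indexed (z, x'): rows are the vertical axis, columns the
    detector's horizontal axis after rotating the volume by ``angle_deg``
    about z.
    """

    data: np.ndarray
    angle_deg: float
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("a radiograph is a 2D image")


RadiographPair = tuple[Radiograph, Radiograph]


def attenuation(vol: IntensityVolume) -> np.ndarray:
    """Water-referenced linear attenuation proxy: HU + 1000, clamped at 0."""
    return np.clip(vol.data + 1000.0, 0.0, None)


def project_raw(vol: IntensityVolume, angle_deg: float) -> np.ndarray:
    """Un-normalised parallel-beam line integrals at a view angle about z.

    Returns a (z, x') image in attenuation·mm units.
    """
    att = attenuation(vol)
    if angle_deg != 0.0:
        att = ndimage.rotate(
            att, angle_deg, axes=(0, 1), reshape=False, order=1,
            mode="constant", cval=0.0,
        )
        att = np.clip(att, 0.0, None)
    img = att.sum(axis=1) * vol.spacing[1]  # integrate along y -> (x', z)
    return img.T  # (z, x')


def project(vol: IntensityVolume, angle_deg: float) -> Radiograph:
    """Normalised DRR at ``angle_deg`` about the vertical axis."""
    raw = project_raw(vol, angle_deg)
    lo, hi = float(raw.min()), float(raw.max())
    if hi > lo:
        data = (raw - lo) / (hi - lo)
    else:
        data = np.zeros_like(raw)
    return Radiograph(data, angle_deg, (vol.spacing[2], vol.spacing[0]))


def judet_pair(
    vol: IntensityVolume, rotational_error_deg: float = 0.0
) -> RadiographPair:
    """The ±45° Judet views; error tilts the second view off orthogonality.

    ``rotational_error_deg = 0`` gives exactly orthogonal views, the geometry
    the fusion permutation assumes.
    """
    if abs(rotational_error_deg) > 45.0:
        raise ValueError("rotational error must satisfy |error| <= 45 degrees")
    x1 = project(vol, -45.0)
    x2 = project(vol, 45.0 + rotational_error_deg)
    return x1, x2


def pair_to_array(pair: RadiographPair) -> np.ndarray:
    """Stack a radiograph pair into the (2, H, W) network input layout."""
    x1, x2 = pair
    if x1.data.shape != x2.data.shape:
        raise ValueError("radiograph pair must share one image size")
    return np.stack([x1.data, x2.data]).astype(np.float32)
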