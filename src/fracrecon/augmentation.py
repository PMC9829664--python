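"""Fractural augmentation: manufacture fractured samples from intact bone.

Pipeline: synthesize a random self-affine rough surface (spectral method,
power-law PSD ~ q^-(2+2H)), voxelize it into a thin slab mask, place it at
a random AO-coded fracture location with a random rigid transform, split the
bone mask with it, and fill the resulting gap with soft-tissue intensities
drawn uniformly from 63–193 HU.  Only nondisplaced fractures can be
manufactured this way — fragments keep their anatomical alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import (
    BinaryMask,
    EmptyMaskError,
    FragmentSet,
    IntensityVolume,
    connected_components,
)

AO_CODES = ("31A", "31B", "31C", "32")

# Tilt of the surface normal away from vertical, per AO location.
# Shaft fractures (32) are near-transverse; neck fractures (31B) oblique.
DEFAULT_TILT_RANGES_DEG = {
    "32": (0.0, 20.0),
    "31B": (30.0, 70.0),
    "31A": (0.0, 30.0),
    "31C": (0.0, 30.0),
}


class NonFracturingDrawError(RuntimeError):
    """A placed surface failed to split the bone into >= 2 valid fragments."""


@dataclass
class RoughSurfaceParams:
    """Parameters of the spectrally synthesized self-affine fracture surface.

    ``hurst`` is the Hurst exponent H of the height field (PSD slope
    -(2+2H)); ``rms`` the target root-mean-square roughness in voxels;
    cutoffs are radial spatial frequencies in cycles/voxel.
    """

    extent: int = 64
    hurst: float = 0.8
    rms: float = 2.0
    cutoff_low: float = 0.02
    cutoff_high: float = 0.4
    thickness: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.hurst < 1.0):
            raise ValueError("Hurst exponent must lie in (0, 1)")
        if self.rms <= 0:
            raise ValueError("rms roughness must be positive")
        if self.thickness < 1:
            raise ValueError("thickness must be >= 1 voxel")
        if not (0.0 < self.cutoff_low < self.cutoff_high <= 0.5):
            raise ValueError("cutoffs must satisfy 0 < low < high <= 0.5")
        if self.extent < 4 or (self.extent & (self.extent - 1)) != 0:
            raise ValueError("extent must be a power of two >= 4")


@dataclass
class FracturePlacement:
    """Rigid placement of a fracture surface inside an AO region box."""

    ao_code: str
    tilt_deg: float
    azimuth_deg: float
    spin_deg: float
    translation: tuple[float, float, float]
    seed: int = 0

    def rotation_matrix(self) -> np.ndarray:
        """World-from-local rotation: spin about local normal, then tilt, then azimuth."""
        t = math.radians(self.tilt_deg)
        a = math.radians(self.azimuth_deg)
        s = math.radians(self.spin_deg)
        rz_spin = np.array(
            [[math.cos(s), -math.sin(s), 0], [math.sin(s), math.cos(s), 0], [0, 0, 1]]
        )
        ry = np.array(
            [[math.cos(t), 0, math.sin(t)], [0, 1, 0], [-math.sin(t), 0, math.cos(t)]]
        )
        rz = np.array(
            [[math.cos(a), -math.sin(a), 0], [math.sin(a), math.cos(a), 0], [0, 0, 1]]
        )
        return rz @ ry @ rz_spin


def generate_height_field(p: RoughSurfaceParams) -> np.ndarray:
    """Zero-mean self-affine height field with PSD ~ q^-(2+2H), RMS = p.rms.

    Spectral synthesis: complex Gaussian noise shaped by a power-law
    amplitude between the radial frequency cutoffs, inverse-FFT'd to real
    space and rescaled to the requested RMS.
    """
    n = p.extent
    rng = np.random.default_rng(p.seed)
    fx = np.fft.fftfreq(n)
    qx, qy = np.meshgrid(fx, fx, indexing="ij")
    q = np.hypot(qx, qy)
    amp = np.zeros_like(q)
    band = (q >= p.cutoff_low) & (q <= p.cutoff_high)
    # PSD ∝ q^-(2+2H)  ⇒  amplitude ∝ q^-(1+H)
    amp[band] = q[band] ** (-(1.0 + p.hurst))
    noise = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    h = np.fft.ifft2(amp * noise).real
    h -= h.mean()
    current_rms = math.sqrt(float((h**2).mean()))
    if current_rms == 0.0:
        raise ValueError("degenerate spectrum: no energy between cutoffs")
    return h * (p.rms / current_rms)


def radial_psd(h: np.ndarray, n_bins: int = 40) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged power spectral density of a 2D field.

    Returns (radial frequency bin centres, mean power per bin); used to
    verify the synthesized slope -(2+2H).
    """
    n = h.shape[0]
    spec = np.abs(np.fft.fft2(h)) ** 2 / h.size
    fx = np.fft.fftfreq(n)
    qx, qy = np.meshgrid(fx, fx, indexing="ij")
    q = np.hypot(qx, qy).ravel()
    power = spec.ravel()
    keep = q > 0
    q, power = q[keep], power[keep]
    edges = np.logspace(np.log10(q.min()), np.log10(0.5), n_bins + 1)
    idx = np.digitize(q, edges) - 1
    centers, means = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            centers.append(math.sqrt(edges[b] * edges[b + 1]))
            means.append(float(power[sel].mean()))
    return np.array(centers), np.array(means)


def fit_psd_slope(p: RoughSurfaceParams) -> float:
    """Log–log slope of the radially averaged PSD between the cutoffs."""
    h = generate_height_field(p)
    qc, pw = radial_psd(h)
    sel = (qc >= p.cutoff_low * 1.5) & (qc <= p.cutoff_high / 1.5) & (pw > 0)
    coef = np.polyfit(np.log(qc[sel]), np.log(pw[sel]), 1)
    return float(coef[0])


def voxelize_surface(h: np.ndarray, thickness: float) -> BinaryMask:
    """Turn a height field into a thin slab mask in its local frame.

    The local frame is (u, v, w): (u, v) spans the sheet laterally and w is
    the surface-normal direction.  Voxels within ``thickness/2`` of the
    embedded sheet w = h(u, v) are set.
    """
    if thickness < 1:
        raise ValueError("thickness must be >= 1 voxel")
    n = h.shape[0]
    span = float(h.max() - h.min()) + thickness + 4.0
    nw = max(int(math.ceil(span)), int(thickness) + 4)
    w0 = (nw - 1) / 2.0 - float(h.mean())
    sheet = h + w0
    # half-open interval [sheet - t/2, sheet + t/2) so a flat field at t = 1
    # rasterises to exactly one voxel per column
    lo = np.ceil(sheet - thickness / 2.0).astype(int)
    hi = (np.ceil(sheet + thickness / 2.0) - 1).astype(int)
    # watertight digital surface: force neighbouring columns' w-intervals to
    # overlap so the slab blocks 26-connected paths even at steep steps
    lo, hi = (
        np.minimum(lo, ndimage.minimum_filter(hi, size=3)),
        np.maximum(hi, ndimage.maximum_filter(lo, size=3)),
    )
    lo = np.clip(lo, 0, nw - 1)
    hi = np.clip(hi, 0, nw - 1)
    w = np.arange(nw)[None, None, :]
    mask = (w >= lo[:, :, None]) & (w <= hi[:, :, None])
    return BinaryMask(mask)


def sample_placement(
    ao: str,
    region_boxes: dict[str, tuple[tuple[int, int], ...]],
    seed: int = 0,
    tilt_ranges: dict[str, tuple[float, float]] | None = None,
) -> FracturePlacement:
    """Draw a random placement for a fracture surface at an AO location."""
    if ao not in AO_CODES:
        raise ValueError(f"unknown AO code {ao!r}; expected one of {AO_CODES}")
    if ao not in region_boxes:
        raise ValueError(f"region map has no box for AO code {ao!r}")
    tilt_ranges = tilt_ranges or DEFAULT_TILT_RANGES_DEG
    rng = np.random.default_rng(seed)
    box = region_boxes[ao]
    translation = tuple(float(rng.uniform(lo, hi + 1)) for lo, hi in box)
    tilt = float(rng.uniform(*tilt_ranges[ao]))
    azimuth = float(rng.uniform(0.0, 360.0))
    spin = float(rng.uniform(0.0, 360.0))
    return FracturePlacement(ao, tilt, azimuth, spin, translation, seed=seed)


def place_surface_mask(
    surface: BinaryMask, placement: FracturePlacement, grid_shape: tuple[int, int, int]
) -> BinaryMask:
    """Rigidly transform a local slab mask onto the volume grid.

    Nearest-neighbour resampling preserves binarity; voxels transformed
    outside the grid are dropped.  Note that resampling a thin digital slab
    can open diagonal pinholes — :func:`place_surface` rasterises the
    continuous surface instead and is what the augmentation pipeline uses.
    """
    rot = placement.rotation_matrix()
    center_local = (np.array(surface.shape) - 1) / 2.0
    trans = np.array(placement.translation)
    # scipy affine_transform: input_coord = matrix @ output_coord + offset
    matrix = rot.T
    offset = center_local - matrix @ trans
    placed = ndimage.affine_transform(
        surface.data.astype(np.uint8),
        matrix,
        offset=offset,
        output_shape=grid_shape,
        order=0,
        mode="constant",
        cval=0,
    )
    return BinaryMask(placed.astype(bool))


def place_surface(
    h: np.ndarray,
    thickness: float,
    placement: FracturePlacement,
    grid_shape: tuple[int, int, int],
) -> BinaryMask:
    """Rasterise the rough surface slab directly on the volume grid.

    Every grid voxel is mapped into the surface's local frame; it belongs to
    the slab when its local height above the (bilinearly interpolated) sheet
    is within half the effective thickness.  The effective thickness adapts
    to the sheet's local slope and to the slab orientation so the digital
    slab always blocks 26-connected paths — a straight nearest-neighbour
    resampling of a thin voxelised slab does not (staircase pinholes).
    """
    n = h.shape[0]
    rot = placement.rotation_matrix()
    trans = np.asarray(placement.translation)
    coords = np.indices(grid_shape, dtype=np.float64).reshape(3, -1)
    local = rot.T @ (coords - trans[:, None])
    u = local[0] + n / 2.0
    v = local[1] + n / 2.0
    w = local[2]
    inside_sheet = (u >= 0) & (u <= n - 1) & (v >= 0) & (v <= n - 1)
    uv = np.vstack([u, v])
    h_uv = ndimage.map_coordinates(h, uv, order=1, mode="nearest")
    gx, gy = np.gradient(h)
    slope1 = np.abs(gx) + np.abs(gy)
    s_uv = ndimage.map_coordinates(slope1, uv, order=1, mode="nearest")
    # 1-norm of the local w axis in world coordinates: the minimum vertical
    # thickness a flat digital slab needs to be 26-separating
    m1 = float(np.abs(rot[:, 2]).sum())
    t_eff = np.maximum(thickness, m1 + 1.8 * s_uv)
    mask = inside_sheet & (np.abs(w - h_uv) <= t_eff / 2.0)
    return BinaryMask(mask.reshape(grid_shape))


def split_bone(
    m_b: BinaryMask,
    g_placed: BinaryMask,
    min_fragment_fraction: float = 0.01,
) -> tuple[FragmentSet, BinaryMask]:
    """Split intact bone with a placed surface mask.

    Returns ``(fragments of m_b − G, m_b ∩ G)``.  The set identities
    union(fragments) ∪ gap = m_b and union(fragments) ∩ gap = ∅ hold
    exactly.  Draws that fail to produce >= 2 fragments of at least
    ``min_fragment_fraction`` of the bone raise
    :class:`NonFracturingDrawError` so the caller can resample.
    """
    if not m_b.data.any():
        raise EmptyMaskError("cannot fracture an empty bone mask")
    gap = BinaryMask(m_b.data & g_placed.data, m_b.spacing)
    residual = m_b.data & ~g_placed.data
    if not residual.any():
        raise NonFracturingDrawError("surface swallowed the whole bone")
    frags = connected_components(BinaryMask(residual, m_b.spacing), connectivity=26)
    min_size = max(1, int(min_fragment_fraction * m_b.count()))
    kept = [f for f in frags.fragments if f.count() >= min_size]
    if len(kept) < 2:
        raise NonFracturingDrawError(
            f"draw produced {len(kept)} valid fragment(s); need >= 2"
        )
    if len(kept) != frags.n:
        raise NonFracturingDrawError("draw produced sliver fragments")
    return frags, gap


SOFT_TISSUE_HU = (63.0, 193.0)


def replace_intensity(
    q: IntensityVolume, m_f_star: BinaryMask, seed: int = 0
) -> IntensityVolume:
    """Fill the fracture gap with uniform soft-tissue intensities (63–193 HU).

    Intensities outside the gap are copied bit-exactly.
    """
    if q.shape != m_f_star.shape:
        raise ValueError(f"grid mismatch: {q.shape} vs {m_f_star.shape}")
    rng = np.random.default_rng(seed)
    out = q.data.copy()
    n = m_f_star.count()
    if n:
        out[m_f_star.data] = rng.uniform(*SOFT_TISSUE_HU, size=n)
    return IntensityVolume(out, q.spacing)


@dataclass
class AugmentedSample:
    volume: IntensityVolume          # Q* with soft-tissue gap fill
    fragments: FragmentSet           # m_b* split into fragments
    gap: BinaryMask                  # m_f* = m_b ∩ T(G)
    placement: FracturePlacement
    type_tag: str = "nondisplaced"


def augment_sample(
    q: IntensityVolume,
    m_b: BinaryMask,
    region_boxes: dict[str, tuple[tuple[int, int], ...]],
    ao_codes: tuple[str, ...] = AO_CODES,
    surface_params: RoughSurfaceParams | None = None,
    seed: int = 0,
    max_retries: int = 25,
    min_fragment_fraction: float = 0.01,
) -> AugmentedSample:
    """Manufacture one nondisplaced fractured sample from an intact one.

    Rejection-resamples the surface and its placement (bounded retries) until
    the bone splits into >= 2 valid fragments.
    """
    if not m_b.data.any():
        raise EmptyMaskError("intact bone mask is empty")
    base = surface_params or RoughSurfaceParams(
        extent=int(2 ** math.ceil(math.log2(max(m_b.shape))))
    )
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for _ in range(max_retries):
        draw_seed = int(rng.integers(0, 2**31 - 1))
        ao = str(rng.choice(ao_codes))
        try:
            sp = RoughSurfaceParams(
                extent=base.extent,
                hurst=base.hurst,
                rms=base.rms,
                cutoff_low=base.cutoff_low,
                cutoff_high=base.cutoff_high,
                thickness=base.thickness,
                seed=draw_seed,
            )
            h = generate_height_field(sp)
            placement = sample_placement(ao, region_boxes, seed=draw_seed)
            g_placed = place_surface(h, sp.thickness, placement, m_b.shape)
            frags, gap = split_bone(m_b, g_placed, min_fragment_fraction)
        except NonFracturingDrawError as err:
            last_err = err
            continue
        q_star = replace_intensity(q, gap, seed=draw_seed)
        return AugmentedSample(q_star, frags, gap, placement)
    raise NonFracturingDrawError(
        f"no fracturing draw within {max_retries} retries "
        f"(ao_codes={ao_codes}, seed={seed}): {last_err}"
    )
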