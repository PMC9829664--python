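"""Synthetic proximal-femur phantoms.

A phantom is the union of simple solids that exhibit the anatomy the AO/OTA
fracture-location codes refer to: a vertical shaft capsule, an angled neck
capsule, a head sphere and two trochanteric bumps.  Intensities are drawn
from Gaussian bone / soft-tissue distributions in Hounsfield units; defaults
put bone well above the 63–193 HU soft-tissue band used when fracture gaps
are filled in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .volumes import BinaryMask, FragmentSet, IntensityVolume


@dataclass
class PhantomParams:
    """Geometry and intensity parameters for one femur phantom.

    Lengths are in millimetres (== voxels at the default 1 mm spacing).
    The neck–shaft angle is in degrees, anatomically between 90 and 180.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    shaft_radius: float = 6.0
    shaft_length: float = 30.0
    neck_radius: float = 4.5
    neck_length: float = 12.0
    neck_shaft_angle_deg: float = 130.0
    head_radius: float = 8.0
    greater_troch_radius: float = 5.0
    lesser_troch_radius: float = 3.0
    bone_hu_mean: float = 700.0
    bone_hu_sd: float = 100.0
    tissue_hu_mean: float = 40.0
    tissue_hu_sd: float = 20.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        radii = (
            self.shaft_radius,
            self.shaft_length,
            self.neck_radius,
            self.neck_length,
            self.head_radius,
            self.greater_troch_radius,
            self.lesser_troch_radius,
        )
        if any(r <= 0 for r in radii):
            raise ValueError("all radii and lengths must be positive")
        if not (90.0 < self.neck_shaft_angle_deg < 180.0):
            raise ValueError("neck–shaft angle must lie in (90, 180) degrees")
        if self.bone_hu_mean <= self.tissue_hu_mean:
            raise ValueError("bone intensity must exceed soft-tissue intensity")

    @classmethod
    def default_for_shape(cls, shape: tuple[int, int, int], **overrides) -> "PhantomParams":
        """Defaults with all lengths scaled so the phantom fills ``shape``."""
        scale = min(shape) / 64.0
        scaled = dict(
            shape=tuple(int(s) for s in shape),
            shaft_radius=6.0 * scale,
            shaft_length=30.0 * scale,
            neck_radius=4.5 * scale,
            neck_length=12.0 * scale,
            head_radius=8.0 * scale,
            greater_troch_radius=5.0 * scale,
            lesser_troch_radius=3.0 * scale,
        )
        scaled.update(overrides)
        return cls(**scaled)


def _scaled_geometry(p: PhantomParams) -> dict:
    """Anchor points of the phantom solids inside the grid (voxel units)."""
    nx, ny, nz = p.shape
    cx, cy = 0.45 * nx, ny / 2.0
    shaft_base = np.array([cx, cy, 0.12 * nz])
    shaft_top = shaft_base + [0.0, 0.0, p.shaft_length]
    ang = math.radians(p.neck_shaft_angle_deg)
    # neck leaves the shaft top medially, rising by (angle - 90°) from horizontal
    direction = np.array([math.sin(ang), 0.0, -math.cos(ang)])
    neck_end = shaft_top + direction * p.neck_length
    head_center = neck_end + direction * (0.6 * p.head_radius)
    gt_center = shaft_top + np.array([-0.8 * p.shaft_radius, 0.0, 2.0])
    lt_center = shaft_top + np.array([0.6 * p.shaft_radius, 0.0, -6.0])
    return {
        "shaft": (shaft_base, shaft_top, p.shaft_radius),
        "neck": (shaft_top, neck_end, p.neck_radius),
        "head": (head_center, p.head_radius),
        "greater_troch": (gt_center, p.greater_troch_radius),
        "lesser_troch": (lt_center, p.lesser_troch_radius),
    }


def _capsule_mask(coords, a, b, r) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    pa = [coords[i] - a[i] for i in range(3)]
    t = (pa[0] * ab[0] + pa[1] * ab[1] + pa[2] * ab[2]) / denom
    t = np.clip(t, 0.0, 1.0)
    d2 = sum((pa[i] - t * ab[i]) ** 2 for i in range(3))
    return d2 <= r * r


def _sphere_mask(coords, c, r) -> np.ndarray:
    d2 = sum((coords[i] - c[i]) ** 2 for i in range(3))
    return d2 <= r * r


def bone_mask(p: PhantomParams) -> np.ndarray:
    """Boolean union of the phantom's analytic solids on the voxel grid."""
    geo = _scaled_geometry(p)
    coords = np.indices(p.shape, dtype=np.float64)
    m = _capsule_mask(coords, *geo["shaft"])
    m |= _capsule_mask(coords, *geo["neck"])
    m |= _sphere_mask(coords, *geo["head"])
    m |= _sphere_mask(coords, *geo["greater_troch"])
    m |= _sphere_mask(coords, *geo["lesser_troch"])
    return m


def make_phantom(p: PhantomParams) -> tuple[IntensityVolume, FragmentSet]:
    """Build one intact phantom: intensity volume plus single-fragment mask."""
    geo = _scaled_geometry(p)
    for name, solid in geo.items():
        r = solid[-1]
        anchors = solid[:-1]
        for center in anchors:
            lo = np.array(center) - r
            hi = np.array(center) + r
            if (lo < -0.5).any() or (hi > np.array(p.shape) - 0.5).any():
                raise ValueError(f"phantom solid {name!r} exceeds the grid {p.shape}")
    mask = bone_mask(p)
    if not mask.any():
        raise ValueError("degenerate geometry: empty bone mask")
    rng = np.random.default_rng(p.seed)
    intensity = rng.normal(p.tissue_hu_mean, p.tissue_hu_sd, size=p.shape)
    intensity[mask] = rng.normal(p.bone_hu_mean, p.bone_hu_sd, size=int(mask.sum()))
    vol = IntensityVolume(intensity, p.spacing)
    frags = FragmentSet([BinaryMask(mask, p.spacing)])
    return vol, frags


def analytic_volume_mc(p: PhantomParams, n_samples: int = 200_000, seed: int = 0) -> float:
    """Monte-Carlo estimate of the continuous union volume (in voxel³ units).

    Used as an independent check on the voxelised bone mask.
    """
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0.0, 1.0, size=(3, n_samples)) * np.array(p.shape)[:, None]
    geo = _scaled_geometry(p)
    inside = _capsule_mask(pts, *geo["shaft"])
    inside |= _capsule_mask(pts, *geo["neck"])
    inside |= _sphere_mask(pts, *geo["head"])
    inside |= _sphere_mask(pts, *geo["greater_troch"])
    inside |= _sphere_mask(pts, *geo["lesser_troch"])
    return float(inside.mean()) * float(np.prod(p.shape))


def region_map(p: PhantomParams) -> dict[str, tuple[tuple[int, int], ...]]:
    """AO-location code → axis-aligned bounding box (inclusive voxel bounds).

    Codes: 31A trochanteric, 31B femoral neck, 31C femoral head, 32 shaft.
    """
    geo = _scaled_geometry(p)
    shape = np.array(p.shape)

    def box(center, half) -> tuple[tuple[int, int], ...]:
        lo = np.maximum(np.floor(center - half), 0).astype(int)
        hi = np.minimum(np.ceil(center + half), shape - 1).astype(int)
        return tuple((int(l), int(h)) for l, h in zip(lo, hi))

    shaft_base, shaft_top, rs = geo["shaft"]
    neck_a, neck_b, rn = geo["neck"]
    head_c, rh = geo["head"]
    gt_c, rgt = geo["greater_troch"]

    # keep the shaft box on the lower diaphysis, clear of the trochanter bumps
    shaft_mid = shaft_base + 0.33 * (shaft_top - shaft_base)
    shaft_half = np.array([rs + 2, rs + 2, 0.28 * p.shaft_length])
    neck_mid = 0.5 * (neck_a + neck_b)
    neck_half = np.array([0.45 * p.neck_length, rn + 2, 0.45 * p.neck_length])
    troch_half = np.array([rs + rgt, rs + rgt, rgt + 3])
    return {
        "31A": box(shaft_top, troch_half),
        "31B": box(neck_mid, neck_half),
        "31C": box(head_c, np.full(3, rh)),
        "32": box(shaft_mid, shaft_half),
    }


@dataclass
class CohortRanges:
    """Uniform sampling ranges for per-sample phantom parameters."""

    shaft_radius: tuple[float, float] = (5.0, 7.0)
    neck_radius: tuple[float, float] = (4.0, 5.0)
    neck_shaft_angle_deg: tuple[float, float] = (120.0, 140.0)
    head_radius: tuple[float, float] = (7.0, 9.0)

    def __post_init__(self) -> None:
        for name in ("shaft_radius", "neck_radius", "neck_shaft_angle_deg", "head_radius"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"empty range for {name}: ({lo}, {hi})")


@dataclass
class CohortSample:
    volume: IntensityVolume
    fragments: FragmentSet
    type_tag: str
    params: PhantomParams
    sample_id: str = ""


def make_cohort(
    n_intact: int,
    ranges: CohortRanges | None = None,
    seed: int = 0,
    base_params: PhantomParams | None = None,
) -> list[CohortSample]:
    """Draw ``n_intact`` intact phantoms with per-sample geometry and seeds.

    Fracture tags are assigned later by the augmentation module; every sample
    returned here is ``type_tag == "intact"``.
    """
    if n_intact < 1:
        raise ValueError("n_intact must be >= 1")
    base = base_params or PhantomParams()
    if ranges is None:
        s = min(base.shape) / 64.0
        ranges = CohortRanges(
            shaft_radius=(5.0 * s, 7.0 * s),
            neck_radius=(4.0 * s, 5.0 * s),
            neck_shaft_angle_deg=(120.0, 140.0),
            head_radius=(7.0 * s, 9.0 * s),
        )
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_intact):
        sample_seed = int(rng.integers(0, 2**31 - 1))
        r = np.random.default_rng(sample_seed)
        p = replace(
            base,
            shaft_radius=float(r.uniform(*ranges.shaft_radius)),
            neck_radius=float(r.uniform(*ranges.neck_radius)),
            neck_shaft_angle_deg=float(r.uniform(*ranges.neck_shaft_angle_deg)),
            head_radius=float(r.uniform(*ranges.head_radius)),
            seed=sample_seed,
        )
        vol, frags = make_phantom(p)
        cohort.append(CohortSample(vol, frags, "intact", p, sample_id=f"phantom_{i:03d}"))
    return cohort
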