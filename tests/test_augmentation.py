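"""Rough-surface synthesis, placement, bone splitting and gap intensity fill."""

import numpy as np
import pytest

from fracrecon.augmentation import (
    AO_CODES,
    FracturePlacement,
    NonFracturingDrawError,
    RoughSurfaceParams,
    SOFT_TISSUE_HU,
    augment_sample,
    fit_psd_slope,
    generate_height_field,
    place_surface,
    replace_intensity,
    sample_placement,
    split_bone,
    voxelize_surface,
)
from fracrecon.volumes import BinaryMask, EmptyMaskError, IntensityVolume


class TestHeightField:
    def test_rms_normalisation_over_seeds(self):
        target = 0.5
        rms = []
        for seed in range(20):
            h = generate_height_field(
                RoughSurfaceParams(extent=64, rms=target, seed=seed)
            )
            rms.append(np.sqrt((h**2).mean()))
        assert abs(np.mean(rms) - target) / target < 0.1

    def test_psd_slope_recovers_hurst_exponent(self):
        slope = fit_psd_slope(RoughSurfaceParams(extent=256, hurst=0.8, seed=4))
        assert abs(slope - (-3.6)) < 0.3

    def test_zero_mean_and_deterministic(self):
        p = RoughSurfaceParams(extent=32, seed=77)
        h1 = generate_height_field(p)
        h2 = generate_height_field(p)
        np.testing.assert_array_equal(h1, h2)
        assert abs(h1.mean()) < 1e-9

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(hurst=0.0),
            dict(hurst=1.0),
            dict(rms=-1.0),
            dict(thickness=0.5),
            dict(cutoff_low=0.3, cutoff_high=0.2),
            dict(extent=33),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RoughSurfaceParams(**kwargs)


class TestVoxelizeSurface:
    def test_flat_field_thickness_one_is_single_plane(self):
        g = voxelize_surface(np.zeros((8, 8)), 1.0)
        per_column = g.data.sum(axis=2)
        assert (per_column == 1).all()

    def test_voxel_count_close_to_slab_volume_for_small_roughness(self):
        h = generate_height_field(RoughSurfaceParams(extent=32, rms=0.3, seed=1))
        t = 3.0
        g = voxelize_surface(h, t)
        expected = 32 * 32 * t
        assert abs(g.count() - expected) / expected < 0.35

    def test_mask_is_26_connected(self):
        from fracrecon.volumes import connected_components

        h = generate_height_field(RoughSurfaceParams(extent=32, rms=2.0, seed=5))
        g = voxelize_surface(h, 2.0)
        assert connected_components(g, 26).n == 1


class TestSamplePlacement:
    def test_centroids_stay_inside_box(self, default_region_boxes):
        box = default_region_boxes["31B"]
        for seed in range(200):
            pl = sample_placement("31B", default_region_boxes, seed=seed)
            for axis in range(3):
                assert box[axis][0] <= pl.translation[axis] <= box[axis][1] + 1

    def test_deterministic(self, default_region_boxes):
        a = sample_placement("32", default_region_boxes, seed=5)
        b = sample_placement("32", default_region_boxes, seed=5)
        assert a == b

    def test_unknown_code_rejected(self, default_region_boxes):
        with pytest.raises(ValueError):
            sample_placement("99", default_region_boxes, seed=0)


class TestSplitBone:
    def test_midplane_cut_of_cube(self):
        cube = np.zeros((20, 20, 20), bool)
        cube[2:18, 2:18, 2:18] = True
        placement = FracturePlacement("32", 0.0, 0.0, 0.0, (10.0, 10.0, 10.0))
        g = place_surface(np.zeros((32, 32)), 1.0, placement, (20, 20, 20))
        frags, gap = split_bone(BinaryMask(cube), g, min_fragment_fraction=0.01)
        assert frags.n == 2
        sizes = sorted(f.count() for f in frags.fragments)
        assert abs(sizes[0] - sizes[1]) <= 16 * 16  # one plane of asymmetry
        assert gap.count() == 16 * 16  # single-plane gap through the cube

    def test_disjoint_surface_is_rejection(self):
        cube = np.zeros((16, 16, 16), bool)
        cube[2:8, 2:8, 2:8] = True
        empty = BinaryMask(np.zeros((16, 16, 16), bool))
        with pytest.raises(NonFracturingDrawError):
            split_bone(BinaryMask(cube), empty)

    def test_empty_bone_is_an_error(self):
        with pytest.raises(EmptyMaskError):
            split_bone(
                BinaryMask(np.zeros((8, 8, 8), bool)),
                BinaryMask(np.ones((8, 8, 8), bool)),
            )

    def test_conservation_on_random_phantom_cuts(
        self, default_phantom, default_region_boxes
    ):
        _, vol, frags = default_phantom
        m_b = frags.fragments[0]
        checked = 0
        seed = 0
        while checked < 10:
            seed += 1
            sp = RoughSurfaceParams(extent=64, seed=seed)
            h = generate_height_field(sp)
            pl = sample_placement("32", default_region_boxes, seed=seed)
            g = place_surface(h, sp.thickness, pl, m_b.shape)
            try:
                parts, gap = split_bone(m_b, g)
            except NonFracturingDrawError:
                continue
            union = parts.union()
            np.testing.assert_array_equal(union.data | gap.data, m_b.data)
            assert not (union.data & gap.data).any()
            checked += 1


class TestReplaceIntensity:
    def test_empty_gap_is_bit_exact_copy(self, default_phantom):
        _, vol, _ = default_phantom
        empty = BinaryMask(np.zeros(vol.shape, bool))
        out = replace_intensity(vol, empty, seed=1)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_replaced_values_in_soft_tissue_band_with_mean_128(self, rng):
        vol = IntensityVolume(np.full((25, 25, 25), 700.0))
        gap = BinaryMask(rng.random((25, 25, 25)) > 0.2)  # >10^4 voxels
        out = replace_intensity(vol, gap, seed=3)
        vals = out.data[gap.data]
        assert vals.min() >= SOFT_TISSUE_HU[0] and vals.max() <= SOFT_TISSUE_HU[1]
        assert abs(vals.mean() - 128.0) < 2.0
        np.testing.assert_array_equal(out.data[~gap.data], 700.0)

    def test_shape_mismatch_rejected(self):
        vol = IntensityVolume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            replace_intensity(vol, BinaryMask(np.zeros((5, 5, 5), bool)))


class TestAugmentSample:
    def test_shaft_fracture_lands_in_shaft_box(
        self, default_phantom, default_region_boxes
    ):
        _, vol, frags = default_phantom
        s = augment_sample(
            vol, frags.fragments[0], default_region_boxes, ao_codes=("32",), seed=2
        )
        assert s.fragments.n == 2
        box = default_region_boxes["32"]
        gap_coords = np.argwhere(s.gap.data)
        center = gap_coords.mean(axis=0)
        for axis in range(3):
            lo, hi = box[axis]
            assert lo - 3 <= center[axis] <= hi + 4

    def test_type_tag_always_nondisplaced(self, default_phantom, default_region_boxes):
        _, vol, frags = default_phantom
        s = augment_sample(vol, frags.fragments[0], default_region_boxes, seed=9)
        assert s.type_tag == "nondisplaced"

    def test_same_seed_bit_identical(self, default_phantom, default_region_boxes):
        _, vol, frags = default_phantom
        a = augment_sample(vol, frags.fragments[0], default_region_boxes, seed=4)
        b = augment_sample(vol, frags.fragments[0], default_region_boxes, seed=4)
        np.testing.assert_array_equal(a.volume.data, b.volume.data)
        np.testing.assert_array_equal(a.gap.data, b.gap.data)
        assert a.placement == b.placement

    def test_retry_budget_exhaustion_reports_context(self, default_phantom):
        _, vol, frags = default_phantom
        hopeless = {"32": ((0, 1), (0, 1), (0, 1))}  # box far from the bone
        with pytest.raises(NonFracturingDrawError, match="seed"):
            augment_sample(
                vol,
                frags.fragments[0],
                hopeless,
                ao_codes=("32",),
                seed=1,
                max_retries=3,
            )
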