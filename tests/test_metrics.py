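"""IoU / ASSD oracles, class-merge convention, aggregation, t-test."""

import numpy as np
import pytest

from fracrecon.metrics import (
    assd,
    assd_bruteforce,
    evaluate_cohort,
    extract_surface,
    iou,
    paired_ttest,
)
from fracrecon.volumes import BinaryMask, EmptyMaskError, LabelVolume


def cube_labels(lo, hi, grid=8, value=1):
    data = np.zeros((grid, grid, grid), dtype=np.uint8)
    data[lo:hi, lo:hi, lo:hi] = value
    return LabelVolume(data)


class TestIoU:
    def test_identical_is_one(self):
        a = cube_labels(2, 5)
        assert iou(a, a) == 1.0

    def test_disjoint_is_zero(self):
        assert iou(cube_labels(0, 2), cube_labels(4, 6)) == 0.0

    def test_shifted_cube_is_one_third(self):
        a = np.zeros((6, 6, 6), np.uint8)
        b = np.zeros((6, 6, 6), np.uint8)
        a[1:3, 1:3, 1:3] = 1
        b[2:4, 1:3, 1:3] = 1  # shift by 1 along x: overlap 4, union 12
        assert iou(LabelVolume(a), LabelVolume(b)) == pytest.approx(1 / 3)

    def test_auxiliary_merged_into_background(self):
        gt = cube_labels(2, 5)
        pred = LabelVolume(gt.data.copy())
        pred.data[gt.data == 0] = 0
        pred.data[0, 0, 0] = 2  # stray gap prediction must not hurt bone IoU
        assert iou(pred, gt) == 1.0
        gt2 = LabelVolume(gt.data.copy())
        gt2.data[2, 2, 2] = 2  # gap voxel in gt leaves the bone class
        expected = ((gt.data == 1).sum() - 1) / (gt.data == 1).sum()
        assert iou(gt, gt2) == pytest.approx(expected)

    def test_both_empty_defined_as_one(self):
        empty = LabelVolume(np.zeros((4, 4, 4), np.uint8))
        assert iou(empty, empty) == 1.0

    def test_symmetry(self, rng):
        a = LabelVolume((rng.random((6, 6, 6)) > 0.5).astype(np.uint8))
        b = LabelVolume((rng.random((6, 6, 6)) > 0.5).astype(np.uint8))
        assert iou(a, b) == iou(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iou(cube_labels(0, 2, grid=4), cube_labels(0, 2, grid=5))


class TestExtractSurface:
    def test_solid_cube_surface_count(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        assert len(extract_surface(BinaryMask(m))) == 26  # 27 - 1 interior

    def test_single_voxel_is_its_own_surface(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        coords = extract_surface(BinaryMask(m))
        np.testing.assert_array_equal(coords, [[1.0, 1.0, 1.0]])

    def test_thin_plane_is_all_surface(self):
        m = np.zeros((5, 5, 5), bool)
        m[:, :, 2] = True
        assert len(extract_surface(BinaryMask(m))) == 25

    def test_grid_boundary_counts_as_outside(self):
        m = np.ones((3, 3, 3), bool)
        assert len(extract_surface(BinaryMask(m))) == 26  # all but the centre

    def test_spacing_scales_coordinates(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        coords = extract_surface(BinaryMask(m, spacing=(2, 2, 2)))
        np.testing.assert_array_equal(coords, [[2.0, 2.0, 2.0]])

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            extract_surface(BinaryMask(np.zeros((3, 3, 3), bool)))


class TestASSD:
    def test_identical_masks_zero(self, default_phantom):
        _, _, frags = default_phantom
        assert assd(frags.fragments[0], frags.fragments[0]) == 0.0

    def test_shifted_cube_matches_bruteforce(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[1:3, 1:3, 1:3] = True
        b[2:4, 1:3, 1:3] = True
        ma, mb = BinaryMask(a), BinaryMask(b)
        assert assd(ma, mb) == pytest.approx(assd_bruteforce(ma, mb))

    def test_random_masks_match_bruteforce_oracle(self, rng):
        done = 0
        while done < 12:
            a = rng.random((10, 10, 10)) > 0.7
            b = rng.random((10, 10, 10)) > 0.7
            if not a.any() or not b.any():
                continue
            ma, mb = BinaryMask(a), BinaryMask(b)
            assert assd(ma, mb) == pytest.approx(assd_bruteforce(ma, mb), rel=1e-9)
            assert assd(ma, mb) == pytest.approx(assd(mb, ma))
            done += 1

    def test_spacing_linearity(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[1:3, 1:3, 1:3] = True
        b[3:5, 3:5, 3:5] = True
        d1 = assd(BinaryMask(a), BinaryMask(b))
        d2 = assd(BinaryMask(a, spacing=(2, 2, 2)), BinaryMask(b, spacing=(2, 2, 2)))
        assert d2 == pytest.approx(2 * d1)

    def test_translation_distance_nondecreasing(self):
        base = np.zeros((16, 16, 16), bool)
        base[2:6, 2:6, 2:6] = True
        prev = -1.0
        for k in range(0, 6):
            shifted = np.roll(base, k, axis=0)
            d = assd(BinaryMask(base), BinaryMask(shifted))
            assert d >= prev - 1e-12
            prev = d

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            assd(
                BinaryMask(np.zeros((4, 4, 4), bool)),
                BinaryMask(np.ones((4, 4, 4), bool)),
            )


class TestEvaluateCohort:
    def test_single_sample_mean_and_zero_sd(self):
        gt = cube_labels(2, 5)
        res = evaluate_cohort([gt], [gt], ["intact"])
        row = res.summary.iloc[0]
        assert row["miou"] == 1.0 and row["miou_sd"] == 0.0
        assert row["massd"] == 0.0

    def test_overall_mean_is_weighted_type_mean(self):
        gts = [cube_labels(1, 4), cube_labels(2, 6), cube_labels(1, 5)]
        preds = [cube_labels(1, 4), cube_labels(2, 5), cube_labels(1, 5)]
        tags = ["intact", "nondisplaced", "nondisplaced"]
        res = evaluate_cohort(preds, gts, tags)
        s = res.summary.set_index("sample_type")
        weighted = (
            s.loc["intact", "miou"] * s.loc["intact", "n"]
            + s.loc["nondisplaced", "miou"] * s.loc["nondisplaced", "n"]
        ) / 3
        assert s.loc["Overall", "miou"] == pytest.approx(weighted)

    def test_row_ordering_deterministic(self):
        gt = cube_labels(2, 5)
        res = evaluate_cohort(
            [gt, gt, gt], [gt, gt, gt], ["displaced", "intact", "nondisplaced"]
        )
        assert list(res.summary["sample_type"]) == [
            "Overall",
            "intact",
            "nondisplaced",
            "displaced",
        ]

    def test_misaligned_lists_rejected(self):
        gt = cube_labels(2, 5)
        with pytest.raises(ValueError):
            evaluate_cohort([gt], [gt, gt], ["intact"])


class TestPairedTTest:
    def test_identical_scores(self):
        t, p = paired_ttest([0.8, 0.7, 0.9], [0.8, 0.7, 0.9])
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_difference_flagged(self):
        with pytest.warns(RuntimeWarning):
            t, p = paired_ttest([0.9, 0.8, 0.7], [0.8, 0.7, 0.6])
        assert np.isinf(t) and t > 0

    def test_three_pair_example_matches_textbook_formula(self):
        a = np.array([0.80, 0.85, 0.90])
        b = np.array([0.75, 0.80, 0.70])
        d = a - b
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        t, p = paired_ttest(a, b)
        assert t == pytest.approx(expected_t)
        assert 0 < p < 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0, 2.0], [1.0])
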