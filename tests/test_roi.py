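"""ROI geometry: slice selection, square crops, masking, dilation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from lesionroi import (
    AlignmentError,
    ConfigurationError,
    DegenerateInputError,
    bbox_square_roi,
    dilate_mask,
    make_input,
    mask_out,
    select_slices,
)
from lesionroi.cohort import LesionMask
from lesionroi.roi import extract_patient_samples


def mask_with_areas(areas, side=16):
    """3D mask whose per-slice foreground area matches ``areas`` exactly."""
    m = np.zeros((len(areas), side, side), dtype=bool)
    for z, a in enumerate(areas):
        flat = m[z].reshape(-1)
        flat[:a] = True
    return LesionMask(patient_id="T", mask=m)


class TestSelectSlices:
    def test_threshold_scan_matches_bruteforce(self):
        areas = [0, 10, 40, 60, 100, 90, 55, 45, 0]
        sel = select_slices(mask_with_areas(areas), area_fraction=0.5, stride=1)
        # oracle: keep indices with area strictly above half the maximum
        expected = [i for i, a in enumerate(areas) if a > 0.5 * max(areas)]
        assert list(sel.slice_indices) == expected == [3, 4, 5, 6]
        assert sel.max_area_vox == 100

    def test_stride_anchored_at_first_retained(self):
        sel = select_slices(mask_with_areas([7] * 12), area_fraction=0.5, stride=5)
        assert list(sel.slice_indices) == [0, 5, 10]

    def test_max_area_slice_always_survives(self):
        areas = [3, 9, 2]
        sel = select_slices(mask_with_areas(areas), area_fraction=0.99, stride=1)
        assert list(sel.slice_indices) == [1]

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            select_slices(mask_with_areas([0, 0]))

    @pytest.mark.parametrize("kwargs", [{"area_fraction": 0.0}, {"area_fraction": 1.5}, {"stride": 0}])
    def test_bad_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            select_slices(mask_with_areas([5]), **kwargs)


class TestBboxSquare:
    def test_hand_geometry_rectangular_bbox(self):
        image = np.arange(100 * 100, dtype=float).reshape(100, 100)
        mask = np.zeros((100, 100), dtype=bool)
        mask[40:60, 45:55] = True  # bbox 20 x 10 -> side ceil(1.2*20) = 24
        crop = bbox_square_roi(image, mask, expand=0.20)
        assert crop.shape == (24, 24)
        np.testing.assert_array_equal(crop, image[38:62, 38:62])

    def test_expand_zero_square_bbox_is_identity(self):
        image = np.random.default_rng(0).random((30, 30))
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:15, 10:20] = True
        crop = bbox_square_roi(image, mask, expand=0.0)
        np.testing.assert_array_equal(crop, image[5:15, 10:20])

    def test_full_image_bbox_zero_pads(self):
        image = np.ones((100, 100))
        mask = np.ones((100, 100), dtype=bool)
        crop = bbox_square_roi(image, mask, expand=0.20)
        assert crop.shape == (120, 120)
        assert crop[10:110, 10:110].min() == 1.0
        border = np.ones((120, 120), dtype=bool)
        border[10:110, 10:110] = False
        assert np.all(crop[border] == 0.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            bbox_square_roi(np.zeros((5, 5)), np.zeros((5, 5)))


class TestMaskOutAndDilate:
    @given(
        img=hnp.arrays(float, (9, 9), elements=st.floats(0, 100)),
        msk=hnp.arrays(bool, (9, 9)),
    )
    @settings(max_examples=50, deadline=None)
    def test_mask_out_is_elementwise_product(self, img, msk):
        np.testing.assert_array_equal(mask_out(img, msk), img * msk)

    def test_mask_out_shape_mismatch(self):
        with pytest.raises(AlignmentError):
            mask_out(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_zero_margin_is_identity(self):
        m = np.random.default_rng(1).random((12, 12)) > 0.7
        np.testing.assert_array_equal(dilate_mask(m, 0.0, 0.5), m)

    def test_single_pixel_disk_radius_two(self):
        m = np.zeros((7, 7), dtype=bool)
        m[3, 3] = True
        d = dilate_mask(m, margin_mm=1.0, spacing_mm=0.5)  # radius 2 px
        # brute-force oracle over the neighborhood
        expected = np.zeros_like(m)
        for r in range(7):
            for c in range(7):
                if (r - 3) ** 2 + (c - 3) ** 2 <= 4:
                    expected[r, c] = True
        np.testing.assert_array_equal(d, expected)
        assert d.sum() == 13

    @given(msk=hnp.arrays(bool, (14, 14)), margin=st.floats(0, 3))
    @settings(max_examples=40, deadline=None)
    def test_dilation_is_monotone(self, msk, margin):
        d = dilate_mask(msk, margin, 0.5)
        assert np.all(d[msk])  # superset, pixelwise

    def test_negative_margin_rejected(self):
        with pytest.raises(ConfigurationError):
            dilate_mask(np.ones((3, 3), dtype=bool), -1.0, 0.5)


class TestMakeInput:
    @pytest.fixture()
    def phantom_slice(self, tiny_cohort):
        _, pairs = tiny_cohort
        rec, lesion = pairs[0]
        sel = select_slices(lesion)
        z = sel.slice_indices[len(sel.slice_indices) // 2]
        return rec.volume[z], lesion.mask[z]

    def test_original_is_passthrough(self, phantom_slice):
        img, msk = phantom_slice
        np.testing.assert_array_equal(make_input(img, msk, "original"), img)

    def test_precise_zeroes_outside_mask(self, phantom_slice):
        img, msk = phantom_slice
        crop = make_input(img, msk, "precise")
        mask_crop = make_input(msk.astype(float), msk, "precise") > 0
        assert np.all(crop[~mask_crop] == 0)
        assert (crop > 0).sum() <= msk.sum()

    def test_expanded_support_strictly_contains_precise(self, phantom_slice):
        img, msk = phantom_slice
        img = img + 1.0  # make support detectable everywhere
        precise = make_input(img, msk, "precise")
        expanded = make_input(img, msk, "expanded", margin_mm=2.0)
        assert (expanded > 0).sum() > (precise > 0).sum()
        # every precise-supported pixel has a nonzero counterpart: the
        # precise support equals mask area, expanded support the dilated area
        assert (precise > 0).sum() == msk.sum()

    def test_square_outputs(self, phantom_slice):
        img, msk = phantom_slice
        for variant in ("bbox", "precise", "expanded"):
            out = make_input(img, msk, variant)
            assert out.shape[0] == out.shape[1]

    def test_unknown_variant_rejected(self, phantom_slice):
        img, msk = phantom_slice
        with pytest.raises(ConfigurationError):
            make_input(img, msk, "fancy")


def test_shared_selection_across_variants(tiny_cohort):
    _, pairs = tiny_cohort
    rec, lesion = pairs[1]
    sel = select_slices(lesion)
    per_variant = {
        v: extract_patient_samples(rec, lesion, v, selection=sel)
        for v in ("original", "bbox", "precise", "expanded")
    }
    index_sets = {v: [s.slice_index for s in samples] for v, samples in per_variant.items()}
    assert len({tuple(ix) for ix in index_sets.values()}) == 1
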