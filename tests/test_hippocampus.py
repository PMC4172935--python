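"""The hippocampus extraction chain: ROI bookkeeping, noise removal,
trimming, extraction and the end-to-end recovery properties."""

import numpy as np
import pytest
from dataclasses import replace

from hippovol.errors import ValidationError
from hippovol.hippocampus import (
    HippocampusConfig,
    ROIRect,
    default_masks,
    extract_hippocampus,
    extract_roi,
    hippocampus_area,
    hippocampus_pipeline,
    remove_noise,
    trim_region,
)
from hippovol.phantom import PhantomSpec, generate_slice
from hippovol.preprocess import SliceImage, ThreshRange, estimate_thresh

GM_RANGE = ThreshRange(85.0, 140.0)


class TestDefaultMasks:
    def test_reference_size_returns_printed_rectangles(self):
        left, right = default_masks(498, 498)
        assert (left.x1, left.y1, left.x2, left.y2) == (130, 300, 225, 360)
        assert (right.x1, right.y1, right.x2, right.y2) == (280, 300, 375, 360)

    def test_reference_roi_dimensions(self):
        left, right = default_masks(498, 498)
        assert (left.width, left.height) == (95, 60)
        assert (right.width, right.height) == (95, 60)

    def test_half_scale_rounding(self):
        left, _ = default_masks(249, 249)
        assert (left.x1, left.y1, left.x2, left.y2) == (65, 150, 113, 180)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValidationError):
            default_masks(1, 498)


class TestExtractRoi:
    def test_full_image_rect_is_identity(self):
        img = SliceImage(np.arange(20, dtype=float).reshape(4, 5))
        out = extract_roi(img, ROIRect(0, 0, 5, 4))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_offset_bookkeeping(self, noiseless_phantom):
        img, _ = noiseless_phantom
        left, _ = default_masks(img.width, img.height)
        roi = extract_roi(img, left)
        assert roi.pixels[5, 3] == img.pixels[305, 133]
        assert (roi.width, roi.height) == (95, 60)

    def test_out_of_bounds_rect_rejected(self):
        img = SliceImage(np.ones((10, 10)))
        with pytest.raises(ValidationError):
            extract_roi(img, ROIRect(5, 5, 12, 8))


class TestRemoveNoise:
    def _ellipse_image(self):
        yy, xx = np.mgrid[0:60, 0:95].astype(float)
        ell = ((xx - 47) / 20) ** 2 + ((yy - 30) / 12) ** 2 <= 1
        px = np.full((60, 95), 60.0)
        px[ell] = 110.0
        return px, ell

    def test_opening_removes_specks_keeps_ellipse(self):
        px, ell = self._ellipse_image()
        for y, x in [(2, 2), (5, 90), (55, 3), (50, 88), (29, 3)]:
            px[y, x] = 110.0  # isolated 1-px specks
        mask = remove_noise(SliceImage(px), GM_RANGE, opening_radius=1)
        np.testing.assert_array_equal(mask, ell)

    def test_all_background_roi_gives_empty_mask(self, caplog):
        mask = remove_noise(SliceImage(np.full((10, 10), 5.0)), GM_RANGE)
        assert not mask.any()

    def test_idempotence(self):
        px, _ = self._ellipse_image()
        m1 = remove_noise(SliceImage(px), GM_RANGE, opening_radius=1)
        px2 = np.where(m1, 110.0, 0.0)
        m2 = remove_noise(SliceImage(px2), GM_RANGE, opening_radius=1)
        np.testing.assert_array_equal(m1, m2)

    def test_largest_component_tie_break_is_deterministic(self):
        px = np.zeros((20, 20))
        px[2:5, 2:5] = 110.0   # 3x3 block, top-left (2,2)
        px[10:13, 10:13] = 110.0  # equal-size block, later corner
        m = remove_noise(SliceImage(px), GM_RANGE, opening_radius=1)
        assert m[3, 3] and not m[11, 11]


class TestTrimRegion:
    def test_bounding_box_plus_margin(self):
        px = np.zeros((60, 95))
        px[10:30, 5:25] = 110.0
        roi = SliceImage(px)
        cleaned = px > 0
        out = trim_region(roi, cleaned, margin=2)
        assert (out.height, out.width) == (24, 24)

    def test_margin_clipped_at_boundary(self):
        px = np.zeros((20, 20))
        px[0:5, 0:5] = 110.0
        out = trim_region(SliceImage(px), px > 0, margin=3)
        assert (out.height, out.width) == (8, 8)

    def test_component_pixels_all_retained(self):
        px = np.zeros((30, 30))
        px[5:15, 5:20] = 110.0
        cleaned = px > 0
        out = trim_region(SliceImage(px), cleaned, margin=2)
        assert int(out.brain_mask.sum()) == int(cleaned.sum())

    def test_noncomponent_pixels_suppressed(self):
        px = np.full((30, 30), 170.0)
        cleaned = np.zeros((30, 30), dtype=bool)
        cleaned[10:20, 10:20] = True
        out = trim_region(SliceImage(px), cleaned, margin=2)
        assert np.all(out.pixels[~out.brain_mask] == 0)

    def test_empty_mask_yields_zero_area_downstream(self):
        out = trim_region(SliceImage(np.ones((5, 5))), np.zeros((5, 5), bool))
        assert hippocampus_area(extract_hippocampus(out, GM_RANGE)) == 0


class TestExtractHippocampus:
    def test_gm_range_selection_within_component(self):
        px = np.zeros((10, 10))
        px[2:8, 2:8] = 110.0
        px[4, 4] = 170.0  # WM pixel inside the component
        comp = px > 0
        trimmed = SliceImage(px, brain_mask=comp)
        mask = extract_hippocampus(trimmed, GM_RANGE)
        assert mask.sum() == comp.sum() - 1
        assert not mask[4, 4]

    def test_all_wm_trimmed_image_gives_empty_mask(self):
        px = np.full((6, 6), 170.0)
        trimmed = SliceImage(px, brain_mask=np.ones((6, 6), bool))
        assert not extract_hippocampus(trimmed, GM_RANGE).any()

    def test_mask_is_subset_of_component(self, noisy_phantom):
        img, _ = noisy_phantom
        t = estimate_thresh(img)
        left, _ = hippocampus_pipeline(img, t)
        assert not np.any(left.final_mask & ~left.trimmed.brain_mask)


class TestPipeline:
    def test_noiseless_recovery_is_exact(self, noiseless_phantom):
        img, truth = noiseless_phantom
        left, right = hippocampus_pipeline(img, estimate_thresh(img))
        assert left.area == truth.hippo_left_area
        assert right.area == truth.hippo_right_area

    def test_containment_chain(self, noisy_phantom):
        img, _ = noisy_phantom
        t = estimate_thresh(img)
        left, _ = hippocampus_pipeline(img, t)
        roi = left.roi_image
        binarized = roi.pixels >= t.lo
        assert not np.any(left.cleaned_mask & ~binarized)
        assert left.final_mask.sum() <= left.cleaned_mask.sum()

    def test_atrophy_reduces_extracted_areas(self):
        ctl_img, _ = generate_slice(PhantomSpec(noise_sd=8.0, atrophy=0.0), seed=4)
        ad_img, _ = generate_slice(PhantomSpec(noise_sd=8.0, atrophy=0.4), seed=4)
        t_ctl, t_ad = estimate_thresh(ctl_img), estimate_thresh(ad_img)
        l_ctl, r_ctl = hippocampus_pipeline(ctl_img, t_ctl)
        l_ad, r_ad = hippocampus_pipeline(ad_img, t_ad)
        assert l_ad.area < l_ctl.area
        assert r_ad.area < r_ctl.area

    def test_mirror_swaps_left_and_right_exactly(self, noisy_phantom):
        img, _ = noisy_phantom
        mirrored = SliceImage(
            img.pixels[:, ::-1].copy(), brain_mask=img.brain_mask[:, ::-1].copy()
        )
        t = estimate_thresh(img)
        tm = estimate_thresh(mirrored)
        left, right = hippocampus_pipeline(img, t)
        m_left, m_right = hippocampus_pipeline(mirrored, tm)
        assert (m_left.area, m_right.area) == (right.area, left.area)

    def test_translation_invariance_of_area(self):
        spec = PhantomSpec(noise_sd=0.0)
        shifted = replace(
            spec,
            hippo_left_center=(180.0, 327.0),
            hippo_right_center=(330.0, 333.0),
        )
        img1, t1 = generate_slice(spec, seed=0)
        img2, t2 = generate_slice(shifted, seed=0)
        a1 = hippocampus_pipeline(img1, estimate_thresh(img1))
        a2 = hippocampus_pipeline(img2, estimate_thresh(img2))
        assert t1.hippo_left_area == t2.hippo_left_area  # same painted size
        assert a1[0].area == a2[0].area
        assert a1[1].area == a2[1].area

    def test_noisy_recovery_within_ten_percent(self):
        hits = 0
        for seed in range(10):
            img, truth = generate_slice(PhantomSpec(noise_sd=8.0), seed=seed)
            left, right = hippocampus_pipeline(img, estimate_thresh(img))
            if abs(left.area - truth.hippo_left_area) <= 0.1 * truth.hippo_left_area:
                hits += 1
        assert hits >= 9
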