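"""Segmentation, centre-region selection, colour statistics, radius measurement."""

import logging

import numpy as np
import pytest

from capsulecalib import (
    CapsuleImage,
    OpticsParams,
    SegmentationResult,
    centre_region,
    extract_colour_stats,
    measure_radius,
    render_capsule,
    segment_capsule,
)
from capsulecalib.errors import (
    DomainError,
    NoCapsuleError,
    RegionSelectionError,
    UnitError,
)
from conftest import make_disc_image


def disc_seg(shape=(128, 128), centre=(64, 64), radius=40):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    mask = (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= radius**2
    return SegmentationResult(capsule_mask=mask, background_mask=~mask)


class TestCapsuleImage:
    def test_rejects_small_or_non_rgb(self):
        with pytest.raises(DomainError):
            CapsuleImage(pixels=np.zeros((16, 128, 3), dtype=np.uint8))
        with pytest.raises(DomainError):
            CapsuleImage(pixels=np.zeros((64, 64), dtype=np.uint8))

    def test_rejects_out_of_range_floats(self):
        with pytest.raises(DomainError):
            CapsuleImage(pixels=np.full((64, 64, 3), 300.0))


class TestSegmentCapsule:
    def test_disc_area_within_two_percent(self):
        r = 40
        img, _ = make_disc_image(radius=r)
        seg = segment_capsule(CapsuleImage(pixels=img))
        assert seg.capsule_mask.sum() == pytest.approx(np.pi * r**2, rel=0.02)

    def test_masks_partition_the_image(self):
        img, _ = make_disc_image()
        seg = segment_capsule(CapsuleImage(pixels=img))
        assert not np.any(seg.capsule_mask & seg.background_mask)
        assert np.all(seg.capsule_mask | seg.background_mask)

    def test_uniform_image_raises(self):
        uniform = np.full((64, 64, 3), 180, dtype=np.uint8)
        with pytest.raises(NoCapsuleError):
            segment_capsule(CapsuleImage(pixels=uniform))

    def test_near_uniform_noise_raises(self):
        rng = np.random.default_rng(0)
        noisy = np.clip(rng.normal(180, 2, size=(64, 64, 3)), 0, 255).astype(np.uint8)
        with pytest.raises(NoCapsuleError):
            segment_capsule(CapsuleImage(pixels=noisy))

    def test_two_capsules_keeps_only_the_larger(self, caplog):
        img, _ = make_disc_image(shape=(160, 160), centre=(60, 60), radius=35)
        yy, xx = np.ogrid[:160, :160]
        small = (yy - 130) ** 2 + (xx - 130) ** 2 <= 18**2
        img[small] = (120, 110, 100)
        with caplog.at_level(logging.WARNING, logger="capsulecalib.colorimetry"):
            seg = segment_capsule(CapsuleImage(pixels=img))
        assert not seg.capsule_mask[130, 130]
        assert seg.capsule_mask[60, 60]
        assert seg.capsule_mask.sum() == pytest.approx(np.pi * 35**2, rel=0.02)
        assert any("components" in r.message for r in caplog.records)

    def test_hollow_ring_is_filled_to_a_disc(self):
        # zero-thickness capsule: only the refraction rim is visible, the
        # filled mask must still be the full disc
        img = render_capsule(
            50.0, 0.0, OpticsParams(noise_sigma=0.0), scale=0.5, seed=0
        )
        seg = segment_capsule(img)
        r_px = 50.0 / 0.5
        assert seg.capsule_mask.sum() == pytest.approx(np.pi * r_px**2, rel=0.02)

    def test_invariant_to_global_brightness_offset(self):
        img, _ = make_disc_image()
        base = segment_capsule(CapsuleImage(pixels=img)).capsule_mask
        for k in (5, 10, 20):
            shifted = (img.astype(int) + k).astype(np.uint8)  # bg 220 + 20 <= 255
            seg = segment_capsule(CapsuleImage(pixels=shifted))
            assert np.array_equal(seg.capsule_mask, base)


class TestCentreRegion:
    def test_disc_radius_is_fraction_of_equivalent_radius(self):
        seg = disc_seg(radius=100, shape=(256, 256), centre=(128, 128))
        region = centre_region(seg, fraction=0.1)
        # equivalent radius ~100 px, so the region is a disc of radius ~10
        assert region.sum() == pytest.approx(np.pi * 10**2, rel=0.05)
        ys, xs = np.nonzero(region)
        assert ys.mean() == pytest.approx(128, abs=1.0)
        assert xs.mean() == pytest.approx(128, abs=1.0)

    def test_half_fraction_covers_quarter_of_mask_area(self):
        seg = disc_seg(radius=50, shape=(160, 160), centre=(80, 80))
        region = centre_region(seg, fraction=0.5)
        assert region.sum() / seg.capsule_mask.sum() == pytest.approx(0.25, abs=0.02)

    def test_region_is_inside_capsule_mask(self):
        seg = disc_seg()
        region = centre_region(seg, fraction=0.3)
        assert not np.any(region & ~seg.capsule_mask)

    def test_empty_mask_raises(self):
        seg = SegmentationResult(
            capsule_mask=np.zeros((64, 64), bool),
            background_mask=np.ones((64, 64), bool),
        )
        with pytest.raises(RegionSelectionError):
            centre_region(seg)

    def test_eccentric_mask_raises(self):
        # a thin bar: the equivalent-radius disc at the centroid pokes out
        mask = np.zeros((64, 64), bool)
        mask[30:34, 4:60] = True
        seg = SegmentationResult(capsule_mask=mask, background_mask=~mask)
        with pytest.raises(RegionSelectionError):
            centre_region(seg, fraction=0.5)

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 0.6])
    def test_invalid_fraction_rejected(self, fraction):
        with pytest.raises(DomainError):
            centre_region(disc_seg(), fraction=fraction)


class TestExtractColourStats:
    def test_uniform_image_metrics(self):
        img = np.empty((64, 64, 3), dtype=np.uint8)
        img[...] = (200, 150, 100)
        seg = disc_seg(shape=(64, 64), centre=(32, 32), radius=20)
        centre = centre_region(seg, fraction=0.2)
        stats = extract_colour_stats(CapsuleImage(pixels=img), centre, seg)
        assert stats.metric_R_minus_B == pytest.approx(100.0)
        assert stats.metric_R_minus_bg == pytest.approx(0.0)
        assert stats.metric_R == pytest.approx(200.0)

    def test_known_centre_and_background_colours(self):
        img, mask = make_disc_image(
            disc_rgb=(180, 120, 60), bg_rgb=(230, 228, 225), radius=40
        )
        image = CapsuleImage(pixels=img)
        seg = segment_capsule(image)
        centre = centre_region(seg, fraction=0.1)
        stats = extract_colour_stats(image, centre, seg)
        assert stats.R_mean == pytest.approx(180.0, abs=1.0)
        assert stats.metric_R_minus_B == pytest.approx(120.0, abs=2.0)
        assert stats.metric_R_minus_bg == pytest.approx(-50.0, abs=2.0)

    def test_zero_thickness_capsule_matches_background(self):
        image = render_capsule(50.0, 0.0, OpticsParams(noise_sigma=0.0), scale=0.5, seed=0)
        seg = segment_capsule(image)
        centre = centre_region(seg, fraction=0.1)
        stats = extract_colour_stats(image, centre, seg)
        # clear core under a shell-less capsule: centre colour is background
        assert stats.metric_R_minus_bg == pytest.approx(0.0, abs=1.0)

    def test_derived_metric_identities_are_exact(self):
        img, _ = make_disc_image()
        image = CapsuleImage(pixels=img)
        seg = segment_capsule(image)
        stats = extract_colour_stats(image, centre_region(seg), seg)
        assert stats.metric_R == stats.R_mean
        assert stats.metric_R_minus_bg == stats.R_mean - stats.R_bg
        assert stats.metric_R_minus_B == stats.R_mean - stats.B_mean

    def test_empty_centre_mask_raises(self):
        img, _ = make_disc_image()
        seg = segment_capsule(CapsuleImage(pixels=img))
        with pytest.raises(DomainError):
            extract_colour_stats(
                CapsuleImage(pixels=img), np.zeros(img.shape[:2], bool), seg
            )


class TestMeasureRadius:
    def test_disc_radius_with_scale(self):
        seg = disc_seg(radius=100, shape=(256, 256), centre=(128, 128))
        assert measure_radius(seg, scale=2.0) == pytest.approx(200.0, rel=0.02)

    def test_single_pixel_closed_form(self):
        mask = np.zeros((64, 64), bool)
        mask[10, 10] = True
        seg = SegmentationResult(capsule_mask=mask, background_mask=~mask)
        assert measure_radius(seg, scale=3.0) == pytest.approx(np.sqrt(1 / np.pi) * 3.0)

    def test_missing_scale_raises(self):
        with pytest.raises(UnitError):
            measure_radius(disc_seg(), scale=None)

    def test_empty_mask_raises(self):
        mask = np.zeros((64, 64), bool)
        seg = SegmentationResult(capsule_mask=mask, background_mask=~mask)
        with pytest.raises(DomainError):
            measure_radius(seg, scale=1.0)
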