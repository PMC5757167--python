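"""Preprocessing chain: per-stage oracles and pipeline invariants."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse
from skimage.transform import rotate

from leafsrc.imaging import (
    ContourRaster,
    PreprocessConfig,
    PreprocessError,
    align_major_axis,
    denoise,
    extract_contour,
    foreground_angle,
    normalize_raster,
    preprocess,
    remove_background,
    remove_footstalk,
    to_grayscale,
)
from leafsrc.synthleaf import FAMILY_LIBRARY, _render

LUMA = (0.2125, 0.7154, 0.0721)


def ellipse_mask(shape=(201, 201), center=(100, 100), axes=(80, 30)):
    img = np.zeros(shape)
    rr, cc = draw_ellipse(*center, *axes, shape=shape)
    img[rr, cc] = 1.0
    return img


class TestGrayscale:
    def test_gray_input_passes_through(self, rng):
        img = rng.uniform(0, 255, (12, 9))
        assert np.array_equal(to_grayscale(img), img)

    def test_uniform_rgb_maps_to_same_value(self):
        img = np.full((8, 8, 3), 77.0)
        assert np.allclose(to_grayscale(img), 77.0)

    def test_matches_per_pixel_luminance_oracle(self, rng):
        img = rng.uniform(0, 255, (8, 8, 3))
        expected = sum(w * img[..., k] for k, w in enumerate(LUMA))
        assert np.allclose(to_grayscale(img), expected)

    def test_empty_image_rejected(self):
        with pytest.raises(PreprocessError):
            to_grayscale(np.zeros((0, 5)))


class TestBackground:
    def test_threshold_boundary_values(self):
        img = np.array([[10.0, 29.0], [30.0, 200.0]])
        out = remove_background(img, 30)
        assert np.array_equal(out, [[0.0, 0.0], [30.0, 200.0]])

    def test_zero_threshold_is_identity(self, rng):
        img = rng.uniform(0, 255, (6, 6))
        assert np.array_equal(remove_background(img, 0), img)

    def test_all_zero_stays_zero(self):
        assert not remove_background(np.zeros((8, 8)), 30).any()


class TestDenoise:
    def test_constant_image_unchanged(self):
        img = np.full((30, 30), 42.0)
        assert np.allclose(denoise(img, 3), img)

    def test_isolated_salt_pixel_removed(self):
        img = np.zeros((41, 41))
        img[20, 20] = 255.0
        assert denoise(img, 3).max() == 0.0

    def test_matches_bruteforce_windowed_median(self, rng):
        from skimage.morphology import disk

        img = rng.uniform(0, 255, (24, 24))
        r = 2
        foot = disk(r).astype(bool)
        padded = np.pad(img, r, mode="edge")
        expected = np.empty_like(img)
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                window = padded[i : i + 2 * r + 1, j : j + 2 * r + 1]
                expected[i, j] = np.median(window[foot])
        assert np.allclose(denoise(img, r), expected)

    def test_radius_capped_for_tiny_images(self):
        img = np.zeros((29, 21))
        img[10:20, 8:14] = 200.0
        out = denoise(img, 10)  # a true radius-10 disk would erase everything
        assert out.max() > 0

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            denoise(np.zeros((10, 10)), 0)


class TestFootstalk:
    def test_blade_without_stalk_unchanged(self):
        mask = ellipse_mask() > 0
        assert np.array_equal(remove_footstalk(mask), mask)

    def test_stalk_removed_area_recovered(self):
        blade = _render(FAMILY_LIBRARY[0], 160) > 0
        stalked = _render(FAMILY_LIBRARY[0], 160, stalk=(3, 40)) > 0
        out = remove_footstalk(stalked)
        assert abs(out.sum() - blade.sum()) / blade.sum() < 0.05

    def test_only_longest_of_two_stalks_removed(self):
        mask = ellipse_mask((240, 201), (120, 100), (80, 30)) > 0
        mask[:41, 99:102] = True  # 40-long stalk on top (touches row 40=blade)
        mask[200:221, 99:102] = True  # 20-long stalk at bottom
        out = remove_footstalk(mask)
        assert not out[:35, :].any()  # long stalk gone
        assert out[205:215, 99:102].any()  # short stalk retained

    def test_empty_mask_rejected(self):
        with pytest.raises(PreprocessError):
            remove_footstalk(np.zeros((20, 20), dtype=bool))


class TestAlignment:
    @pytest.mark.parametrize("theta", list(range(0, 180, 10)))
    def test_principal_axis_vertical_after_alignment(self, theta):
        img = rotate(ellipse_mask(), theta, resize=True, order=1)
        out = align_major_axis(img)
        assert abs(foreground_angle(out)) < 2.0

    def test_vertical_ellipse_survives(self):
        img = ellipse_mask()
        out = align_major_axis(img)
        assert abs(foreground_angle(out)) < 0.5

    def test_disk_skips_rotation_and_crops(self):
        img = np.zeros((101, 101))
        rr, cc = draw_disk((50, 50), 30)
        img[rr, cc] = 1.0
        out = align_major_axis(img)
        # tight crop of an untouched disk: bounding square of the diameter
        assert out.shape[0] == out.shape[1]
        assert abs(out.shape[0] - 59) <= 2

    def test_no_foreground_rejected(self):
        with pytest.raises(PreprocessError):
            align_major_axis(np.zeros((10, 10)))


class TestContour:
    def test_rectangle_perimeter(self):
        img = np.zeros((40, 30))
        img[5:35, 5:25] = 1.0
        edges = extract_contour(img)
        # 1-px boundary of a 30x20 rectangle, allowing corner effects
        perimeter = 2 * (30 + 20) - 4
        assert abs(edges.sum() - perimeter) / perimeter < 0.1

    def test_disk_edge_count_near_circumference(self):
        img = np.zeros((101, 101))
        rr, cc = draw_disk((50, 50), 30)
        img[rr, cc] = 1.0
        edges = extract_contour(img)
        assert abs(edges.sum() - 2 * np.pi * 30) / (2 * np.pi * 30) < 0.15

    def test_border_touching_foreground_keeps_closed_boundary(self):
        img = ellipse_mask()
        cropped = img[20:181, 70:131]  # foreground touches every border
        edges = extract_contour(cropped)
        rr = np.nonzero(edges)[0]
        interior = range(rr.min() + 2, rr.max() - 1)
        assert all((rr == r).sum() >= 2 for r in interior)

    def test_constant_image_rejected(self):
        with pytest.raises(PreprocessError):
            extract_contour(np.zeros((20, 20)))


class TestNormalize:
    def test_output_is_32x32_in_unit_range(self):
        img = ellipse_mask()
        out = normalize_raster(img)
        assert out.pixels.shape == (32, 32)
        assert out.pixels.min() >= 0 and out.pixels.max() <= 1

    def test_translation_invariance_via_cropping(self):
        contour = extract_contour(ellipse_mask())
        a = np.pad(contour, ((5, 40), (17, 3)))
        b = np.pad(contour, ((33, 2), (0, 50)))
        ra, rb = normalize_raster(a), normalize_raster(b)
        assert np.allclose(ra.pixels, rb.pixels)

    def test_empty_contour_rejected(self):
        with pytest.raises(PreprocessError):
            normalize_raster(np.zeros((64, 64)))


class TestPipeline:
    def test_clean_fixture_yields_valid_raster(self):
        raster = preprocess(_render(FAMILY_LIBRARY[1], 160), source_id="fix")
        assert isinstance(raster, ContourRaster)
        assert raster.pixels.shape == (32, 32)
        assert raster.source_id == "fix"

    def test_rotation_tolerance(self):
        from skimage.morphology import dilation

        base = _render(FAMILY_LIBRARY[1], 160, rotation_deg=20.0)
        rot = _render(FAMILY_LIBRARY[1], 160, rotation_deg=110.0)
        a = preprocess(base).pixels > 0.3
        b = preprocess(rot).pixels > 0.3
        # thin contours: a pixel "matches" when the other raster has
        # support within one pixel
        unmatched = (a & ~dilation(b)).sum() + (b & ~dilation(a)).sum()
        assert unmatched / max(a.sum() + b.sum(), 1) < 0.10

    def test_alignment_idempotent_at_full_resolution(self):
        # re-running the alignment stage on its own output must be a no-op
        # up to interpolation (the square raster destroys the aspect, so
        # idempotence is only well-posed before normalization)
        img = rotate(ellipse_mask(), 37.0, resize=True, order=1)
        once = align_major_axis(img)
        twice = align_major_axis(once)
        assert abs(foreground_angle(twice)) < 0.5
        h = min(once.shape[0], twice.shape[0])
        w = min(once.shape[1], twice.shape[1])
        changed = (np.abs(once[:h, :w] - twice[:h, :w]) > 0.1).mean()
        assert changed < 0.05

    def test_normalize_idempotent_on_its_output(self):
        raster = preprocess(_render(FAMILY_LIBRARY[0], 160, rotation_deg=30.0))
        again = normalize_raster(raster.pixels)
        assert np.allclose(again.pixels, raster.pixels, atol=1e-9)

    def test_blank_image_error_names_stage(self):
        with pytest.raises(PreprocessError) as err:
            preprocess(np.zeros((64, 64)))
        assert err.value.stage

    def test_out_size_configurable(self):
        cfg = PreprocessConfig(out_size=16)
        raster = preprocess(_render(FAMILY_LIBRARY[0], 160), cfg)
        assert raster.pixels.shape == (16, 16)

    def test_silhouette_atom_mode(self):
        cfg = PreprocessConfig(contour_atoms=False)
        raster = preprocess(_render(FAMILY_LIBRARY[0], 160), cfg)
        # silhouettes are filled: far more foreground than a contour
        assert (raster.pixels > 0.5).sum() > 300
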