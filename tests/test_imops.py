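import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from neuromorph import (
    GrayImage,
    analyze_particles,
    binary_dilate,
    binary_erode,
    count_particles,
    filter_particles,
    gaussian_blur,
    grayscale_open,
    mask_and,
    mask_multiply_gray,
    mask_subtract,
    skeletonize,
    subtract_background,
    subtract_clamped,
    threshold_range,
)

from _util import (
    dilate_oracle,
    erode_oracle,
    erode_oracle_loops,
    flood_fill_components,
)


def gray(arr, gmax=255):
    return GrayImage(np.asarray(arr, dtype=np.uint8 if gmax <= 255 else np.uint16), gmax)


class TestGrayImage:
    def test_rejects_out_of_range_and_bad_gmax(self):
        with pytest.raises(ValueError):
            GrayImage(np.full((4, 4), 300, np.uint16), 255)
        with pytest.raises(ValueError):
            GrayImage(np.zeros((4, 4), np.uint8), 1000)
        with pytest.raises(ValueError):
            GrayImage(np.zeros((4, 4), float), 255)


class TestGaussianBlur:
    def test_constant_preserved(self):
        img = gray(np.full((16, 16), 37))
        assert (gaussian_blur(img, 2.0).pixels == 37).all()

    def test_single_pixel_matches_kernel_oracle(self):
        px = np.zeros((41, 41), np.uint8)
        px[20, 20] = 200
        out = gaussian_blur(gray(px), 2.0).pixels.astype(int)
        x = np.arange(-20, 21)
        k = np.exp(-(x**2) / (2 * 2.0**2))
        k /= k.sum()
        oracle = np.rint(200 * np.outer(k, k)).astype(int)
        assert np.array_equal(out, oracle)

    def test_total_intensity_conserved_within_rounding(self):
        rng = np.random.default_rng(0)
        px = rng.integers(0, 200, (64, 64)).astype(np.uint8)
        out = gaussian_blur(gray(px), 2.0).pixels
        assert abs(int(out.sum()) - int(px.sum())) <= px.size  # +-0.5/px rounding

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_blur(gray(np.zeros((4, 4))), 0.0)


class TestSubtractClamped:
    def test_identity_and_clamping(self):
        a = gray([[5, 200], [9, 9]])
        b = gray([[9, 60], [9, 9]])
        out = subtract_clamped(a, b).pixels
        assert out.tolist() == [[0, 140], [0, 0]]
        assert (subtract_clamped(a, a).pixels == 0).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_clamped(gray(np.zeros((3, 3))), gray(np.zeros((4, 4))))


class TestThresholdRange:
    def test_full_range_and_inclusive_bounds(self):
        img = gray([[0, 10, 20]])
        assert threshold_range(img, 0, 255).all()
        assert threshold_range(img, 0, 10).tolist() == [[True, True, False]]
        assert threshold_range(img, 10, 10).tolist() == [[False, True, False]]

    def test_lo_above_hi_rejected(self):
        with pytest.raises(ValueError):
            threshold_range(gray(np.zeros((2, 2))), 5, 3)


class TestSubtractBackground:
    def test_constant_maps_to_zero(self):
        img = gray(np.full((80, 300), 37))
        assert (subtract_background(img, 50).pixels == 0).all()

    def test_slow_ramp_flattened(self):
        ramp = np.tile(np.linspace(0, 30, 1000), (60, 1))
        img = gray(np.rint(ramp))
        assert subtract_background(img, 50).pixels.max() < 5

    def test_thin_line_keeps_contrast_above_flattened_ramp(self):
        arr = np.tile(np.linspace(0, 30, 1000), (60, 1))
        arr[29:32, :] += 100
        out = subtract_background(gray(np.rint(arr)), 50).pixels.astype(int)
        assert (out[30] - np.maximum(out[20], out[40])).min() >= 80


class TestCountMorphology:
    def test_erode7_three_pixel_line_keeps_interior_only(self):
        m = np.zeros((11, 12), bool)
        m[5, 5:8] = True
        assert np.argwhere(binary_erode(m, 1, 7)).tolist() == [[5, 6]]

    def test_erode7_removes_isolated_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert not binary_erode(m, 1, 7).any()

    def test_erode7_square_matches_per_pixel_oracle(self):
        m = np.zeros((14, 14), bool)
        m[2:12, 2:12] = True
        out = binary_erode(m, 1, 7)
        assert np.array_equal(out, erode_oracle_loops(m, 7))
        assert out[2, 2] and out[2, 11]  # corners have only 5 bg neighbors

    def test_dilate_single_pixel_becomes_3x3(self):
        m = np.zeros((7, 7), bool)
        m[3, 3] = True
        out = binary_dilate(m, 1, 1)
        assert out.sum() == 9 and out[2:5, 2:5].all()

    def test_dilate_empty_stays_empty(self):
        assert not binary_dilate(np.zeros((6, 6), bool), 1, 1).any()

    def test_dilate_disk_grows_by_boundary_ring(self):
        yy, xx = np.mgrid[0:30, 0:30]
        disk = np.hypot(yy - 15, xx - 15) <= 10
        assert np.array_equal(binary_dilate(disk, 1, 1), dilate_oracle(disk, 1))

    @pytest.mark.parametrize("count", [1, 3, 7, 8])
    def test_random_masks_match_shift_oracle(self, count, rng):
        for _ in range(25):
            m = rng.random((48, 48)) < 0.45
            assert np.array_equal(binary_erode(m, 1, count), erode_oracle(m, count))
            assert np.array_equal(binary_dilate(m, 1, count), dilate_oracle(m, count))

    def test_erode_dilate_duality_on_padded_masks(self, rng):
        for _ in range(30):
            m = np.pad(rng.random((24, 24)) < 0.4, 2)
            count = int(rng.integers(1, 9))
            d = binary_dilate(m, 1, count)
            e = ~binary_erode(~m, 1, count)
            assert np.array_equal(d[2:-2, 2:-2], e[2:-2, 2:-2])

    def test_parameter_validation(self):
        m = np.zeros((4, 4), bool)
        with pytest.raises(ValueError):
            binary_erode(m, 0, 1)
        with pytest.raises(ValueError):
            binary_dilate(m, 1, 9)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(mask=arrays(bool, (16, 16)), count=st.integers(1, 8))
    def test_extensivity_and_count_monotonicity(self, mask, count):
        eroded = binary_erode(mask, 1, count)
        dilated = binary_dilate(mask, 1, count)
        assert (eroded <= mask).all()
        assert (mask <= dilated).all()
        if count < 8:
            # a stricter count erodes less and dilates less
            assert (binary_erode(mask, 1, count + 1) >= eroded).all()
            assert (binary_dilate(mask, 1, count + 1) <= dilated).all()


class TestGrayscaleOpen:
    def test_idempotent_on_constant(self):
        img = gray(np.full((20, 20), 42))
        assert (grayscale_open(img, 3).pixels == 42).all()

    def test_removes_thin_line_keeps_wide_disk(self):
        arr = np.full((50, 50), 10, np.uint8)
        arr[24:26, 5:45] = 200
        assert grayscale_open(gray(arr), 3).pixels.max() <= 10
        yy, xx = np.mgrid[0:50, 0:50]
        disk = np.where(np.hypot(yy - 25, xx - 25) <= 15, 200, 10).astype(np.uint8)
        opened = grayscale_open(gray(disk), 3).pixels
        assert opened[25, 25] == 200

    def test_anti_extensive(self, rng):
        for _ in range(10):
            arr = (rng.random((40, 40)) * 255).astype(np.uint8)
            assert (grayscale_open(gray(arr), 2).pixels <= arr).all()


class TestSkeletonize:
    def test_one_pixel_line_unchanged(self):
        m = np.zeros((5, 9), bool)
        m[2, 1:8] = True
        assert np.array_equal(skeletonize(m), m)

    def test_solid_bar_thins_to_single_path(self):
        m = np.zeros((9, 27), bool)
        m[3:6, 3:24] = True
        s = skeletonize(m)
        assert 19 <= s.sum() <= 23
        assert count_particles(s) == 1

    def test_disjoint_blobs_stay_disjoint(self):
        m = np.zeros((20, 40), bool)
        m[4:9, 4:9] = True
        m[12:17, 25:31] = True
        assert count_particles(skeletonize(m)) == 2

    def test_properties_on_random_blob_masks(self):
        yy, xx = np.mgrid[0:64, 0:64]
        for seed in range(200):
            r = np.random.default_rng(seed)
            m = np.zeros((64, 64), bool)
            for _ in range(int(r.integers(2, 7))):
                cy, cx, rad = r.uniform(8, 56), r.uniform(8, 56), r.uniform(3, 9)
                m |= np.hypot(yy - cy, xx - cx) <= rad
            s = skeletonize(m)
            assert (s <= m).all()
            assert count_particles(s) == count_particles(m)
            assert not (s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]).any()


class TestMaskAlgebra:
    def test_subtract_self_is_empty(self, rng):
        m = rng.random((10, 10)) < 0.5
        assert not mask_subtract(m, m).any()

    def test_and_is_intersection(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[1, 1] = a[1, 2] = True
        b[1, 2] = b[2, 2] = True
        assert np.argwhere(mask_and(a, b)).tolist() == [[1, 2]]

    def test_multiply_gray_identity_and_zero(self):
        img = gray(np.arange(16).reshape(4, 4))
        assert np.array_equal(mask_multiply_gray(img, np.ones((4, 4), bool)).pixels,
                              img.pixels)
        assert (mask_multiply_gray(img, np.zeros((4, 4), bool)).pixels == 0).all()


class TestAnalyzeParticles:
    def test_size_filter_example(self):
        m = np.zeros((40, 40), bool)
        m[1, 1:6] = True          # area 5
        m[10:14, 10:15] = True    # area 20
        m[20:30, 20:30] = True    # area 100
        parts = analyze_particles(m, 20, np.inf)
        assert len(parts) == 2 and sum(p.area for p in parts) == 120

    def test_empty_mask(self):
        assert analyze_particles(np.zeros((5, 5), bool)) == []

    def test_diagonal_chain_is_one_particle(self):
        m = np.zeros((10, 10), bool)
        for i in range(7):
            m[i + 1, i + 1] = True
        parts = analyze_particles(m)
        assert len(parts) == 1 and parts[0].area == 7

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(15):
            m = rng.random((32, 32)) < 0.35
            comps = flood_fill_components(m)
            parts = analyze_particles(m)
            assert len(parts) == len(comps)
            assert sorted(p.area for p in parts) == sorted(len(c) for c in comps)

    def test_areas_sum_to_foreground_count(self, rng):
        m = rng.random((50, 50)) < 0.4
        assert sum(p.area for p in analyze_particles(m)) == int(m.sum())

    def test_filter_particles_removes_small(self):
        m = np.zeros((20, 20), bool)
        m[1, 1:4] = True
        m[10:16, 10:16] = True
        kept = filter_particles(m, min_size=10)
        assert kept.sum() == 36
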