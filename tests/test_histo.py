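"""Histomorphometry stages: features, thresholding, separation, shapes, statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

from marrowniche.histo import (
    AdipocyteObject,
    Image2D,
    MorphometrySummary,
    ROIMask,
    SegmentationParams,
    compare_groups,
    crack_perimeter,
    morphometry,
    neighborhood_features,
    segment_image,
    separate_clusters,
    shape_filter,
    threshold_adipocytes,
)
from marrowniche.synth import MarrowImageParams, gen_marrow_image


def _gray_image(arr, px=1.0):
    return Image2D(pixels=np.asarray(arr, dtype=np.uint8), pixel_size_um=px)


class TestNeighborhoodFeatures:
    def test_constant_image(self):
        img = _gray_image(np.full((9, 9), 42))
        f = neighborhood_features(img, 2)
        assert np.allclose(f[..., 0], 42.0)
        assert np.allclose(f[..., 1], 0.0)
        assert np.allclose(f[..., 2], 0.0)

    def test_isolated_bright_pixel_removed_by_median(self):
        arr = np.full((5, 5), 10)
        arr[2, 2] = 255
        f = neighborhood_features(_gray_image(arr), 1)
        assert f[2, 2, 0] == pytest.approx(10.0)  # 3x3 median ignores the outlier

    def test_product_channel_is_median_times_std(self):
        rng = np.random.default_rng(0)
        img = _gray_image(rng.integers(0, 255, size=(20, 20)))
        f = neighborhood_features(img, 2)
        assert np.allclose(f[..., 2], f[..., 0] * f[..., 1])

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError):
            neighborhood_features(_gray_image(np.zeros((10, 10))), 6)


class TestThreshold:
    def _setup(self, noise=0.0, texture=0.0, seed=0):
        params = MarrowImageParams(
            width_px=384, height_px=384, n_adipocytes=12,
            background_noise_sd=noise, texture_amplitude=texture, seed=seed,
        )
        return gen_marrow_image(params)

    def test_empty_roi_rejected(self):
        img, roi, _ = self._setup()
        empty = ROIMask(mask=np.zeros_like(roi.mask), pixel_size_um=1.0)
        f = neighborhood_features(img, 1)
        with pytest.raises(ValueError, match="ROI"):
            threshold_adipocytes(f, empty, SegmentationParams())

    def test_noiseless_mask_matches_planted_vacuoles(self):
        img, roi, truth = self._setup(noise=0.0, texture=0.0, seed=3)
        params = SegmentationParams(window_radius_px=1)
        mask = threshold_adipocytes(neighborhood_features(img, 1), roi, params)
        planted = truth.label_map > 0
        jaccard = (mask & planted).sum() / (mask | planted).sum()
        assert jaccard >= 0.98

    def test_raising_luminance_threshold_shrinks_mask(self):
        img, roi, _ = self._setup(noise=5.0, texture=12.0, seed=4)
        f = neighborhood_features(img, 3)
        masks = []
        for thr in (210.0, 225.0, 240.0):
            p = SegmentationParams(luminance_threshold=thr, texture_threshold=1e9)
            masks.append(threshold_adipocytes(f, roi, p))
        assert (masks[1] & ~masks[0]).sum() == 0
        assert (masks[2] & ~masks[1]).sum() == 0

    def test_constant_channel_auto_threshold_rejected(self):
        img = _gray_image(np.full((64, 64), 100))
        roi = ROIMask(mask=np.ones((64, 64), bool), pixel_size_um=1.0)
        f = neighborhood_features(img, 2)
        with pytest.raises(ValueError, match="fixed threshold"):
            threshold_adipocytes(f, roi, SegmentationParams())

    def test_interior_holes_filled(self):
        mask_img = np.full((64, 64), 180)
        rr, cc = draw_disk((32, 32), 15)
        mask_img[rr, cc] = 250
        mask_img[32, 32] = 180  # a one-pixel hole
        roi = ROIMask(mask=np.ones((64, 64), bool), pixel_size_um=1.0)
        f = neighborhood_features(_gray_image(mask_img), 1)
        out = threshold_adipocytes(
            f, roi, SegmentationParams(luminance_threshold=215.0, texture_threshold=1e9)
        )
        assert out[32, 32]


class TestSeparateClusters:
    def test_single_disk_one_label(self):
        mask = np.zeros((80, 80), bool)
        rr, cc = draw_disk((40, 40), 25)
        mask[rr, cc] = True
        labels = separate_clusters(mask, 1.0, 15.0)
        assert labels.max() == 1

    def test_two_overlapping_disks_split(self):
        # radius 30 um disks overlapping ~20%: two labels, centroids near truth
        mask = np.zeros((160, 200), bool)
        centers = [(80, 60), (80, 114)]  # distance 54 = 2r - 6
        for c in centers:
            rr, cc = draw_disk(c, 30)
            mask[rr, cc] = True
        labels = separate_clusters(mask, 1.0, 15.0)
        assert labels.max() == 2
        found = ndi.center_of_mass(mask, labels, [1, 2])
        for c in centers:
            d = min(math.hypot(f[0] - c[0], f[1] - c[1]) for f in found)
            assert d <= 5.0

    def test_disjoint_blobs_label_count(self):
        mask = np.zeros((120, 120), bool)
        for c in [(20, 20), (60, 60), (100, 30)]:
            rr, cc = draw_disk(c, 10)
            mask[rr, cc] = True
        labels = separate_clusters(mask, 1.0, 15.0)
        assert labels.max() == 3

    def test_foreground_conserved_exactly(self):
        img, roi, _ = gen_marrow_image(
            MarrowImageParams(width_px=384, height_px=384, n_adipocytes=14,
                              cluster_fraction=0.5, seed=5)
        )
        f = neighborhood_features(img, 3)
        mask = threshold_adipocytes(f, roi, SegmentationParams())
        labels = separate_clusters(mask, 1.0, 15.0)
        assert (labels > 0).sum() == mask.sum()

    def test_empty_mask(self):
        labels = separate_clusters(np.zeros((10, 10), bool), 1.0, 15.0)
        assert labels.max() == 0


class TestShapeFilter:
    @staticmethod
    def _labels_from_mask(mask):
        return mask.astype(np.int32)

    @pytest.mark.parametrize("r", [10, 20, 30, 45, 60])
    def test_disk_form_factor_near_one(self, r):
        mask = np.zeros((2 * r + 9, 2 * r + 9), bool)
        rr, cc = draw_disk((r + 4, r + 4), r + 0.5)
        mask[rr, cc] = True
        objs = shape_filter(
            self._labels_from_mask(mask), 1.0,
            SegmentationParams(min_area_um2=50.0, max_area_um2=1e6),
        )
        assert len(objs) == 1
        assert 0.90 <= objs[0].form_factor <= 1.05

    def test_rectangle_form_factor_closed_form(self):
        # 100x4 px: perimeter 2(100+4)=208, area 400 -> 4*pi*400/208^2
        mask = np.zeros((20, 120), bool)
        mask[8:12, 10:110] = True
        assert crack_perimeter(mask) == pytest.approx(208.0)
        objs = shape_filter(
            self._labels_from_mask(mask), 1.0,
            SegmentationParams(min_area_um2=50.0, max_area_um2=1e6, min_form_factor=0.0),
        )
        expected = 4 * math.pi * 400 / 208**2
        assert objs[0].form_factor == pytest.approx(expected, abs=1e-3)

    def test_elongated_rectangle_removed_by_default_cut(self):
        mask = np.zeros((20, 120), bool)
        mask[8:12, 10:110] = True
        objs = shape_filter(
            self._labels_from_mask(mask), 1.0,
            SegmentationParams(min_area_um2=50.0, max_area_um2=1e6),  # min_ff 0.5
        )
        assert objs == []

    def test_area_band(self):
        mask = np.zeros((40, 40), bool)
        rr, cc = draw_disk((20, 20), 5)  # area ~78 px
        mask[rr, cc] = True
        small_removed = shape_filter(
            self._labels_from_mask(mask), 1.0, SegmentationParams(min_area_um2=200.0)
        )
        assert small_removed == []
        kept = shape_filter(
            self._labels_from_mask(mask), 1.0,
            SegmentationParams(min_area_um2=50.0, max_area_um2=1e4),
        )
        assert len(kept) == 1

    def test_monotone_in_filter_strictness(self):
        img, roi, _ = gen_marrow_image(
            MarrowImageParams(width_px=384, height_px=384, n_adipocytes=15, seed=6)
        )
        f = neighborhood_features(img, 3)
        mask = threshold_adipocytes(f, roi, SegmentationParams())
        labels = separate_clusters(mask, 1.0, 15.0)
        base = SegmentationParams(min_area_um2=200.0, max_area_um2=15000.0, min_form_factor=0.5)
        n_base = len(shape_filter(labels, 1.0, base))
        stricter_ff = SegmentationParams(min_area_um2=200.0, max_area_um2=15000.0, min_form_factor=0.8)
        narrower = SegmentationParams(min_area_um2=400.0, max_area_um2=8000.0, min_form_factor=0.5)
        assert len(shape_filter(labels, 1.0, stricter_ff)) <= n_base
        assert len(shape_filter(labels, 1.0, narrower)) <= n_base

    def test_physical_units(self):
        mask = np.zeros((30, 30), bool)
        mask[10:20, 10:20] = True  # 10x10 px square
        objs = shape_filter(
            self._labels_from_mask(mask), 2.0,
            SegmentationParams(min_area_um2=100.0, max_area_um2=1e4, min_form_factor=0.0),
        )
        assert objs[0].area_um2 == pytest.approx(400.0)  # 100 px * 4 um^2
        assert objs[0].perimeter_um == pytest.approx(80.0)  # 40 px * 2 um

    def test_bad_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            shape_filter(np.ones((5, 5), np.int32), 0.0, SegmentationParams())


class TestMorphometry:
    def _roi(self, n_px, px=1.0):
        side = int(math.isqrt(n_px))
        mask = np.zeros((side + 2, max(side + 2, (n_px // side) + 2)), bool)
        count = 0
        for r in range(mask.shape[0]):
            for c in range(mask.shape[1]):
                if count < n_px:
                    mask[r, c] = True
                    count += 1
        return ROIMask(mask=mask, pixel_size_um=px)

    def test_density_arithmetic(self):
        # 10 objects over 2 mm^2 -> 5 per mm^2
        roi = ROIMask(mask=np.ones((2000, 1000), bool), pixel_size_um=1.0)  # 2 mm^2
        objs = [
            AdipocyteObject(label=i, area_um2=500.0, perimeter_um=80.0,
                            form_factor=0.95, centroid=(0, 0), bbox=(0, 0, 1, 1))
            for i in range(10)
        ]
        s = morphometry(objs, roi)
        assert s.density_per_mm2 == pytest.approx(5.0)
        assert s.density_per_mm2 == s.n_adipocytes / s.roi_area_mm2

    def test_empty_objects(self):
        roi = ROIMask(mask=np.ones((100, 100), bool), pixel_size_um=1.0)
        s = morphometry([], roi)
        assert s.n_adipocytes == 0
        assert s.density_per_mm2 == 0.0
        assert s.sizes_um2 == []
        assert math.isnan(s.mean_size_um2)

    def test_zero_area_rejected(self):
        roi = ROIMask(mask=np.zeros((10, 10), bool), pixel_size_um=1.0)
        with pytest.raises(ValueError):
            morphometry([], roi)


class TestCompareGroups:
    def test_identical_groups_p_near_one(self):
        u, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_fully_separated_small_groups(self):
        # all 4,5,6 above all 1,2,3: U=0, exact two-sided p = 2/20
        u, p = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u in (0.0, 9.0)
        assert p == pytest.approx(0.1)

    def test_exact_matches_permutation_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            n_a = int(rng.integers(3, 6))
            n_b = int(rng.integers(3, 13 - n_a))
            a = rng.integers(0, 6, size=n_a).astype(float)  # ties likely
            b = rng.integers(0, 6, size=n_b).astype(float)
            _, p_exact = compare_groups(a, b)
            # Monte-Carlo permutation estimate of the same two-sided p
            pooled = np.concatenate([a, b])
            from scipy.stats import rankdata

            def u_of(idx):
                ranks = rankdata(pooled)
                return ranks[list(idx)].sum() - n_a * (n_a + 1) / 2

            u_obs = u_of(range(n_a))
            lows = highs = total = 0
            for _ in range(20000):
                idx = rng.choice(n_a + n_b, size=n_a, replace=False)
                u = u_of(idx)
                total += 1
                lows += u <= u_obs + 1e-9
                highs += u >= u_obs - 1e-9
            p_mc = min(1.0, 2.0 * min(lows, highs) / total)
            assert abs(p_exact - p_mc) < 0.02

    def test_large_samples_use_asymptotic(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.8, 1, 40)
        from scipy.stats import mannwhitneyu

        u, p = compare_groups(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestPipelineProperties:
    def test_scale_equivariance(self):
        # same scene at half the pixel size (2x upsampled): physical results agree
        img, roi, truth = gen_marrow_image(
            MarrowImageParams(width_px=384, height_px=384, n_adipocytes=10, seed=7)
        )
        objs1, _, s1 = segment_image(img, roi)
        up = np.kron(img.pixels, np.ones((2, 2, 1))).astype(np.uint8)
        roi_up = np.kron(roi.mask, np.ones((2, 2), bool))
        img2 = Image2D(pixels=up, pixel_size_um=0.5)
        roi2 = ROIMask(mask=roi_up, pixel_size_um=0.5)
        objs2, _, s2 = segment_image(img2, roi2)
        assert s2.n_adipocytes == s1.n_adipocytes
        assert s2.density_per_mm2 == pytest.approx(s1.density_per_mm2, rel=0.02)
        assert s2.mean_size_um2 == pytest.approx(s1.mean_size_um2, rel=0.02)

    def test_count_recovery_on_default_benchmark(self):
        hits = 0
        for seed in range(3):
            img, roi, truth = gen_marrow_image(MarrowImageParams(seed=40 + seed))
            _, _, summary = segment_image(img, roi)
            hits += abs(summary.n_adipocytes - truth.true_count) <= 0.05 * truth.true_count
        assert hits == 3
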