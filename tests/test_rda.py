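"""Region-detection algorithm stages against independent oracles."""

import numpy as np
import pytest

from ihcquant import CellSource, DiameterRange, ImageRecord
from ihcquant.rda import (
    DegenerateHistogramError,
    DetectOption,
    LabImage,
    cluster_mask,
    extract_cells,
    grey_from_lab,
    otsu3_from_hist,
    otsu3_thresholds,
    rda_detect,
    rgb_to_lab,
    seeded_kmeans4,
    split_joined_high,
    threshold_below,
)

from conftest import CORE_RANGE, disc_mask


def lab_oracle(rgb):
    """Independent sRGB (D65) -> XYZ -> CIELAB computation."""
    c = np.array(rgb, dtype=np.float64) / 255.0
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    M = np.array([[0.4124, 0.3576, 0.1805],
                  [0.2126, 0.7152, 0.0722],
                  [0.0193, 0.1192, 0.9505]])
    xyz = M @ lin
    white = np.array([0.95047, 1.0, 1.08883])
    t = xyz / white
    f = np.where(t > (6 / 29) ** 3, np.cbrt(t), t / (3 * (6 / 29) ** 2) + 4 / 29)
    L = 116 * f[1] - 16
    return L, 500 * (f[0] - f[1]), 200 * (f[1] - f[2])


def one_pixel(rgb):
    return ImageRecord(np.array([[rgb]], dtype=np.uint8))


class TestRgbToLab:
    @pytest.mark.parametrize("rgb, expect_L", [
        ((255, 255, 255), 255), ((0, 0, 0), 0),
    ])
    def test_extremes_map_to_neutral_ab(self, rgb, expect_L):
        lab = rgb_to_lab(one_pixel(rgb))
        assert lab.L[0, 0] == expect_L
        assert abs(int(lab.a[0, 0]) - 128) <= 1
        assert abs(int(lab.b[0, 0]) - 128) <= 1

    def test_matches_standard_formula_oracle(self):
        rng = np.random.default_rng(0)
        for rgb in rng.integers(0, 256, size=(20, 3)):
            lab = rgb_to_lab(one_pixel(tuple(rgb)))
            L, a, b = lab_oracle(rgb)
            assert abs(lab.L[0, 0] - L * 255 / 100) <= 1.0
            assert abs(lab.a[0, 0] - (a + 128)) <= 1.0
            assert abs(lab.b[0, 0] - (b + 128)) <= 1.0

    def test_mid_grey_is_neutral_with_intermediate_lightness(self):
        lab = rgb_to_lab(one_pixel((128, 128, 128)))
        assert 0 < lab.L[0, 0] < 255
        assert abs(int(lab.a[0, 0]) - 128) <= 1
        assert abs(int(lab.b[0, 0]) - 128) <= 1


def lab_from_products(L_row, b_row):
    L = np.array([L_row], dtype=np.uint8)
    b = np.array([b_row], dtype=np.uint8)
    return LabImage(L, np.full_like(L, 128), b)


class TestGreyFromLab:
    def test_constant_image_normalizes_to_zero(self):
        lab = lab_from_products([7, 7, 7], [9, 9, 9])
        assert (grey_from_lab(lab) == 0).all()

    def test_normalization_endpoints_and_midpoint(self):
        # products {100, 300} -> {0, 255}; {100, 200, 300} -> {0, 128, 255}
        assert grey_from_lab(lab_from_products([10, 10], [10, 30])).tolist() == [[0, 255]]
        assert grey_from_lab(lab_from_products([10, 10, 10], [10, 20, 30])
                             ).tolist() == [[0, 128, 255]]

    def test_invariant_under_consistent_pixel_permutation(self):
        rng = np.random.default_rng(3)
        L = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        b = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        perm = rng.permutation(64)
        g1 = grey_from_lab(LabImage(L, np.full_like(L, 128), b)).ravel()[perm]
        g2 = grey_from_lab(LabImage(
            L.ravel()[perm].reshape(8, 8), np.full_like(L, 128),
            b.ravel()[perm].reshape(8, 8))).ravel()
        assert (g1 == g2).all()


from _oracles import otsu3_oracle


class TestOtsu3:
    def test_four_equal_spikes_split_just_above_each_value(self):
        img = np.repeat([10, 90, 170, 250], 16).astype(np.uint8).reshape(8, 8)
        assert tuple(otsu3_thresholds(img)) == (11, 91, 171)

    def test_attains_oracle_optimum_on_random_images(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
            t = otsu3_thresholds(img)
            hist = np.bincount(img.ravel(), minlength=256)
            best_wvar, _ = otsu3_oracle(hist)
            v = np.arange(256.0)
            edges = [0, *t, 256]
            got = 0.0
            for lo, hi in zip(edges[:-1], edges[1:]):
                h = hist[lo:hi].astype(float)
                w = h.sum()
                if w > 0:
                    mu = (h * v[lo:hi]).sum() / w
                    got += (h * (v[lo:hi] - mu) ** 2).sum()
            assert got == pytest.approx(best_wvar, abs=1e-6)

    def test_fewer_than_four_values_is_degenerate(self):
        img = np.repeat([10, 90, 170], 16).astype(np.uint8)
        with pytest.raises(DegenerateHistogramError):
            otsu3_thresholds(img)

    def test_lexicographic_tie_break(self):
        # single empty gap: thresholds through empty bins tie; smallest wins
        hist = np.zeros(256)
        hist[[10, 100, 180, 240]] = 5
        t = otsu3_from_hist(hist)
        assert t == (11, 101, 181)


class TestThresholdBelow:
    def test_strictly_below(self):
        img = np.array([[0, 100, 200]], dtype=np.uint8)
        assert threshold_below(img, 101).tolist() == [[255, 255, 0]]
        assert threshold_below(img, 1).tolist() == [[255, 0, 0]]

    def test_threshold_bounds_checked(self):
        with pytest.raises(ValueError):
            threshold_below(np.zeros((2, 2), np.uint8), 256)


def blob_lab(colors, positions, shape=(40, 40), r=4):
    """LabImage with constant-color square blobs on the first color."""
    L = np.full(shape, colors[0][0], np.uint8)
    a = np.full(shape, colors[0][1], np.uint8)
    b = np.full(shape, colors[0][2], np.uint8)
    for (cl, ca, cb), (y, x) in zip(colors[1:], positions):
        L[y - r:y + r, x - r:x + r] = cl
        a[y - r:y + r, x - r:x + r] = ca
        b[y - r:y + r, x - r:x + r] = cb
    return LabImage(L, a, b)


class TestSeededKmeans:
    def test_two_seed_colors_are_fixed_points(self):
        lab = blob_lab([(200, 128, 128), (20, 140, 100)], [(10, 10)])
        binary = np.where(lab.L < 100, 255, 0).astype(np.uint8)
        labels = seeded_kmeans4(lab, binary)
        assert set(np.unique(labels)) == {0, 1}
        assert (labels[lab.L[:, :] == 20] == 1).all()
        assert (labels[lab.L[:, :] == 200] == 0).all()

    def test_four_separated_blobs_recovered(self):
        # colors along a line from dark-stained to background
        colors = [(220, 128, 140), (20, 150, 80), (90, 142, 100), (155, 135, 120)]
        lab = blob_lab(colors, [(10, 10), (10, 30), (30, 10)])
        binary = np.where(lab.L < 50, 255, 0).astype(np.uint8)
        labels = seeded_kmeans4(lab, binary)
        assert (labels[lab.L == 20] == 1).all()    # strongly stained
        assert (labels[lab.L == 220] == 0).all()   # background
        assert (labels[lab.L == 90] == 2).all()    # nearer cluster 1
        assert (labels[lab.L == 155] == 3).all()

    def test_order_independence(self):
        rng = np.random.default_rng(5)
        L = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        lab = LabImage(L, np.full_like(L, 128), np.full_like(L, 128))
        binary = np.where(L < 128, 255, 0).astype(np.uint8)
        labels = seeded_kmeans4(lab, binary)
        # consistent permutation of pixels permutes labels identically
        perm = rng.permutation(144)
        lab_p = LabImage(L.ravel()[perm].reshape(12, 12),
                         np.full_like(L, 128), np.full_like(L, 128))
        bin_p = binary.ravel()[perm].reshape(12, 12)
        assert (seeded_kmeans4(lab_p, bin_p).ravel()
                == labels.ravel()[perm]).all()

    def test_single_phase_mask_rejected(self):
        lab = blob_lab([(200, 128, 128)], [])
        with pytest.raises(ValueError):
            seeded_kmeans4(lab, np.zeros((40, 40), np.uint8))


class TestClusterMask:
    def test_equality_and_closing(self):
        labels = np.full((9, 9), 2, np.uint8)
        assert (cluster_mask(labels, 2) == 255).all()
        labels[4, 4] = 0  # single-pixel hole
        assert cluster_mask(labels, 2, close=False)[4, 4] == 0
        assert cluster_mask(labels, 2, close=True)[4, 4] == 255


class TestSplitJoinedHigh:
    def test_empty_mask_passthrough(self):
        assert (split_joined_high(np.zeros((20, 20), np.uint8)) == 0).all()

    def test_single_disc_shrinks_to_concentric_core(self):
        mask = disc_mask((128, 128), 64, 64, 30)
        out = split_joined_high(mask)
        assert out[64, 64] == 255                       # center retained
        assert not (out & ~mask).any()                  # output within input
        assert (out == 255).sum() < (mask == 255).sum()

    def test_two_overlapping_discs_separate(self):
        from skimage import measure
        r = 24
        mask = disc_mask((128, 128), 44, 64, r) | disc_mask((128, 128), 84, 64, r)
        assert measure.label(mask > 0, connectivity=2).max() == 1  # joined
        out = split_joined_high(mask)
        assert measure.label(out > 0, connectivity=2).max() == 2


class TestExtractCells:
    def test_disc_centroid_and_diameter_gate(self):
        mask = disc_mask((64, 64), 30, 28, 10)  # diameter 20
        cells = extract_cells(mask, DiameterRange(10, 40), CellSource.RDA_HIGH)
        assert len(cells) == 1
        assert cells[0].x == pytest.approx(30, abs=0.5)
        assert cells[0].y == pytest.approx(28, abs=0.5)
        assert cells[0].source is CellSource.RDA_HIGH
        small = disc_mask((64, 64), 30, 28, 4)  # diameter 8 < d_min
        assert extract_cells(small, DiameterRange(10, 40), CellSource.EDA) == []

    def test_two_squares_closed_form(self):
        mask = np.zeros((64, 64), np.uint8)
        mask[5:20, 5:20] = 255
        mask[40:55, 30:45] = 255
        cells = extract_cells(mask, DiameterRange(10, 40), CellSource.RDA_LOW)
        assert len(cells) == 2
        d = 2 * np.sqrt(225 / np.pi)
        assert d == pytest.approx(16.93, abs=0.01)
        assert sorted((c.x, c.y) for c in cells) == [(12.0, 12.0), (37.0, 47.0)]

    def test_translation_equivariance(self):
        mask = disc_mask((80, 80), 25, 30, 8)
        moved = np.roll(np.roll(mask, 13, axis=0), 7, axis=1)
        a = extract_cells(mask, DiameterRange(10, 40), CellSource.EDA)
        b = extract_cells(moved, DiameterRange(10, 40), CellSource.EDA)
        assert len(a) == len(b) == 1
        assert b[0].x - a[0].x == pytest.approx(7, abs=1e-9)
        assert b[0].y - a[0].y == pytest.approx(13, abs=1e-9)


class TestRdaDetect:
    def test_high_channel_finds_dark_nuclei(self, dark_scene):
        img, gt = dark_scene
        cells = rda_detect(img, CORE_RANGE, DetectOption.HIGH)
        truth = np.array([[c.x, c.y] for c in gt.cells])
        found = sum(
            1 for t in truth
            if any(np.hypot(c.x - t[0], c.y - t[1]) < 14 for c in cells))
        assert found >= 19
        assert len(cells) <= len(gt.cells) + 1

    def test_blank_image_yields_no_cells(self):
        blank = ImageRecord(np.full((64, 64, 3), 180, np.uint8))
        for opt in DetectOption:
            assert rda_detect(blank, DiameterRange(5, 20), opt) == []

    def test_all_detections_respect_diameter_gate(self, standard_scene):
        img, _ = standard_scene
        rng = DiameterRange(14, 26)
        from ihcquant.rda import rda_detect_multi
        from skimage import measure
        by = rda_detect_multi(img, rng, tuple(DetectOption))
        for cells in by.values():
            assert all(0 <= c.x < img.width and 0 <= c.y < img.height
                       for c in cells)
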