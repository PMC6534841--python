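"""Otsu, cross features, clustering and Rosin cluster-count selection."""

import numpy as np
import pytest

from woundkit.errors import InvalidInputError, NoFeaturePointsError
from woundkit.suture_roi import (
    ClusterScoreCurve,
    build_hierarchy,
    binarize_otsu,
    cross_feature_pixels,
    cross_kernel,
    detect_rois,
    extract_feature_points,
    rosin_threshold,
    score_curve,
    score_piecewise,
    select_cluster_count,
)

from .conftest import flood_fill_components, random_mask


def brute_force_otsu(values):
    """Exhaustive between-class-variance maximization over all 256 levels."""
    hist = np.bincount(values.ravel(), minlength=256).astype(float)
    total = hist.sum()
    best_t, best_var = 0, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (np.arange(t + 1) * hist[: t + 1]).sum() / w0
        m1 = (np.arange(t + 1, 256) * hist[t + 1 :]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestCrossKernel:
    def test_printed_matrix(self):
        expected = np.array(
            [
                [0, 0, 1, 0, 0],
                [0, 0, 1, 0, 0],
                [1, 1, 1, 1, 1],
                [0, 0, 1, 0, 0],
                [0, 0, 1, 0, 0],
            ],
            dtype=np.uint8,
        )
        assert np.array_equal(cross_kernel(), expected)
        assert cross_kernel().sum() == 9


class TestBinarizeOtsu:
    def test_bimodal_extremes(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 255
        out = binarize_otsu(img)
        assert not out[:, :5].any() and out[:, 5:].all()

    def test_constant_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            out = binarize_otsu(np.full((8, 8), 42, dtype=np.uint8))
        assert not out.any()

    def test_matches_brute_force_on_random_histograms(self, rng):
        for _ in range(50):
            img = rng.integers(0, 256, (12, 12)).astype(np.uint8)
            if np.unique(img).size < 2:
                continue
            ours = binarize_otsu(img)
            t = brute_force_otsu(img)
            assert np.array_equal(ours, img > t)


def brute_force_opening(mask, kernel):
    """Sliding-window erosion then dilation, straight from the definitions."""
    mask = np.asarray(mask, dtype=bool)
    kh, kw = kernel.shape
    oh, ow = kh // 2, kw // 2
    h, w = mask.shape
    padded = np.zeros((h + 2 * oh, w + 2 * ow), dtype=bool)
    padded[oh : oh + h, ow : ow + w] = mask
    eroded = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            window = padded[r : r + kh, c : c + kw]
            eroded[r, c] = bool((window | ~kernel.astype(bool)).all())
    out = np.zeros_like(mask)
    for r, c in np.argwhere(eroded):
        for dr in range(-oh, oh + 1):
            for dc in range(-ow, ow + 1):
                if kernel[dr + oh, dc + ow] and 0 <= r + dr < h and 0 <= c + dc < w:
                    out[r + dr, c + dc] = True
    return out


class TestCrossFeaturePixels:
    def test_exact_cross_is_preserved(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:7, 4] = True
        mask[4, 2:7] = True
        out = cross_feature_pixels(mask)
        assert np.array_equal(out, mask)

    def test_isolated_pixel_removed(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        assert not cross_feature_pixels(mask).any()

    def test_thin_line_removed_plus_retained(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[3, 2:14] = True  # 1-px horizontal line, no vertical bars
        assert not cross_feature_pixels(mask).any()
        plus = np.zeros((16, 16), dtype=bool)
        plus[4:13, 8] = True
        plus[8, 4:13] = True
        assert cross_feature_pixels(plus).any()

    def test_matches_brute_force_opening(self, rng):
        kernel = cross_kernel()
        for _ in range(30):
            mask = random_mask(rng, (16, 16), 0.45)
            assert np.array_equal(
                cross_feature_pixels(mask), brute_force_opening(mask, kernel)
            )


class TestExtractFeaturePoints:
    def test_centroid_rounding_half_up(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0:2, 0:2] = True  # centroid (0.5, 0.5)
        assert extract_feature_points(mask).tolist() == [[1, 1]]

    def test_count_preserved(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2, 2] = mask[10, 10] = mask[18, 3] = True
        assert len(extract_feature_points(mask)) == 3

    def test_matches_flood_fill_mean_oracle(self, rng):
        for _ in range(30):
            mask = random_mask(rng, (16, 16), 0.2)
            pts = extract_feature_points(mask)
            labels, n = flood_fill_components(mask, 8)
            assert len(pts) == n
            expected = set()
            for lab in range(1, n + 1):
                coords = np.argwhere(labels == lab)
                cent = np.floor(coords.mean(axis=0) + 0.5).astype(int)
                expected.add(tuple(cent))
            assert {tuple(p) for p in pts} == expected


class TestBuildHierarchy:
    def test_two_points_single_merge(self):
        h = build_hierarchy([[0, 0], [3, 4]])
        assert h.linkage_matrix.shape == (1, 4)
        assert h.linkage_matrix[0, 2] == pytest.approx(5.0)

    def test_cuts_are_nested(self, rng):
        pts = rng.random((12, 2)) * 100
        h = build_hierarchy(pts)
        for k in range(2, 12):
            coarse = h.cut(k - 1)
            fine = h.cut(k)
            # each fine cluster lies inside exactly one coarse cluster
            for lab in np.unique(fine):
                assert np.unique(coarse[fine == lab]).size == 1

    def test_first_merge_is_closest_pair(self):
        h = build_hierarchy([[0, 0], [0, 1], [0, 10]])
        assert h.cut(2).tolist()[0] == h.cut(2).tolist()[1]
        assert h.cut(2)[2] != h.cut(2)[0]

    def test_too_few_points(self):
        with pytest.raises(NoFeaturePointsError):
            build_hierarchy([[1, 1]])


class TestScorePiecewise:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(2, 4, 0.5), (3, 3, 0.0), (4, 2, -0.5)],
    )
    def test_branches(self, a, b, expected):
        assert score_piecewise(a, b) == pytest.approx(expected)


class TestRosinThreshold:
    def test_sharp_corner_example(self):
        curve = ClusterScoreCurve(
            ks=np.array([2, 3, 4, 5, 6]),
            values=np.array([100.0, 10.0, 5.0, 4.0, 3.5]),
            variant="formula",
        )
        assert rosin_threshold(curve) == 3

    def test_linear_curve_returns_first_k(self):
        curve = ClusterScoreCurve(
            ks=np.array([2, 3, 4, 5]),
            values=np.array([40.0, 30.0, 20.0, 10.0]),
            variant="formula",
        )
        assert rosin_threshold(curve) == 2

    def test_scale_invariance(self, rng):
        for _ in range(20):
            vals = np.sort(rng.random(8))[::-1] * 50 + 1
            curve = ClusterScoreCurve(np.arange(2, 10), vals, "formula")
            scaled = ClusterScoreCurve(np.arange(2, 10), vals * 37.5, "formula")
            assert rosin_threshold(curve) == rosin_threshold(scaled)

    def test_matches_exhaustive_chord_distance_oracle(self, rng):
        for _ in range(50):
            vals = np.sort(rng.random(9))[::-1] * 20
            ks = np.arange(2, 11).astype(float)
            curve = ClusterScoreCurve(ks, vals, "formula")
            got = rosin_threshold(curve)
            i0 = int(np.argmax(vals))
            p0 = np.array([ks[i0], vals[i0]])
            p1 = np.array([ks[-1], vals[-1]])
            chord = p1 - p0
            best_k, best_d = int(ks[0]), 0.0
            found = False
            for i in range(i0 + 1, len(ks)):
                d = abs(
                    chord[0] * (vals[i] - p0[1]) - chord[1] * (ks[i] - p0[0])
                ) / np.hypot(*chord)
                if d > best_d + 1e-12:
                    best_k, best_d = int(ks[i]), d
                    found = True
            if found:
                assert got == best_k

    def test_empty_curve_rejected(self):
        with pytest.raises(InvalidInputError):
            rosin_threshold(ClusterScoreCurve(np.array([]), np.array([]), "formula"))


class TestScoreCurve:
    def test_formula_curve_is_reciprocal_of_piecewise(self):
        pts = np.random.default_rng(0).random((12, 2)) * 100
        h = build_hierarchy(pts)
        curve = score_curve(h, variant="formula")
        for k, v in zip(curve.ks, curve.values):
            s = score_piecewise(12 / k, float(k))
            assert s > 0
            assert v == pytest.approx(1.0 / s)

    def test_dispersion_curve_starts_at_total_variance(self):
        rng = np.random.default_rng(1)
        pts = rng.random((10, 2)) * 50
        h = build_hierarchy(pts)
        curve = score_curve(h, variant="dispersion")
        assert curve.ks[0] == 1
        total = ((pts - pts.mean(axis=0)) ** 2).sum() / len(pts)
        assert curve.values[0] == pytest.approx(np.log(total))

    def test_dispersion_is_non_increasing(self):
        rng = np.random.default_rng(2)
        pts = rng.random((14, 2)) * 80
        curve = score_curve(build_hierarchy(pts), variant="dispersion")
        assert (np.diff(curve.values) <= 1e-9).all()


class TestClusterCountRecovery:
    @pytest.mark.parametrize("c", [2, 3, 4, 5])
    def test_well_separated_blobs(self, c):
        """Rosin on the dispersion curve recovers the blob count in >= 90%
        of seeded trials for tight, well-separated blobs."""
        hits = 0
        trials = 50
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            centers = np.stack(
                [np.linspace(0, 60.0 * (c - 1), c), np.zeros(c)], axis=1
            ) + rng.uniform(100, 200, 2)
            pts = np.concatenate(
                [ctr + rng.normal(0, 3.0, (4, 2)) for ctr in centers]
            )
            h = build_hierarchy(pts)
            hits += select_cluster_count(h) == c
        assert hits / trials >= 0.90


class TestDetectRois:
    def test_min_max_box_without_pad(self):
        h = build_hierarchy([[10, 10], [30, 20], [200, 200], [205, 210]])
        rois = detect_rois(h, 2, pad=0)
        assert len(rois) == 2
        boxes = sorted((r.x_min, r.y_min, r.x_max, r.y_max) for r in rois)
        assert boxes[0] == (10, 10, 20, 30)
        assert boxes[1] == (200, 200, 210, 205)

    def test_roi_count_equals_k(self, rng):
        pts = rng.random((14, 2)) * 200
        h = build_hierarchy(pts)
        for k in (2, 3, 5, 7):
            assert len(detect_rois(h, k)) == k

    def test_boxes_contain_member_points(self, rng):
        pts = rng.random((10, 2)) * 100
        h = build_hierarchy(pts)
        for roi in detect_rois(h, 3, pad=4):
            for y, x in roi.points:
                assert roi.x_min <= x <= roi.x_max
                assert roi.y_min <= y <= roi.y_max

    def test_clipping_to_image(self):
        h = build_hierarchy([[1, 1], [2, 2], [50, 50], [52, 52]])
        rois = detect_rois(h, 2, pad=10, image_shape=(60, 60))
        for roi in rois:
            assert roi.x_min >= 0 and roi.y_min >= 0
            assert roi.x_max <= 59 and roi.y_max <= 59
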