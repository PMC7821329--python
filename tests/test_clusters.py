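"""Cluster detection, size classes and condensation statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memclust import clusters as mc
from memclust import synthetic as syn
from memclust.images import CalibratedImage, DegenerateImageError


def _image(pixels, ps=0.05):
    return CalibratedImage(np.asarray(pixels, dtype=float), ps)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class TestSegmentation:
    def test_blank_noisy_background_gives_empty_mask(self):
        rng = np.random.default_rng(0)
        img = _image(100 + rng.normal(0, 2, (128, 128)).clip(-90, None))
        assert mc.segment_membrane(img, method="otsu").sum() == 0

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateImageError):
            mc.segment_membrane(_image(np.full((32, 32), 7.0)))

    def test_square_segments_exactly(self):
        px = np.zeros((64, 64))
        px[20:30, 20:30] = 500.0
        mask = mc.segment_membrane(_image(px), method="otsu")
        assert mask.sum() == 100
        assert mask[20:30, 20:30].all()

    def test_mask_covers_planted_pixels_noise_free(self):
        spec = syn.ClusterFieldSpec(n_clusters=60, seed=5)
        img, _ = syn.generate_cluster_image(spec)
        mask = mc.segment_membrane(img, method="half_max")
        # pixels above half maximum of the noise-free rendering
        half = spec.background_intensity + 0.5 * spec.cluster_peak_intensity
        planted = img.pixels >= half
        assert (mask & planted).sum() >= 0.95 * planted.sum()


# ---------------------------------------------------------------------------
# detection and the flood-fill oracle
# ---------------------------------------------------------------------------

def _flood_fill_components(mask):
    """Brute-force 8-connected components (BFS), independent of skimage."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], []
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and not seen[yy, xx]:
                                seen[yy, xx] = True
                                stack.append((yy, xx))
                comps.append(frozenset(comp))
    return set(comps)


class TestDetection:
    def test_empty_mask_gives_no_records(self):
        img = _image(np.zeros((32, 32)))
        assert mc.detect_clusters(img, np.zeros((32, 32), bool)) == []

    def test_single_square_area(self):
        px = np.zeros((64, 64))
        px[10:20, 30:40] = 1.0
        recs = mc.detect_clusters(_image(px, ps=0.05), px > 0)
        assert len(recs) == 1
        assert recs[0].area == pytest.approx(0.25)  # 100 px × 0.0025 µm²
        assert recs[0].size_class == "small"

    def test_planted_field_recovery(self):
        spec = syn.ClusterFieldSpec(n_clusters=50, seed=1)
        img, truth = syn.generate_cluster_image(spec)
        mask = mc.segment_membrane(img, method="half_max")
        recs = mc.detect_clusters(img, mask)
        assert len(recs) == len(truth)
        truth_xy = np.array([t.centroid for t in truth])
        for r in recs:
            i = np.argmin(np.hypot(*(truth_xy - r.centroid).T))
            assert r.area == pytest.approx(truth[i].area, rel=0.15)

    def test_matches_flood_fill_oracle_on_random_masks(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            mask = rng.random((64, 64)) < 0.25
            img = _image(rng.random((64, 64)) + 0.1, ps=0.1)
            recs = mc.detect_clusters(img, mask)
            oracle = _flood_fill_components(mask)
            assert len(recs) == len(oracle)
            assert sorted(int(round(r.area / 0.01)) for r in recs) == sorted(
                len(c) for c in oracle)

    def test_area_conservation(self):
        spec = syn.ClusterFieldSpec(n_clusters=30, seed=9)
        img, _ = syn.generate_cluster_image(spec)
        mask = mc.segment_membrane(img, method="half_max")
        recs = mc.detect_clusters(img, mask)
        assert sum(r.area for r in recs) == pytest.approx(
            mask.sum() * img.pixel_size**2)


# ---------------------------------------------------------------------------
# size classes and distribution
# ---------------------------------------------------------------------------

class TestSizeClasses:
    @pytest.mark.parametrize("area,expected", [
        (0.1, "tiny"), (0.5, "small"), (1.5, "long"),
        (0.2, "small"), (0.6, "medium"), (1.0, "long"),  # left-closed bins
        (0.199999, "tiny"), (0.999999, "medium"),
    ])
    def test_bin_assignment(self, area, expected):
        assert mc.classify_cluster_size(area) == expected

    @pytest.mark.parametrize("area", [0.0, -0.5])
    def test_nonpositive_area_rejected(self, area):
        with pytest.raises(ValueError):
            mc.classify_cluster_size(area)

    def test_monotone_step_function(self):
        order = {c: i for i, c in enumerate(mc.SIZE_CLASSES)}
        areas = np.linspace(0.01, 2.0, 300)
        ranks = [order[mc.classify_cluster_size(a)] for a in areas]
        assert all(b >= a for a, b in zip(ranks, ranks[1:]))

    def test_distribution_all_one_class(self):
        recs = [_rec(i, 1.5) for i in range(10)]
        dist = mc.size_distribution(recs)
        assert dist.frequencies["long"] == 1.0
        assert dist.n_total == 10

    def test_distribution_one_per_class(self):
        recs = [_rec(1, 0.1), _rec(2, 0.3), _rec(3, 0.7), _rec(4, 1.2)]
        dist = mc.size_distribution(recs)
        assert all(f == 0.25 for f in dist.frequencies.values())
        assert sum(dist.counts.values()) == dist.n_total == 4

    def test_empty_distribution_flagged_undefined(self):
        dist = mc.size_distribution([])
        assert dist.n_total == 0
        assert all(np.isnan(f) for f in dist.frequencies.values())


def _rec(label, area, xy=(0.0, 0.0)):
    return mc.ClusterRecord(
        label=label, area=area, centroid=xy, mean_intensity=1.0,
        total_intensity=1.0, size_class=mc.classify_cluster_size(area))


# ---------------------------------------------------------------------------
# spacing
# ---------------------------------------------------------------------------

class TestSpacing:
    def test_two_clusters(self):
        s = mc.cluster_spacing([_rec(1, 0.5, (0.0, 0.0)), _rec(2, 0.5, (1.0, 0.0))])
        assert s.mean == pytest.approx(1.0)

    def test_regular_grid_pitch(self):
        recs = [_rec(i * 10 + j, 0.5, (i * 0.7, j * 0.7))
                for i in range(4) for j in range(4)]
        assert mc.cluster_spacing(recs).mean == pytest.approx(0.7)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.random((40, 2)) * 10
        recs = [_rec(i, 0.5, tuple(p)) for i, p in enumerate(pts)]
        nn = mc.cluster_spacing(recs).nn_distances
        d = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                     pts[:, None, 1] - pts[None, :, 1])
        np.fill_diagonal(d, np.inf)
        np.testing.assert_allclose(nn, d.min(axis=1))

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            mc.cluster_spacing([_rec(1, 0.5)])


# ---------------------------------------------------------------------------
# clustering index
# ---------------------------------------------------------------------------

class TestClusteringIndex:
    def test_constant_signal_zero(self):
        assert mc.clustering_index(np.full(100, 5.0)).index == 0.0

    def test_two_level_hand_value(self):
        v = np.array([0.0] * 50 + [2.0] * 50)
        assert mc.clustering_index(v).index == pytest.approx(1.0)

    def test_condensed_exceeds_uniform_at_equal_total(self):
        spec = syn.ClusterFieldSpec(n_clusters=80, seed=2)
        img, _ = syn.generate_cluster_image(spec)
        clustered = img.pixels.ravel()
        uniform = np.full_like(clustered, clustered.mean())
        uniform += np.linspace(-1e-6, 1e-6, uniform.size)  # not exactly constant
        assert (mc.clustering_index(clustered).index
                > mc.clustering_index(uniform).index)

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        v = np.array([1.0, 2.0, 5.0, 9.0, 3.0])
        base = mc.clustering_index(v).index
        assert mc.clustering_index(v * scale).index == pytest.approx(base)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            mc.clustering_index(np.zeros(10))


# ---------------------------------------------------------------------------
# outside confidence
# ---------------------------------------------------------------------------

class TestOutsideConfidence:
    def test_null_calibrates_to_5pct(self):
        rng = np.random.default_rng(11)
        mock = rng.lognormal(5.0, 0.4, 10_000)
        treated = rng.lognormal(5.0, 0.4, 10_000)
        res = mc.outside_confidence(treated, mock)
        assert res.percentage == pytest.approx(5.0, abs=1.5)
        assert res.interval[0] < res.interval[1]

    def test_values_at_mock_median_are_inside(self):
        rng = np.random.default_rng(1)
        mock = rng.normal(100, 10, 500)
        treated = np.full(200, np.median(mock))
        assert mc.outside_confidence(treated, mock).percentage == 0.0

    def test_large_shift_puts_everything_outside(self):
        rng = np.random.default_rng(2)
        mock = rng.normal(100, 10, 1000)
        treated = rng.normal(100, 10, 1000) + 100  # +10 mock sd
        assert mc.outside_confidence(treated, mock).percentage == pytest.approx(100.0, abs=0.5)

    def test_undersized_mock_rejected(self):
        with pytest.raises(ValueError, match="40"):
            mc.outside_confidence(np.ones(100), np.ones(39))

    def test_parametric_variant_also_calibrates(self):
        rng = np.random.default_rng(5)
        mock = rng.normal(50, 5, 10_000)
        treated = rng.normal(50, 5, 10_000)
        res = mc.outside_confidence(treated, mock, method="parametric")
        assert res.percentage == pytest.approx(5.0, abs=1.5)


# ---------------------------------------------------------------------------
# colocalisation
# ---------------------------------------------------------------------------

class TestColocalisation:
    def test_identical_images_fully_correlated(self):
        spec = syn.ClusterFieldSpec(n_clusters=20, seed=4)
        img, _ = syn.generate_cluster_image(spec)
        mask = mc.segment_membrane(img, method="half_max")
        res = mc.colocalise(img, img, mask, mask)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.object_overlap_fraction == 1.0

    def test_disjoint_masks_zero_overlap(self):
        px = np.zeros((64, 64))
        px[5:10, 5:10] = 10.0
        qx = np.zeros((64, 64))
        qx[40:45, 40:45] = 10.0
        a, b = _image(px, 0.1), _image(qx, 0.1)
        res = mc.colocalise(a, b, px > 0, qx > 0)
        assert res.object_overlap_fraction == 0.0

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(8)
        a = _image(rng.random((128, 128)))
        b = _image(rng.random((128, 128)))
        mask = np.ones((128, 128), bool)
        r = mc.colocalise(a, b, mask, mask).pearson_r
        assert abs(r) < 3.0 / np.sqrt(mask.sum())

    def test_shape_mismatch_rejected(self):
        a = _image(np.ones((10, 10)))
        b = _image(np.ones((12, 12)))
        with pytest.raises(ValueError):
            mc.colocalise(a, b, np.ones((10, 10), bool), np.ones((12, 12), bool))
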