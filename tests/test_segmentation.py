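"""HSV conversion, Otsu thresholding and mask refinement against oracles."""

import colorsys

import numpy as np
import pytest

from rgbdclean import (
    ColorImage,
    GrayHistogram,
    between_class_variance,
    binarize,
    default_area_threshold,
    normalize_rgb,
    otsu_threshold,
    quantize_v,
    refine_mask,
    rgb_to_hsv,
    v_histogram,
)
from rgbdclean.errors import (
    DegenerateHistogramError,
    DomainError,
    EmptyHistogramError,
)


def hist_from_counts(counts, L=256):
    c = np.zeros(L, dtype=np.int64)
    for level, n in counts.items():
        c[level] = n
    return GrayHistogram(counts=c, L=L)


def brute_force_otsu(h: GrayHistogram):
    """Independent scalar scan: direct class sums per candidate threshold."""
    p = h.counts / h.counts.sum()
    L = h.L
    mu_T = sum(i * p[i] for i in range(L))
    best_k, best_s = None, -1.0
    for k in range(L - 1):
        w0 = sum(p[i] for i in range(k + 1))
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            s = 0.0
        else:
            mu0 = sum(i * p[i] for i in range(k + 1)) / w0
            mu1 = sum(i * p[i] for i in range(k + 1, L)) / w1
            s = w0 * (mu0 - mu_T) ** 2 + w1 * (mu1 - mu_T) ** 2
        if s > best_s + 1e-15:
            best_s, best_k = s, k
    return best_k, best_s


def random_multimodal_histogram(rng, L=256):
    counts = np.zeros(L, dtype=np.int64)
    for _ in range(rng.integers(2, 5)):
        center = rng.integers(0, L)
        sd = rng.uniform(2, 30)
        n = rng.integers(50, 500)
        levels = np.clip(np.round(rng.normal(center, sd, size=n)), 0, L - 1).astype(int)
        counts += np.bincount(levels, minlength=L)
    return GrayHistogram(counts=counts, L=L)


class TestNormalizeRgb:
    def test_exact_division_by_255(self):
        img = ColorImage(np.array([[[255, 0, 51]]], dtype=np.uint8))
        out = normalize_rgb(img)
        assert out.normalized
        np.testing.assert_array_equal(out.values[0, 0], [1.0, 0.0, 0.2])

    def test_already_normalized_warns_and_passes_through(self):
        img = ColorImage(np.zeros((2, 2, 3)), normalized=True)
        with pytest.warns(UserWarning):
            out = normalize_rgb(img)
        assert out is img


class TestRgbToHsv:
    @pytest.mark.parametrize(
        "rgb,expected_hsv",
        [
            ((1, 0, 0), (0, 1, 1)),        # pure red: R-branch, zero numerator
            ((0, 0, 1), (240, 1, 1)),      # pure blue: B-branch
            ((1, 0, 0.5), (330, 1, 1)),    # negative hue wrapped by +360
            ((0, 1, 0), (120, 1, 1)),
            ((0.5, 0.5, 0.5), (0, 0, 0.5)),  # achromatic: H convention 0
            ((0, 0, 0), (0, 0, 0)),          # S defined 0 when V = 0
        ],
    )
    def test_definitional_examples(self, rgb, expected_hsv):
        img = ColorImage(np.array([[rgb]], dtype=float), normalized=True)
        hsv = rgb_to_hsv(img)
        np.testing.assert_allclose(
            [hsv.H[0, 0], hsv.S[0, 0], hsv.V[0, 0]], expected_hsv, atol=1e-12
        )

    def test_matches_colorsys_on_random_triples(self):
        rng = np.random.default_rng(42)
        triples = rng.random((10_000, 3))
        corners = np.array(np.meshgrid([0, 1], [0, 1], [0, 1])).T.reshape(-1, 3).astype(float)
        triples = np.vstack([triples, corners])
        img = ColorImage(triples.reshape(1, -1, 3), normalized=True)
        hsv = rgb_to_hsv(img)
        for i, (r, g, b) in enumerate(triples):
            h_ref, s_ref, v_ref = colorsys.rgb_to_hsv(r, g, b)
            h_err = abs((hsv.H[0, i] - h_ref * 360.0 + 180.0) % 360.0 - 180.0)
            assert h_err < 1e-9
            assert abs(hsv.S[0, i] - s_ref) < 1e-9
            assert abs(hsv.V[0, i] - v_ref) < 1e-9

    def test_invalid_pixels_zeroed(self):
        img = ColorImage(np.full((2, 2, 3), 0.8), normalized=True)
        valid = np.array([[True, False], [True, True]])
        hsv = rgb_to_hsv(img, valid)
        assert hsv.V[0, 1] == 0.0 and hsv.S[0, 1] == 0.0 and hsv.H[0, 1] == 0.0
        assert hsv.V[0, 0] == 0.8

    def test_unnormalized_input_rejected(self):
        with pytest.raises(DomainError):
            rgb_to_hsv(ColorImage(np.zeros((1, 1, 3), dtype=np.uint8)))


class TestVHistogram:
    def test_endpoint_levels(self):
        V = np.array([[0.0, 1.0]])
        h = v_histogram(V, np.ones_like(V, dtype=bool), 256)
        assert h.counts[0] == 1 and h.counts[255] == 1 and h.N == 2
        np.testing.assert_allclose(h.probabilities.sum(), 1.0, atol=1e-12)

    def test_all_invalid_raises(self):
        with pytest.raises(EmptyHistogramError):
            v_histogram(np.zeros((3, 3)), np.zeros((3, 3), dtype=bool))

    def test_counts_only_valid_pixels(self, rng):
        V = rng.random((16, 16))
        valid = rng.random((16, 16)) > 0.3
        h = v_histogram(V, valid)
        assert h.N == int(valid.sum())
        np.testing.assert_allclose(h.probabilities.sum(), 1.0, atol=1e-12)

    def test_eight_bit_round_trip(self):
        bytes_ = np.arange(256, dtype=np.uint8)
        V = bytes_.astype(float) / 255.0
        np.testing.assert_array_equal(quantize_v(V, 256), bytes_)


class TestBetweenClassVariance:
    def test_single_class_gives_zero(self):
        h = hist_from_counts({100: 500})
        assert between_class_variance(h, 50) == 0.0
        assert between_class_variance(h, 200) == 0.0

    def test_two_equal_spikes_closed_form(self):
        a, b = 60, 180
        h = hist_from_counts({a: 100, b: 100})
        # For any split between the spikes: w0 = w1 = 1/2, so
        # sigma^2 = w0 w1 (mu0 - mu1)^2 = ((b - a) / 2)^2.
        expected = ((b - a) / 2) ** 2
        for k in (a, (a + b) // 2, b - 1):
            assert between_class_variance(h, k) == pytest.approx(expected, abs=1e-9)

    def test_two_form_equivalence_on_random_histograms(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            h = random_multimodal_histogram(rng)
            p = h.probabilities
            i = np.arange(h.L)
            mu_T = float((i * p).sum())
            for k in rng.integers(0, h.L - 1, size=10):
                w0 = p[: k + 1].sum()
                w1 = 1.0 - w0
                direct = 0.0
                if 0 < w0 < 1:
                    mu0 = (i[: k + 1] * p[: k + 1]).sum() / w0
                    mu1 = (i[k + 1:] * p[k + 1:]).sum() / w1
                    direct = w0 * (mu0 - mu_T) ** 2 + w1 * (mu1 - mu_T) ** 2
                assert between_class_variance(h, int(k)) == pytest.approx(direct, abs=1e-9)

    def test_k_out_of_range_rejected(self):
        h = hist_from_counts({0: 10, 255: 10})
        with pytest.raises(DomainError):
            between_class_variance(h, 255)


class TestOtsuThreshold:
    def test_two_spike_plateau_resolved_to_smallest_k(self):
        h = hist_from_counts({50: 50, 200: 50})
        res = otsu_threshold(h)
        assert res.k_opt == 50
        plateau = res.curve[50:200]
        np.testing.assert_allclose(plateau, plateau[0])
        assert res.sigma2 == res.curve.max()

    def test_extreme_spikes_tie_break(self):
        h = hist_from_counts({0: 70, 255: 30})
        assert otsu_threshold(h).k_opt == 0

    def test_single_level_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(hist_from_counts({128: 1000}))

    def test_brute_force_agreement_on_100_random_histograms(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            h = random_multimodal_histogram(rng)
            res = otsu_threshold(h)
            k_ref, _ = brute_force_otsu(h)
            assert res.k_opt == k_ref

    def test_class_moment_identities(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            h = random_multimodal_histogram(rng)
            p = h.probabilities
            i = np.arange(h.L)
            mu_T = float((i * p).sum())
            for k in range(h.L - 1):
                w0 = p[: k + 1].sum()
                w1 = p[k + 1:].sum()
                assert abs(w0 + w1 - 1.0) < 1e-9
                m0 = (i[: k + 1] * p[: k + 1]).sum()
                m1 = (i[k + 1:] * p[k + 1:]).sum()
                # omega0*mu0 + omega1*mu1 reduces to the unconditional sums.
                assert abs(m0 + m1 - mu_T) < 1e-9

    def test_agrees_with_skimage_cross_check(self):
        skimage_filters = pytest.importorskip("skimage.filters")
        rng = np.random.default_rng(21)
        for _ in range(20):
            h = random_multimodal_histogram(rng)
            if np.count_nonzero(h.counts) < 2:
                continue
            ours = otsu_threshold(h).k_opt
            ref = skimage_filters.threshold_otsu(
                hist=(h.counts.astype(float), np.arange(h.L))
            )
            assert ours == int(ref)


class TestBinarize:
    def test_threshold_split(self):
        V = np.array([[10 / 255, 200 / 255]])
        mask = binarize(V, np.ones_like(V, dtype=bool), 50)
        np.testing.assert_array_equal(mask, [[0, 1]])

    def test_level_equal_to_threshold_is_target(self):
        V = np.array([[50 / 255]])
        mask = binarize(V, np.ones_like(V, dtype=bool), 50)
        assert mask[0, 0] == 1

    def test_invalid_pixel_is_background(self):
        V = np.array([[200 / 255]])
        mask = binarize(V, np.array([[False]]), 50)
        assert mask[0, 0] == 0

    def test_bimodal_image_boundary_semantics(self, rng):
        # Two-constant image: the smallest-k tie-break puts the threshold on
        # the top populated level of the lower class, and the closed lower
        # boundary of the binarization keeps that level as target. The upper
        # mode is always entirely target; the lower mode separates exactly
        # only strictly below the threshold level.
        lo, hi = 0.2, 0.8
        V = np.where(rng.random((32, 32)) < 0.5, lo, hi)
        valid = np.ones_like(V, dtype=bool)
        h = v_histogram(V, valid)
        k = otsu_threshold(h).k_opt
        assert k == quantize_v(np.array(lo)).item()  # plateau resolved low
        mask = binarize(V, valid, k)
        assert mask[V == hi].all()
        np.testing.assert_array_equal(mask.astype(bool), quantize_v(V) >= k)

    def test_noisy_bimodal_separation_after_refinement(self):
        # With continuous noise the valley is sparsely populated; the few
        # pixels landing exactly on the threshold level are isolated and the
        # area filter erases them, so the two modes separate in practice.
        rng = np.random.default_rng(0)
        bright = np.zeros((64, 64), dtype=bool)
        bright[16:48, 16:48] = True
        V = np.clip(np.where(bright, 0.8, 0.2) + rng.normal(0, 0.02, (64, 64)), 0, 1)
        valid = np.ones_like(V, dtype=bool)
        h = v_histogram(V, valid)
        k = otsu_threshold(h).k_opt
        # The threshold sits on the top populated level of the dark class:
        # above the dark mean, below the bright mode.
        assert quantize_v(np.array(0.2)) < k < quantize_v(np.array(0.75))
        mask = refine_mask(binarize(V, valid, k), kernel=3, s_th=50).astype(bool)
        assert mask[bright].mean() > 0.99
        assert mask[~bright].mean() < 0.01


class TestRefineMask:
    def test_interior_hole_filled(self):
        mask = np.zeros((7, 7), dtype=np.uint8)
        mask[1:6, 1:6] = 1
        mask[3, 3] = 0
        out = refine_mask(mask, kernel=1, s_th=0)
        assert out[3, 3] == 1
        np.testing.assert_array_equal(out[1:6, 1:6], 1)

    def test_small_components_erased(self):
        mask = np.zeros((12, 12), dtype=np.uint8)
        mask[1:4, 1:4] = 1       # area 9
        mask[8:9, 8:11] = 1      # area 3
        out = refine_mask(mask, kernel=1, s_th=5)
        assert out[1:4, 1:4].all()
        assert not out[8:9, 8:11].any()

    def test_identity_when_disabled(self, rng):
        mask = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        # Remove interior holes first so the identity claim is exact.
        mask = refine_mask(mask, kernel=1, s_th=0)
        out = refine_mask(mask, kernel=1, s_th=0)
        np.testing.assert_array_equal(out, mask)

    def test_output_is_binary(self, rng):
        mask = (rng.random((20, 20)) > 0.7).astype(np.uint8)
        out = refine_mask(mask, kernel=3, s_th=4)
        assert set(np.unique(out)) <= {0, 1}

    def test_closing_bridges_pixel_gap(self):
        mask = np.zeros((5, 9), dtype=np.uint8)
        mask[2, 1:4] = 1
        mask[2, 5:8] = 1
        out = refine_mask(mask, kernel=3, s_th=0)
        assert out[2, 4] == 1

    @pytest.mark.parametrize("kernel", [0, 2])
    def test_even_or_zero_kernel_rejected(self, kernel):
        with pytest.raises(DomainError):
            refine_mask(np.zeros((4, 4)), kernel=kernel)


def test_default_area_threshold_scales_with_resolution():
    assert default_area_threshold(480, 640) == 5000
    assert default_area_threshold(120, 160) == round(5000 / 16)
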