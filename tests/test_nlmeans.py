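import numpy as np
import pytest

from knlmeans import (
    GrayImage,
    PatchConfig,
    SpeckleParams,
    add_speckle,
    gradient_magnitude,
    naive_oracle_denoise,
    nlmeans_denoise,
    nlmeans_gradient_denoise,
    patch_distance,
    psnr,
    weight_field,
)


class TestPatchConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"patch_radius": 0},
            {"search_radius": 1, "patch_radius": 2},
            {"h": 0.0},
            {"h": -1.0},
            {"a": 0.0},
            {"gaussian_sigma": -1.0},
            {"h_lambda": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PatchConfig(**kwargs)

    def test_kernel_sigma_defaults_to_half_radius(self):
        assert PatchConfig(patch_radius=3).kernel_sigma == 1.5


class TestPatchDistance:
    def test_zero_for_identical_pixel_and_symmetry(self, random_image):
        img = random_image((9, 9), seed=4)
        cfg = PatchConfig(patch_radius=2, h=0.1)
        assert patch_distance(img, (4, 4), (4, 4), cfg) == 0.0
        d_ij = patch_distance(img, (1, 2), (6, 7), cfg)
        d_ji = patch_distance(img, (6, 7), (1, 2), cfg)
        assert d_ij == pytest.approx(d_ji, rel=1e-12)
        assert d_ij > 0

    def test_uniform_limit_kernel_matches_hand_sum(self):
        # a huge kernel width makes the normalized kernel uniform (1/9),
        # so the distance is the plain mean of squared patch differences
        grid = GrayImage((np.arange(25).reshape(5, 5) % 7) / 10.0)
        cfg = PatchConfig(patch_radius=1, gaussian_sigma=1e9, h=0.1)
        i, j = (2, 2), (1, 3)
        padded = np.pad(grid.pixels, 1, mode="symmetric")
        expected = 0.0
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                diff = (
                    padded[i[0] + 1 + dy, i[1] + 1 + dx]
                    - padded[j[0] + 1 + dy, j[1] + 1 + dx]
                )
                expected += diff**2 / 9.0
        assert patch_distance(grid, i, j, cfg) == pytest.approx(expected, rel=1e-12)


class TestGradientMagnitude:
    def test_constant_image_is_zero(self):
        assert np.all(gradient_magnitude(np.full((5, 7), 0.3)) == 0.0)

    def test_linear_ramp_interior_is_exact(self):
        g = 0.05
        ramp = np.tile(g * np.arange(10), (8, 1))
        mag = gradient_magnitude(ramp)
        assert np.allclose(mag[:, 1:-1], g, atol=1e-14)
        # mirrored border stencil halves the one-sided difference
        assert np.allclose(mag[:, 0], g / 2, atol=1e-14)

    def test_single_bright_pixel_stencil(self):
        v = 0.8
        img = np.zeros((3, 3))
        img[1, 1] = v
        mag = gradient_magnitude(img)
        assert mag[1, 1] == 0.0
        for r, c in [(0, 1), (1, 0), (1, 2), (2, 1)]:
            assert mag[r, c] == pytest.approx(v / 2)

    def test_requires_two_pixels_per_axis(self):
        with pytest.raises(ValueError):
            gradient_magnitude(np.zeros((1, 5)))


class TestOracleEquivalence:
    @pytest.mark.parametrize("use_gradient", [False, True])
    def test_windowed_filter_matches_bruteforce(self, random_image, use_gradient):
        img = random_image((12, 12), seed=7)
        cfg = PatchConfig(
            patch_radius=2, search_radius=None, h=0.2, use_gradient=use_gradient
        )
        fast = (
            nlmeans_gradient_denoise(img, cfg)
            if use_gradient
            else nlmeans_denoise(img, cfg)
        )
        oracle = naive_oracle_denoise(img, cfg)
        assert np.abs(fast.pixels - oracle.pixels).max() <= 1e-10

    def test_oracle_refuses_large_inputs(self, random_image):
        with pytest.raises(ValueError):
            naive_oracle_denoise(random_image((33, 12), seed=0), PatchConfig(h=0.1))

    def test_oracle_single_pixel_unchanged(self):
        img = GrayImage(np.array([[0.4]]))
        assert naive_oracle_denoise(img, PatchConfig(h=0.1)).pixels[0, 0] == 0.4


class TestDenoiseContracts:
    @pytest.mark.parametrize(
        "filt", [nlmeans_denoise, nlmeans_gradient_denoise], ids=["plain", "gradient"]
    )
    def test_constant_image_is_fixed_point(self, filt):
        const = GrayImage(np.full((16, 16), 0.37))
        out = filt(const, PatchConfig(h=0.1, search_radius=4))
        assert np.allclose(out.pixels, 0.37, atol=1e-12)

    def test_huge_h_tends_to_candidate_window_mean(self, random_image):
        img = random_image((10, 10), seed=9)
        out = nlmeans_denoise(img, PatchConfig(h=1e6, search_radius=None))
        assert np.allclose(out.pixels, img.pixels.mean(), atol=1e-9)

    def test_output_within_input_range(self, random_image):
        img = random_image((20, 20), seed=10)
        out = nlmeans_denoise(img, PatchConfig(h=0.15, search_radius=5))
        assert out.pixels.min() >= img.pixels.min() - 1e-12
        assert out.pixels.max() <= img.pixels.max() + 1e-12

    def test_mirror_symmetry(self, random_image):
        img = random_image((18, 14), seed=11)
        cfg = PatchConfig(h=0.2, search_radius=5)
        a = np.fliplr(nlmeans_denoise(img, cfg).pixels)
        b = nlmeans_denoise(np.fliplr(img.pixels), cfg).pixels
        assert np.allclose(a, b, atol=1e-12)

    def test_denoising_improves_psnr_on_speckled_phantom(self, phantom_clean):
        gains = []
        for seed in range(5):
            noisy = add_speckle(phantom_clean, SpeckleParams(0.2, seed))
            out = nlmeans_denoise(noisy)
            gains.append(psnr(phantom_clean, out) - psnr(phantom_clean, noisy))
        assert np.mean(gains) > 0


class TestWeightField:
    def test_weights_normalized_and_match_filter_output(self, random_image):
        img = random_image((16, 16), seed=12)
        cfg = PatchConfig(h=0.2, search_radius=4)
        out = nlmeans_denoise(img, cfg).pixels
        for pix in [(0, 0), (7, 8), (15, 15), (3, 12)]:
            wf = weight_field(img, pix, cfg)
            assert wf.weights.sum() == pytest.approx(1.0, abs=1e-10)
            assert wf.normalizer >= 1.0  # self weight exp(0)=1 always counts
            recon = float(
                np.sum(wf.weights * img.pixels[wf.candidates[:, 0], wf.candidates[:, 1]])
            )
            assert recon == pytest.approx(out[pix], abs=1e-10)

    def test_gradient_variant_consistent_too(self, random_image):
        img = random_image((12, 12), seed=13)
        cfg = PatchConfig(h=0.2, search_radius=None, use_gradient=True)
        out = nlmeans_gradient_denoise(img, cfg).pixels
        wf = weight_field(img, (5, 6), cfg)
        recon = float(
            np.sum(wf.weights * img.pixels[wf.candidates[:, 0], wf.candidates[:, 1]])
        )
        assert recon == pytest.approx(out[5, 6], abs=1e-10)


class TestGradientAugmentation:
    def test_constant_image_fixed_point_with_zero_factors(self):
        # both distance factors vanish: exponent 0, maximal weights, and
        # the convex combination of a constant stays the constant
        const = GrayImage(np.full((12, 12), 0.61))
        out = nlmeans_gradient_denoise(const, PatchConfig(h=0.1, search_radius=3))
        assert np.allclose(out.pixels, 0.61, atol=1e-12)

    def test_gradient_factor_amplifies_structural_contrast(self):
        # on a clean step edge, the ratio of cross-edge to same-side patch
        # distance grows once the gradient factor multiplies in: structurally
        # dissimilar candidates are penalized disproportionately
        step = np.zeros((16, 16))
        step[:, 8:] = 0.8
        cfg = PatchConfig(h=0.2, search_radius=None)
        grad = gradient_magnitude(step)
        i, j_cross, j_same = (8, 7), (8, 10), (8, 3)
        d_int_cross = patch_distance(step, i, j_cross, cfg)
        d_int_same = patch_distance(step, i, j_same, cfg)
        dg_cross = patch_distance(grad, i, j_cross, cfg)
        dg_same = patch_distance(grad, i, j_same, cfg)
        plain_ratio = d_int_cross / d_int_same
        product_ratio = (d_int_cross * dg_cross) / (d_int_same * dg_same)
        assert product_ratio > plain_ratio
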