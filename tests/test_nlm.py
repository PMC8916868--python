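"""NLM weights, filters and the ADMM-regularized variant.

The oracle for the filter is a naive triple-loop reference
(tests/oracles.py) that shares no code with the vectorized path.
"""

import dataclasses

import numpy as np
import pytest

from sonoderm.image import Image2D
from sonoderm.nlm import (
    ADMMConfig,
    NLMConfig,
    denoise_nlm,
    denoise_nlm_improved,
    estimate_noise_sigma,
    laplacian_edge_map,
    mu_for_sigma,
    patch_distance,
    patch_weight,
)
from sonoderm.phantom import NoiseSpec, SkinPhantomSpec, add_noise, make_skin_phantom

from oracles import naive_nlm, naive_patch_distance


class TestPatchDistance:
    def test_degenerate_kernel_is_squared_difference(self):
        img = Image2D(np.array([[1.0, 9.0], [5.0, 5.0]]))
        cfg = NLMConfig(mu=1.0, patch_radius=0)
        assert patch_distance(img, (0, 0), (0, 1), cfg) == pytest.approx(64.0)

    def test_self_distance_zero_and_symmetry(self, random_image):
        img = random_image(8, 8)
        cfg = NLMConfig(mu=10.0, patch_radius=1)
        assert patch_distance(img, (3, 3), (3, 3), cfg) == 0.0
        d_ij = patch_distance(img, (1, 2), (6, 4), cfg)
        d_ji = patch_distance(img, (6, 4), (1, 2), cfg)
        assert d_ij == pytest.approx(d_ji, abs=1e-14)

    def test_matches_naive_double_loop(self, random_image):
        img = random_image(8, 8)
        cfg = NLMConfig(mu=10.0, patch_radius=1, gaussian_patch_sd=1.3)
        for i, j in [((0, 0), (7, 7)), ((2, 3), (5, 1)), ((4, 4), (4, 5))]:
            expected = naive_patch_distance(img.pixels, i, j, 1, 1.3)
            assert patch_distance(img, i, j, cfg) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self, random_image):
        img = random_image(8, 8)
        with pytest.raises(IndexError):
            patch_distance(img, (0, 0), (8, 0), NLMConfig(mu=1.0))


class TestPatchWeight:
    def test_identical_patches_weight_one(self):
        img = Image2D(np.tile(np.array([[1.0, 2.0, 3.0]]), (3, 4)))
        cfg = NLMConfig(mu=5.0, patch_radius=1, gamma=2.0)
        # columns 1 and 4 see identical 3x3 patches (pattern period 3)
        assert patch_weight(img, (1, 1), (1, 4), cfg) == pytest.approx(1.0)

    def test_gamma_zero_reduces_to_classic(self, random_image):
        img = random_image(8, 8)
        cfg = NLMConfig(mu=50.0, patch_radius=1, gamma=0.0)
        d = patch_distance(img, (2, 2), (5, 5), cfg)
        assert patch_weight(img, (2, 2), (5, 5), cfg) == pytest.approx(np.exp(-d / 50.0))

    def test_antiphase_patches_get_zero_weight(self):
        # patches [1,2,3] vs [3,2,1] columnwise: centred cosine = -1
        img = Image2D(np.tile(np.array([[1.0, 2.0, 3.0, 2.0, 1.0]]), (3, 1)))
        cfg = NLMConfig(mu=1e12, patch_radius=1, gamma=1.0)
        w = patch_weight(img, (1, 1), (1, 3), cfg)
        assert w == pytest.approx(0.0, abs=1e-12)


class TestDenoiseNLM:
    def test_constant_image_fixed_point(self):
        img = Image2D(np.full((16, 16), 42.0))
        out = denoise_nlm(img, NLMConfig(mu=10.0, search_radius=3))
        assert np.allclose(out.pixels, 42.0, atol=1e-12)

    def test_shift_equivariance(self, random_image):
        img = random_image(16, 16)
        cfg = NLMConfig(mu=200.0, search_radius=3)
        a = denoise_nlm(img, cfg).pixels
        b = denoise_nlm(img.with_pixels(img.pixels + 31.5), cfg).pixels
        assert np.allclose(b - 31.5, a, atol=1e-9)

    def test_output_within_window_range(self, random_image):
        img = random_image(20, 20)
        out = denoise_nlm(img, NLMConfig(mu=100.0, gamma=0.0, search_radius=3)).pixels
        assert out.min() >= img.pixels.min() - 1e-9
        assert out.max() <= img.pixels.max() + 1e-9

    @pytest.mark.parametrize("gamma", [0.0, 1.0])
    @pytest.mark.parametrize("center_rule", ["max_other", "one", "zero"])
    def test_matches_naive_reference(self, random_image, gamma, center_rule):
        img = random_image(12, 12)
        cfg = NLMConfig(
            mu=300.0, patch_radius=1, search_radius=3, gamma=gamma,
            center_weight_rule=center_rule,
        )
        got = denoise_nlm(img, cfg).pixels
        expected = naive_nlm(
            img.pixels, 300.0, 1, 3, 1.0, gamma=gamma, center_rule=center_rule
        )
        assert np.max(np.abs(got - expected)) < 1e-10

    def test_edge_boundary_mode_matches_naive(self, random_image):
        img = random_image(12, 12)
        cfg = NLMConfig(mu=300.0, search_radius=3, gamma=1.0, boundary="edge")
        got = denoise_nlm(img, cfg).pixels
        expected = naive_nlm(img.pixels, 300.0, 1, 3, 1.0, gamma=1.0, boundary="edge")
        assert np.max(np.abs(got - expected)) < 1e-10

    def test_mu_map_reduces_smoothing_where_small(self, layered_phantom):
        _, clean, _ = layered_phantom
        noisy = add_noise(clean, NoiseSpec(sigma=15.0), 3)
        cfg = NLMConfig(mu=450.0, gamma=0.0)
        strong = denoise_nlm(noisy, cfg).pixels
        weak = denoise_nlm(noisy, cfg, mu_map=np.full(noisy.shape, 1e-3)).pixels
        # near-zero mu keeps the image close to the input
        assert np.mean((weak - noisy.pixels) ** 2) < np.mean((strong - noisy.pixels) ** 2)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            denoise_nlm(Image2D(np.zeros((4, 4))), NLMConfig(mu=1.0, search_radius=5))


class TestLaplacianEdgeMap:
    def test_constant_and_ramp_are_zero(self):
        const = Image2D(np.full((10, 10), 3.0))
        assert np.array_equal(laplacian_edge_map(const), np.zeros((10, 10)))
        ramp = Image2D(np.tile(np.arange(10.0), (10, 1)))
        assert np.array_equal(laplacian_edge_map(ramp), np.zeros((10, 10)))

    def test_unit_impulse_normalizes_to_one_at_center(self):
        a = np.zeros((9, 9))
        a[4, 4] = 1.0
        emap = laplacian_edge_map(Image2D(a))
        assert emap[4, 4] == pytest.approx(1.0)
        assert emap[4, 5] == pytest.approx(0.25)  # raw |1| against max |−4|
        assert emap.max() == 1.0


class TestNoiseEstimate:
    @pytest.mark.parametrize("sigma", [5.0, 15.0, 25.0])
    def test_recovers_known_sigma_on_flat_image(self, sigma):
        img = add_noise(Image2D(np.zeros((128, 128))), NoiseSpec(sigma=sigma), 21)
        assert estimate_noise_sigma(img) == pytest.approx(sigma, rel=0.1)


class TestDenoiseImproved:
    def test_beta_zero_is_identity(self, layered_phantom):
        _, clean, _ = layered_phantom
        noisy = add_noise(clean, NoiseSpec(sigma=15.0), 4)
        out = denoise_nlm_improved(noisy, NLMConfig(mu=450.0), ADMMConfig(beta=0.0))
        assert np.array_equal(out.pixels, noisy.pixels)

    def test_constant_image_fixed_point(self):
        img = Image2D(np.full((16, 16), 9.0))
        out = denoise_nlm_improved(img, NLMConfig(mu=10.0, search_radius=3))
        assert np.array_equal(out.pixels, img.pixels)

    def test_shift_equivariance(self, layered_phantom):
        _, clean, _ = layered_phantom
        noisy = add_noise(clean, NoiseSpec(sigma=15.0), 6)
        cfg = NLMConfig(mu=450.0)
        a = denoise_nlm_improved(noisy, cfg).pixels
        b = denoise_nlm_improved(noisy.with_pixels(noisy.pixels + 50.0), cfg).pixels
        assert np.allclose(b - 50.0, a, atol=1e-9)

    @pytest.mark.parametrize("sigma", [10.0, 25.0])
    def test_both_variants_reduce_noise(self, layered_phantom, sigma):
        """MSE(denoised, clean) < MSE(noisy, clean) for each variant and seed."""
        _, clean, _ = layered_phantom
        cfg = NLMConfig(mu=mu_for_sigma(sigma))
        for seed in (1, 2):
            noisy = add_noise(clean, NoiseSpec(sigma=sigma), seed)
            base = np.mean((noisy.pixels - clean.pixels) ** 2)
            classic = denoise_nlm(noisy, dataclasses.replace(cfg, gamma=0.0))
            improved = denoise_nlm_improved(noisy, cfg)
            assert np.mean((classic.pixels - clean.pixels) ** 2) < base
            assert np.mean((improved.pixels - clean.pixels) ** 2) < base
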