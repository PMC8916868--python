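"""Phantom generators: construction consistency, determinism, noise statistics."""

import json

import numpy as np
import pytest
from scipy import stats

from sonoderm.elasto import modulus_stats, shell_ring
from sonoderm.image import Image2D
from sonoderm.phantom import (
    CohortSpec,
    ElasticityPhantomSpec,
    NoiseSpec,
    SkinPhantomSpec,
    add_noise,
    load_image_tiff,
    load_mask_png,
    make_cohort,
    make_elasticity_phantom,
    make_skin_phantom,
    save_image_tiff,
    save_mask_png,
    spec_from_json,
    spec_to_json,
)


class TestSkinPhantom:
    def test_thickness_by_construction(self):
        spec = SkinPhantomSpec(entry_depth_px=40, dermis_base_depth_px=100, pixel_spacing=0.05)
        _, truth = make_skin_phantom(spec, 0)
        assert truth["thickness_mm"] == pytest.approx(3.0)

    def test_textureless_is_piecewise_constant(self):
        img, _ = make_skin_phantom(SkinPhantomSpec(texture_sigma=0.0), 7)
        assert len(np.unique(img.pixels)) <= 3

    def test_layer_levels_match_spec(self):
        spec = SkinPhantomSpec(texture_sigma=0.0, layer_intensities=(10.0, 200.0, 80.0))
        img, truth = make_skin_phantom(spec, 0)
        a = img.pixels
        assert np.all(a[: spec.entry_depth_px] == 10.0)
        assert np.all(a[spec.entry_depth_px : spec.dermis_base_depth_px] == 200.0)
        assert np.all(a[spec.dermis_base_depth_px :] == 80.0)

    def test_determinism(self):
        spec = SkinPhantomSpec()
        a, _ = make_skin_phantom(spec, 42)
        b, _ = make_skin_phantom(spec, 42)
        c, _ = make_skin_phantom(spec, 43)
        assert np.array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, c.pixels)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"entry_depth_px": 0},
            {"entry_depth_px": 100, "dermis_base_depth_px": 40},
            {"dermis_base_depth_px": 300},
            {"pixel_spacing": -1.0},
            {"texture_sigma": -0.1},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SkinPhantomSpec(**kwargs)


class TestNoise:
    def test_sigma_zero_is_identity(self, random_image):
        img = random_image()
        out = add_noise(img, NoiseSpec(sigma=0.0), 3)
        assert np.array_equal(out.pixels, img.pixels)

    def test_additive_moments(self):
        img = Image2D(np.full((256, 256), 100.0))
        out = add_noise(img, NoiseSpec(sigma=20.0), 11)
        resid = out.pixels - img.pixels
        assert abs(resid.mean()) < 0.5
        assert abs(resid.std() - 20.0) < 0.05 * 20.0

    def test_additive_distribution_ks(self):
        """Residuals follow Normal(0, sigma) (KS test at alpha = 0.01)."""
        img = Image2D(np.zeros((128, 128)))
        resid = add_noise(img, NoiseSpec(sigma=15.0), 5).pixels.ravel()
        p = stats.kstest(resid, "norm", args=(0.0, 15.0)).pvalue
        assert p > 0.01

    def test_clipping_bounds(self, random_image):
        img = random_image(lo=0, hi=255)
        out = add_noise(img, NoiseSpec(sigma=500.0, clip_range=(0.0, 255.0)), 1)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 255.0

    def test_speckle_scales_with_intensity(self):
        img = Image2D(np.concatenate([np.full((64, 64), 10.0), np.full((64, 64), 200.0)], axis=1))
        out = add_noise(img, NoiseSpec(kind="speckle_multiplicative", sigma=0.2), 2)
        resid = out.pixels - img.pixels
        assert resid[:, 64:].std() > 5 * resid[:, :64].std()

    def test_determinism_and_validation(self, random_image):
        img = random_image()
        a = add_noise(img, NoiseSpec(sigma=10.0), 9)
        b = add_noise(img, NoiseSpec(sigma=10.0), 9)
        assert np.array_equal(a.pixels, b.pixels)
        with pytest.raises(ValueError):
            NoiseSpec(sigma=-1.0)
        with pytest.raises(ValueError):
            NoiseSpec(clip_range=(5.0, 5.0))


class TestElasticityPhantom:
    def test_lesion_mean_exact_without_jitter(self):
        spec = ElasticityPhantomSpec(jitter_sigma_kpa=0.0, ring_width_mm=None, ring_kpa=None)
        emap, mask = make_elasticity_phantom(spec, 0)
        st = modulus_stats(emap, mask)
        assert st.emean == spec.lesion_kpa
        assert st.esd == 0.0

    def test_hard_ring_ordering(self):
        """ring > lesion > background means: the quantitative hard-ring sign."""
        spec = ElasticityPhantomSpec(jitter_sigma_kpa=0.0)
        emap, mask = make_elasticity_phantom(spec, 0)
        ring = shell_ring(mask, spec.ring_width_mm, spec.pixel_spacing)
        ring_mean = modulus_stats(emap, ring).emean
        lesion_mean = modulus_stats(emap, mask).emean
        outside = ~(mask.mask | ring.mask)
        background_mean = emap.values[outside].mean()
        assert ring_mean > lesion_mean > background_mean

    def test_determinism(self):
        spec = ElasticityPhantomSpec()
        a, _ = make_elasticity_phantom(spec, 5)
        b, _ = make_elasticity_phantom(spec, 5)
        assert np.array_equal(a.values, b.values)

    def test_lesion_must_fit(self):
        with pytest.raises(ValueError):
            ElasticityPhantomSpec(lesion_center=(2, 32), lesion_radius_px=12)


class TestCohort:
    def test_row_count_and_groups(self):
        df = make_cohort(CohortSpec(n_cases=1, n_controls=4, seed=1))
        assert len(df) == 5
        assert (df.group == "case").sum() == 1
        assert (df.group == "control").sum() == 4

    def test_effect_size_shifts_cases(self):
        df = make_cohort(CohortSpec(n_cases=200, n_controls=200, effect_size=3.0,
                                    base_mean=10.0, base_sd=2.0, seed=3))
        shift = df[df.group == "case"].measurement.mean() - df[df.group == "control"].measurement.mean()
        assert shift == pytest.approx(3.0 * 2.0, abs=0.5)

    def test_reproducible(self):
        a = make_cohort(CohortSpec(seed=8))
        b = make_cohort(CohortSpec(seed=8))
        assert a.equals(b)


class TestIO:
    def test_tiff_roundtrip(self, tmp_path, random_image):
        img = random_image(spacing=0.05)
        path = tmp_path / "img.tif"
        save_image_tiff(path, img)
        back = load_image_tiff(path)
        assert np.allclose(back.pixels, img.pixels, atol=1e-4)
        assert back.pixel_spacing == pytest.approx(0.05)

    def test_mask_roundtrip(self, tmp_path):
        _, mask = make_elasticity_phantom(ElasticityPhantomSpec(), 0)
        path = tmp_path / "mask.png"
        save_mask_png(path, mask)
        back = load_mask_png(path)
        assert np.array_equal(back.mask, mask.mask)

    def test_spec_json_roundtrip(self):
        for spec in (
            NoiseSpec(sigma=3.0, clip_range=(0, 255)),
            SkinPhantomSpec(),
            ElasticityPhantomSpec(),
            CohortSpec(seed=9),
        ):
            assert spec_from_json(spec_to_json(spec)) == spec

    def test_cohort_csv_header(self, tmp_path):
        df = make_cohort(CohortSpec(seed=2))
        path = tmp_path / "cohort.csv"
        df.to_csv(path, index=False)
        assert path.read_text().splitlines()[0] == "subject_id,group,measurement"
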