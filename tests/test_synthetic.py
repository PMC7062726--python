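"""The synthetic study-system generator: determinism, ground-truth links."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from stormfall.imaging import build_composite, default_endmembers, normalize_npv, unmix_image
from stormfall.inventory import plot_agb_loss
from stormfall.synthetic import (
    FACTOR_RANGES,
    RISK_FACTORS,
    SceneConfig,
    apply_damage_to_fractions,
    correlated_field,
    default_plot_specs,
    gen_inventory,
    gen_risk_rasters,
    gen_true_damage,
    render_scenes,
    stage_rng,
    true_calibration_slope,
)


class TestRiskRasters:
    def test_deterministic_under_seed(self):
        cfg = SceneConfig(n_rows=20, n_cols=20, seed=11)
        a = gen_risk_rasters(cfg)
        b = gen_risk_rasters(cfg)
        for name in RISK_FACTORS:
            np.testing.assert_array_equal(a.risk_rasters[name], b.risk_rasters[name])

    def test_all_nine_factors_with_requested_shape(self):
        land = gen_risk_rasters(SceneConfig(n_rows=10, n_cols=10))
        assert set(land.risk_rasters) == set(RISK_FACTORS)
        assert all(r.shape == (10, 10) for r in land.risk_rasters.values())

    def test_continuous_factors_span_physical_ranges(self):
        land = gen_risk_rasters(SceneConfig(n_rows=30, n_cols=30, seed=2))
        for name, (lo, hi) in FACTOR_RANGES.items():
            r = land.risk_rasters[name]
            assert r.min() >= lo - 1e-9 and r.max() <= hi + 1e-9

    def test_zero_corr_length_gives_independent_pixels(self):
        field = correlated_field(stage_rng(5, "x"), (100, 100), 0.0)
        r = np.corrcoef(field[:, :-1].ravel(), field[:, 1:].ravel())[0, 1]
        assert abs(r) < 0.1

    def test_positive_corr_length_gives_autocorrelation(self):
        field = correlated_field(stage_rng(5, "x"), (100, 100), 8.0)
        r = np.corrcoef(field[:, :-1].ravel(), field[:, 1:].ravel())[0, 1]
        assert r > 0.8

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(n_rows=0)
        with pytest.raises(ValueError):
            SceneConfig(n_bands=2)
        with pytest.raises(ValueError):
            SceneConfig(cloud_fraction=1.0)


class TestTrueDamage:
    def test_zero_coefficients_give_constant_surface(self):
        land = gen_risk_rasters(SceneConfig(n_rows=15, n_cols=15, seed=1))
        d = gen_true_damage(land, coefficients={}, noise_sd=0.0, intercept=-1.0)
        assert np.ptp(d) == pytest.approx(0.0)
        assert d[0, 0] == pytest.approx(1 / (1 + np.e))

    def test_rainfall_only_surface_is_monotone_in_rainfall(self):
        land = gen_risk_rasters(SceneConfig(n_rows=40, n_cols=40, seed=1))
        d = gen_true_damage(land, coefficients={"storm_rainfall": 1.0}, noise_sd=0.0)
        rho = spearmanr(d.ravel(), land.risk_rasters["storm_rainfall"].ravel()).statistic
        assert rho > 0.99

    def test_unknown_factor_rejected(self):
        land = gen_risk_rasters(SceneConfig(n_rows=10, n_cols=10))
        with pytest.raises(ValueError, match="unknown"):
            gen_true_damage(land, coefficients={"storm_surge": 1.0})

    def test_damage_bounded(self):
        land = gen_risk_rasters(SceneConfig(n_rows=30, n_cols=30, seed=9))
        d = gen_true_damage(land, seed=9)
        assert d.min() >= 0 and d.max() <= 1


class TestFractionModel:
    def test_fraction_closure(self):
        cfg = SceneConfig(n_rows=25, n_cols=25, seed=4)
        land = gen_risk_rasters(cfg)
        gen_true_damage(land, seed=4)
        apply_damage_to_fractions(land, cfg.pre_fractions)
        for fr in (land.fractions_pre, land.fractions_post):
            np.testing.assert_allclose(fr.sum(axis=0), 1.0, atol=1e-12)
            assert fr.min() >= -1e-12

    def test_noiseless_dnpv_equals_mapped_damage(self):
        """post normalized NPV − pre equals d·(1−c): the invertible link that
        makes the calibration slope identifiable."""
        cfg = SceneConfig(n_rows=20, n_cols=20, seed=4, noise_sd=0.0, cloud_fraction=0.0)
        land = gen_risk_rasters(cfg)
        gen_true_damage(land, seed=4)
        apply_damage_to_fractions(land, cfg.pre_fractions)
        pre_n = normalize_npv(land.fractions_pre)
        post_n = normalize_npv(land.fractions_post)
        c = pre_n[0, 0]
        np.testing.assert_allclose(post_n - pre_n, land.damage * (1 - c), atol=1e-12)
        assert true_calibration_slope(cfg.pre_fractions) == pytest.approx(1 / (1 - c))


class TestRenderScenes:
    def _landscape(self, cfg):
        land = gen_risk_rasters(cfg)
        gen_true_damage(land, seed=cfg.seed)
        apply_damage_to_fractions(land, cfg.pre_fractions)
        return land

    def test_noiseless_cloudless_render_is_exact(self, endmembers):
        cfg = SceneConfig(n_rows=12, n_cols=12, noise_sd=0.0, cloud_fraction=0.0, seed=2)
        land = self._landscape(cfg)
        pre, post = render_scenes(land, endmembers, cfg)
        expected = np.einsum("bk,kij->bij", endmembers.spectra, land.fractions_pre)
        for img in pre:
            np.testing.assert_allclose(img.reflectance, expected, atol=1e-12)
            assert img.valid_mask.all()

    def test_pure_gv_pixel_renders_gv_spectrum(self, endmembers):
        cfg = SceneConfig(n_rows=5, n_cols=5, noise_sd=0.0, cloud_fraction=0.0,
                          pre_fractions=(1.0, 0.0, 0.0), seed=2)
        land = self._landscape(cfg)
        land.damage[:] = 0.0
        apply_damage_to_fractions(land, cfg.pre_fractions)
        pre, _ = render_scenes(land, endmembers, cfg)
        np.testing.assert_allclose(pre[0].reflectance[:, 0, 0], endmembers.spectra[:, 0], atol=1e-12)

    def test_noise_rms_matches_configured_sd(self, endmembers):
        cfg = SceneConfig(n_rows=100, n_cols=100, noise_sd=0.01, cloud_fraction=0.0, seed=6)
        land = self._landscape(cfg)
        pre, _ = render_scenes(land, endmembers, cfg)
        clean = np.einsum("bk,kij->bij", endmembers.spectra, land.fractions_pre)
        rms = np.sqrt(np.mean((pre[0].reflectance - clean) ** 2))
        assert abs(rms - 0.01) < 0.002  # within 20% over 10^4 pixels x 6 bands

    def test_cloud_block_size_roughly_matches_fraction(self, endmembers):
        cfg = SceneConfig(n_rows=50, n_cols=50, cloud_fraction=0.2, seed=3,
                          n_images_per_period=4)
        land = self._landscape(cfg)
        pre, _ = render_scenes(land, endmembers, cfg)
        assert pre[0].valid_mask.all()  # coverage image stays clean
        for img in pre[1:]:
            frac = 1 - img.valid_mask.mean()
            assert 0.1 < frac < 0.3

    def test_band_mismatch_rejected(self):
        cfg = SceneConfig(n_rows=5, n_cols=5, n_bands=6, seed=2)
        land = self._landscape(cfg)
        with pytest.raises(ValueError, match="bands"):
            render_scenes(land, default_endmembers(4), cfg)

    def test_deterministic_under_seed(self, endmembers):
        cfg = SceneConfig(n_rows=10, n_cols=10, seed=8)
        land = self._landscape(cfg)
        a, _ = render_scenes(land, endmembers, cfg)
        b, _ = render_scenes(land, endmembers, cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.reflectance, y.reflectance)
            np.testing.assert_array_equal(x.valid_mask, y.valid_mask)


@pytest.fixture()
def landscape():
    cfg = SceneConfig(n_rows=60, n_cols=60, seed=13)
    land = gen_risk_rasters(cfg)
    gen_true_damage(land, seed=13)
    return land


class TestInventory:

    def test_census_threshold_and_determinism(self, landscape, allometry):
        plots = gen_inventory(landscape, seed=13)
        again = gen_inventory(landscape, seed=13)
        assert all(t.dbh_cm >= 10 for p in plots for t in p.trees)
        for p, q in zip(plots, again):
            assert [(t.dbh_cm, t.status, t.canopy_class) for t in p.trees] == [
                (t.dbh_cm, t.status, t.canopy_class) for t in q.trees
            ]

    def test_zero_damage_plot_keeps_all_stems_standing(self, landscape, allometry):
        landscape.damage = np.zeros(landscape.shape)
        specs = [((5, 5), 0.25, 80)]
        plots = gen_inventory(landscape, plot_specs=specs, seed=1)
        assert all(t.status == "standing" for t in plots[0].trees)
        summary = plot_agb_loss(plots[0], allometry)
        assert summary.prop_agb_lost <= 0.05

    def test_high_damage_plot_matches_target(self, landscape, allometry):
        landscape.damage = np.full(landscape.shape, 0.9)
        specs = [((5, 5), 0.25, 100)]
        plots = gen_inventory(landscape, plot_specs=specs, seed=1)
        summary = plot_agb_loss(plots[0], allometry)
        assert 0.85 <= summary.prop_agb_lost <= 0.95

    def test_matching_tolerance_across_plots(self, allometry):
        cfg = SceneConfig(n_rows=80, n_cols=80, seed=21)
        land = gen_risk_rasters(cfg)
        gen_true_damage(land, seed=21)
        plots = gen_inventory(land, seed=21)
        for plot in plots:
            local = np.mean([land.damage[i, j] for i, j in plot.pixels])
            achieved = plot_agb_loss(plot, allometry).prop_agb_lost
            assert abs(achieved - local) <= 0.05

    def test_break_heights_recorded_for_subset_only(self, landscape):
        landscape.damage = np.full(landscape.shape, 0.5)
        specs = [((i * 6, 5), 0.09, 40) for i in range(5)]
        plots = gen_inventory(landscape, plot_specs=specs, seed=2, n_with_break_data=3)
        for plot in plots[:3]:
            assert all(t.break_height_m is not None for t in plot.trees if t.status == "broken")
        for plot in plots[3:]:
            assert all(t.break_height_m is None for t in plot.trees)

    def test_plot_outside_extent_rejected(self, landscape):
        with pytest.raises(ValueError, match="extent"):
            gen_inventory(landscape, plot_specs=[((59, 59), 0.25, 10)], seed=1)


def test_full_chain_noiseless_recovers_exact_slope(allometry):
    """With no sensor noise or clouds, compositing + unmixing + normalization
    reproduces the constructed ΔNPV = d(1-c) link almost exactly."""
    cfg = SceneConfig(n_rows=30, n_cols=30, noise_sd=0.0, cloud_fraction=0.0, seed=17)
    land = gen_risk_rasters(cfg)
    gen_true_damage(land, seed=17)
    apply_damage_to_fractions(land, cfg.pre_fractions)
    E = default_endmembers(cfg.n_bands)
    pre, post = render_scenes(land, E, cfg)

    def norm(images):
        comp = build_composite(images)
        return normalize_npv(unmix_image(comp.reflectance, E))

    dnpv = norm(post) - norm(pre)
    slope = true_calibration_slope(cfg.pre_fractions)
    np.testing.assert_allclose(dnpv * slope, land.damage, atol=1e-8)
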