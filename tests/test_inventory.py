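"""Allometry, BUD loss accounting and the taper model."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from stormfall.inventory import (
    AllometryParams,
    BREAST_HEIGHT_M,
    PlotRecord,
    TaperParams,
    TreeRecord,
    branch_loss_fraction,
    conservative_plot_loss,
    plot_agb_loss,
    plot_pre_agb,
    taper_fraction_above,
    tree_agb,
)


class TestTreeAGB:
    def test_identity_coefficients_return_driver(self, identity_allometry):
        comps = tree_agb(TreeRecord(dbh_cm=20), identity_allometry)
        assert comps["stem"] == pytest.approx(20.0)
        assert comps["total"] == pytest.approx(60.0)

    def test_agb_increases_with_dbh(self, allometry):
        totals = [tree_agb(TreeRecord(dbh_cm=d), allometry)["total"] for d in (10, 20, 40)]
        assert totals[0] < totals[1] < totals[2]

    def test_default_coefficients_match_closed_form(self, allometry):
        comps = tree_agb(TreeRecord(dbh_cm=25), allometry)
        for comp in ("stem", "branch", "leaf"):
            a, b = allometry.coeffs[("dicot", comp)]
            assert comps[comp] == pytest.approx(math.exp(a + b * math.log(25)))

    def test_palm_uses_height_from_dbh_model(self, allometry):
        palm = TreeRecord(dbh_cm=20, group="palm")
        c0, c1 = allometry.palm_height
        h = c0 + c1 * 20
        a, b = allometry.coeffs[("palm", "stem")]
        assert tree_agb(palm, allometry)["stem"] == pytest.approx(math.exp(a + b * math.log(h)))

    def test_census_threshold_enforced(self):
        with pytest.raises(ValueError, match="census"):
            TreeRecord(dbh_cm=9.9)

    def test_bad_exponent_rejected(self):
        with pytest.raises(ValueError, match="exponent"):
            AllometryParams(coeffs={("dicot", "stem"): (0.0, -1.0)})


class TestPlotPreAGB:
    def test_unit_arithmetic(self, identity_allometry):
        # stem+branch+leaf = 3 x dbh kg; one 'tree' of 500/3 cm DBH in 0.25 ha
        tree = TreeRecord(dbh_cm=500 / 3)
        plot = PlotRecord(plot_id="p", area_ha=0.25, trees=[tree])
        assert plot_pre_agb(plot, identity_allometry) == pytest.approx(2.0)

    def test_linearity_in_stems(self, allometry, rng):
        trees = [TreeRecord(dbh_cm=float(d)) for d in rng.uniform(10, 50, 20)]
        one = plot_pre_agb(PlotRecord("p", 1.0, trees), allometry)
        two = plot_pre_agb(PlotRecord("p", 1.0, trees + trees), allometry)
        assert two == pytest.approx(2 * one)

    def test_matches_brute_force_summation(self, allometry, rng):
        trees = [TreeRecord(dbh_cm=float(d)) for d in rng.uniform(10, 80, 50)]
        plot = PlotRecord("p", 0.5, trees)
        expected = sum(tree_agb(t, allometry)["total"] for t in trees) / 1000 / 0.5
        assert plot_pre_agb(plot, allometry) == pytest.approx(expected)


class TestBranchLoss:
    @pytest.mark.parametrize(
        "cls,frac", [("low", 0.125), ("moderate", 0.50), ("severe", 0.875)]
    )
    def test_class_midpoints(self, cls, frac):
        assert branch_loss_fraction(cls) == frac

    def test_recorded_percent_overrides_in_conservative_mode(self):
        assert branch_loss_fraction("moderate", branch_pct=30, conservative=True) == 0.30
        # not in conservative mode the midpoint stands
        assert branch_loss_fraction("moderate", branch_pct=30) == 0.50

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="canopy"):
            branch_loss_fraction("catastrophic")


class TestPlotLoss:
    def test_hand_computed_three_stem_plot(self, identity_allometry, three_stem_plot):
        # all standing / low, leaves off: loss = 0.125 * branch AGB
        s = plot_agb_loss(three_stem_plot, identity_allometry, leaf_loss=False)
        total = 3 * (20 + 30 + 15)  # three equal components
        lost = 0.125 * (20 + 30 + 15)
        assert s.prop_agb_lost == pytest.approx(lost / total)
        assert s.prop_stems_bud == 0
        assert s.stem_density_bud == 0

    def test_leaf_loss_adds_leaf_component(self, identity_allometry, three_stem_plot):
        s = plot_agb_loss(three_stem_plot, identity_allometry, leaf_loss=True)
        total = 3 * 65.0
        assert s.prop_agb_lost == pytest.approx((0.125 * 65 + 65) / total)

    def test_all_dead_means_total_loss(self, allometry):
        trees = [TreeRecord(dbh_cm=d, status="dead") for d in (12, 20, 33)]
        s = plot_agb_loss(PlotRecord("p", 0.1, trees), allometry)
        assert s.prop_agb_lost == pytest.approx(1.0)
        assert s.prop_stems_bud == 1.0
        assert s.prop_basal_area_bud == pytest.approx(1.0)

    def test_basal_area_fraction(self, allometry):
        trees = [
            TreeRecord(dbh_cm=20, status="uprooted"),
            TreeRecord(dbh_cm=20, status="standing"),
        ]
        s = plot_agb_loss(PlotRecord("p", 0.1, trees), allometry)
        assert s.prop_basal_area_bud == pytest.approx(0.5)
        assert s.stem_density_bud == pytest.approx(10.0)  # 1 stem / 0.1 ha

    def test_uprooted_caveat_reported_not_applied(self, allometry):
        trees = [TreeRecord(dbh_cm=20, status="uprooted")]
        s = plot_agb_loss(PlotRecord("p", 0.1, trees), allometry)
        assert s.uprooted_survival_caveat == pytest.approx(0.45)
        assert s.prop_agb_lost == pytest.approx(1.0)  # full loss still counted


class TestTaper:
    def test_break_at_tip_and_ground(self):
        assert taper_fraction_above(30, 20, 20) == pytest.approx(0.0)
        assert taper_fraction_above(30, 20, 0) == pytest.approx(1.0)

    def test_cone_closed_form(self):
        # gamma=1 is a true cone with apex at H: volume above b ~ (H-b)^3
        frac = taper_fraction_above(30, 20.0, 10.0, TaperParams(gamma=1.0))
        assert frac == pytest.approx(((20 - 10) / 20) ** 3, abs=1e-12)

    def test_matches_adaptive_quadrature(self, rng):
        for _ in range(25):
            H = float(rng.uniform(5, 35))
            b = float(rng.uniform(0, H))
            gamma = float(rng.uniform(0.5, 2.5))
            taper = TaperParams(gamma=gamma, n_segments=4000)
            ours = taper_fraction_above(30, H, b, taper)
            prof = lambda h: ((H - h) / (H - BREAST_HEIGHT_M)) ** (2 * gamma)
            above, _ = quad(prof, b, H)
            total, _ = quad(prof, 0, H)
            assert ours == pytest.approx(above / total, abs=1e-6)

    def test_monotone_in_break_height(self):
        fracs = [taper_fraction_above(30, 25, b, TaperParams(gamma=1.6)) for b in np.linspace(0, 25, 11)]
        assert all(a >= b - 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_segment_convergence(self):
        coarse = taper_fraction_above(30, 22, 8, TaperParams(gamma=1.7, n_segments=100))
        fine = taper_fraction_above(30, 22, 8, TaperParams(gamma=1.7, n_segments=10000))
        assert abs(coarse - fine) < 1e-4

    def test_break_above_tip_rejected(self):
        with pytest.raises(ValueError, match="break"):
            taper_fraction_above(30, 20, 21)


class TestConservative:
    def _plot_with_break(self, break_frac):
        trees = [
            TreeRecord(dbh_cm=30, status="broken", height_m=20,
                       break_height_m=break_frac * 20, canopy_class="moderate",
                       branch_pct=50.0, stem_id="b1"),
            TreeRecord(dbh_cm=20, status="standing", height_m=15,
                       canopy_class="low", branch_pct=12.5, stem_id="s1"),
            TreeRecord(dbh_cm=25, status="uprooted", height_m=18, stem_id="u1"),
        ]
        return PlotRecord("p", 0.25, trees)

    def test_conservative_below_standard_with_broken_stems(self, allometry):
        plot = self._plot_with_break(0.5)
        std = plot_agb_loss(plot, allometry)
        con = conservative_plot_loss(plot, allometry)
        assert con.agb_lost_mg_ha < std.agb_lost_mg_ha

    def test_methods_agree_without_broken_stems(self, allometry):
        trees = [
            TreeRecord(dbh_cm=20, status="standing", canopy_class="moderate", branch_pct=50.0),
            TreeRecord(dbh_cm=25, status="dead"),
            TreeRecord(dbh_cm=30, status="uprooted"),
        ]
        plot = PlotRecord("p", 0.25, trees)
        std = plot_agb_loss(plot, allometry)
        con = conservative_plot_loss(plot, allometry)
        assert con.agb_lost_mg_ha == pytest.approx(std.agb_lost_mg_ha)

    def test_break_at_tip_removes_full_stem_component(self, allometry):
        plot = self._plot_with_break(1.0)
        std = plot_agb_loss(plot, allometry)
        con = conservative_plot_loss(plot, allometry)
        broken = plot.trees[0]
        comps = tree_agb(broken, allometry)
        # standard counts the whole broken stem; conservative keeps branch
        # (midpoint = recorded pct) and leaf losses but no stem loss
        expected_diff = comps["stem"] + comps["branch"] * (1 - 0.5)
        diff_kg = (std.agb_lost_mg_ha - con.agb_lost_mg_ha) * 1000 * plot.area_ha
        assert diff_kg == pytest.approx(expected_diff)

    def test_missing_break_height_names_the_stem(self, allometry):
        trees = [TreeRecord(dbh_cm=30, status="broken", height_m=20, stem_id="odd-1")]
        with pytest.raises(ValueError, match="odd-1"):
            conservative_plot_loss(PlotRecord("p", 0.1, trees), allometry)

    def test_synthetic_plot_set_mean_conservative_not_larger(self, allometry):
        from stormfall.synthetic import (
            SceneConfig, gen_risk_rasters, gen_true_damage, gen_inventory,
        )

        cfg = SceneConfig(n_rows=60, n_cols=60, seed=3)
        land = gen_risk_rasters(cfg)
        gen_true_damage(land, seed=3)
        plots = gen_inventory(land, seed=3, n_with_break_data=19,
                              plot_specs=None)
        with_break = plots[:19]
        std = np.mean([plot_agb_loss(p, allometry).prop_agb_lost for p in with_break])
        con = np.mean([conservative_plot_loss(p, allometry).prop_agb_lost for p in with_break])
        assert con <= std
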