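"""Which risk factors drive the damage index, and do they interact?

Samples ΔNPV pixels with co-located risk factors from a synthetic system
whose true damage surface weights storm rainfall above canopy height above
wind, fits a regression forest, and reports permutation importance (VIMP),
minimal depth (MD), a partial-dependence slope and Friedman's H for the
rainfall-soil-water pair.
"""

import numpy as np

from stormfall import imaging
from stormfall.riskmodel import (
    fit_ensemble,
    friedman_h,
    importance_table,
    partial_dependence,
    sample_pixels,
)
from stormfall.synthetic import (
    SceneConfig,
    apply_damage_to_fractions,
    gen_risk_rasters,
    gen_true_damage,
    render_scenes,
)

config = SceneConfig(seed=11)
landscape = gen_risk_rasters(config)
gen_true_damage(landscape, seed=config.seed)
apply_damage_to_fractions(landscape, config.pre_fractions)
endmembers = imaging.default_endmembers(config.n_bands)
pre_images, post_images = render_scenes(landscape, endmembers, config)


def normalized_npv(images):
    comp = imaging.build_composite(images)
    out = imaging.normalize_npv(imaging.unmix_image(comp.reflectance, endmembers))
    return np.where(comp.valid_mask, out, np.nan)


dnpv = imaging.compute_delta_npv(normalized_npv(pre_images), normalized_npv(post_images))

sample = sample_pixels(landscape.risk_rasters, dnpv, n=4000, seed=config.seed)
ensemble = fit_ensemble(sample, n_trees=300, seed=config.seed)
print(f"sampled {sample.n} pixels; holdout R² = {ensemble.test_r2:.3f}")

table = importance_table(ensemble, seed=config.seed).sort_values("rank_vimp")
print("\nrisk-factor importance (VIMP = Δ holdout MSE × 1000; MD = mean first-split depth):")
print(table.round(3).to_string())

curve = partial_dependence(ensemble, "storm_rainfall", grid_size=15)
pd_span = curve["pd"].iloc[-1] - curve["pd"].iloc[0]
print(f"\npartial dependence of ΔNPV on storm rainfall spans {pd_span:+.3f} "
      "across the rainfall range (others held at mean values)")

h = friedman_h(ensemble, "storm_rainfall", "soil_water", n_points=300, seed=config.seed)
print(f"Friedman's H(rainfall, soil water) = {h:.3f} "
      "(0 = additive effects, 1 = pure interaction)")
print(
    "\nRainfall should top both importance rankings, ahead of canopy height "
    "and wind, matching the weights built into the damage surface."
)
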