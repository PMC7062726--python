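"""Synthetic study systems with known ground truth.

Everything downstream of real Sentinel-2 scenes, LiDAR and field campaigns
is emulated here: spatially autocorrelated risk-factor rasters, a true
damage surface in which storm rainfall outweighs wind, pre/post endmember
fractions rendered into noisy multiband images with cloud gaps, first/last
return elevation rasters, and stem censuses whose computed biomass loss
tracks the local true damage.

Ground truth is explicit by construction.  Pre-storm endmember fractions
are spatially constant by default, and true damage ``d`` moves a share of
the GV fraction into NPV (shade untouched):

    f_npv_post = f_npv_pre + d · f_gv_pre,   f_gv_post = (1 − d) · f_gv_pre

so the normalized index change is ΔNPV = d · (1 − c) with
c = f_npv_pre / (f_gv_pre + f_npv_pre), and the true calibration slope of
damage on ΔNPV is 1 / (1 − c) — an identifiable target for recovery tests.

Randomness uses one root seed; every stage derives its own independent
stream keyed by stage name, so adding a stage does not perturb the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .imaging import BandImage, EndmemberSet
from .inventory import (
    AllometryParams,
    PlotRecord,
    TreeRecord,
    plot_agb_loss,
    tree_agb,
)

#: Raster pixel footprint (10 m Sentinel-2-like pixels).
PIXEL_AREA_HA = 0.01

RISK_FACTORS = (
    "wind",
    "storm_rainfall",
    "antecedent_rainfall",
    "slope",
    "curvature",
    "exposure",
    "soil_water",
    "geology",
    "canopy_height",
)

GEOLOGY_CLASSES = ("volcanic", "limestone", "alluvial", "ultramafic")

#: Plausible physical ranges for the continuous risk factors
#: (units: km h⁻¹, mm, mm, degrees, unitless, mm, m).
FACTOR_RANGES = {
    "wind": (100.0, 210.0),
    "storm_rainfall": (200.0, 1500.0),
    "antecedent_rainfall": (50.0, 400.0),
    "slope": (0.0, 45.0),
    "curvature": (-2.0, 2.0),
    "soil_water": (50.0, 300.0),
    "canopy_height": (5.0, 35.0),
}

#: Standardized-scale weights of the true damage surface.  Storm rainfall
#: dominates, canopy height is second, wind third; curvature and exposure
#: are near zero — the ordering the risk model is expected to recover.
DEFAULT_DAMAGE_COEFFS = {
    "storm_rainfall": 1.2,
    "canopy_height": 0.7,
    "wind": 0.45,
    "antecedent_rainfall": 0.30,
    "soil_water": 0.30,
    "slope": 0.15,
    "geology": 0.10,
    "curvature": 0.02,
    "exposure": 0.02,
}

DEFAULT_DAMAGE_INTERCEPT = -0.9


@dataclass
class SceneConfig:
    """Dimensions, noise and cloud settings of a synthetic scene."""

    n_rows: int = 100
    n_cols: int = 100
    n_bands: int = 6
    noise_sd: float = 0.01
    cloud_fraction: float = 0.10
    n_images_per_period: int = 3
    spatial_corr_length: float = 8.0
    seed: int = 0
    #: keep one image per period cloud-free so every pixel is observable
    ensure_coverage: bool = True
    #: spatially constant pre-storm (GV, NPV, shade) fractions
    pre_fractions: tuple = (0.6, 0.1, 0.3)

    def __post_init__(self) -> None:
        if min(self.n_rows, self.n_cols, self.n_images_per_period) <= 0:
            raise ValueError("scene dimensions and image counts must be positive")
        if self.n_bands < 3:
            raise ValueError("unmixing 3 endmembers needs at least 3 bands")
        if not 0 <= self.cloud_fraction < 1:
            raise ValueError("cloud_fraction must lie in [0, 1)")
        if self.noise_sd < 0 or self.spatial_corr_length < 0:
            raise ValueError("noise_sd and spatial_corr_length must be >= 0")
        f = np.asarray(self.pre_fractions, dtype=float)
        if f.shape != (3,) or np.any(f < 0) or abs(f.sum() - 1) > 1e-9:
            raise ValueError("pre_fractions must be 3 non-negative values summing to 1")


@dataclass
class TrueLandscape:
    """Risk rasters plus (once generated) true damage and fractions."""

    risk_rasters: dict
    damage: np.ndarray | None = None
    fractions_pre: np.ndarray | None = None  # (3, rows, cols)
    fractions_post: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.risk_rasters.values())).shape


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """An independent random stream for one pipeline stage.

    Streams are keyed by (root seed, CRC32 of the stage name), so each stage
    is reproducible on its own and insensitive to the others.
    """
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(stage.encode())]))


def correlated_field(
    rng: np.random.Generator, shape: tuple, corr_length: float
) -> np.ndarray:
    """A ~N(0,1) Gaussian random field with the given correlation length.

    White noise is smoothed with a Gaussian kernel (sigma = corr_length in
    pixels) and re-standardized; corr_length 0 leaves pixels independent.
    """
    white = rng.standard_normal(shape)
    if corr_length <= 0:
        return white
    smooth = gaussian_filter(white, sigma=corr_length, mode="reflect")
    sd = smooth.std()
    if sd == 0:  # pathological single-pixel field
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def gen_risk_rasters(config: SceneConfig) -> TrueLandscape:
    """Generate the nine risk-factor rasters.

    Continuous factors are autocorrelated Gaussian fields min-max rescaled
    to plausible physical ranges; topographic exposure is a thresholded
    binary field and geology a four-class partition of a smoothed field.
    All fields are mutually independent and deterministic given the seed.
    """
    shape = (config.n_rows, config.n_cols)
    rasters = {}
    for name, (lo, hi) in FACTOR_RANGES.items():
        f = correlated_field(stage_rng(config.seed, f"risk:{name}"), shape, config.spatial_corr_length)
        span = f.max() - f.min()
        scaled = (f - f.min()) / span if span > 0 else np.full(shape, 0.5)
        rasters[name] = lo + scaled * (hi - lo)
    exp_field = correlated_field(
        stage_rng(config.seed, "risk:exposure"), shape, config.spatial_corr_length
    )
    rasters["exposure"] = (exp_field > 0).astype(float)
    geo_field = correlated_field(
        stage_rng(config.seed, "risk:geology"), shape, config.spatial_corr_length
    )
    edges = np.quantile(geo_field, [0.25, 0.5, 0.75])
    rasters["geology"] = np.digitize(geo_field, edges).astype(float)
    return TrueLandscape(risk_rasters=rasters)


def _standardize(arr: np.ndarray) -> np.ndarray:
    sd = arr.std()
    return (arr - arr.mean()) / sd if sd > 0 else np.zeros_like(arr)


def gen_true_damage(
    landscape: TrueLandscape,
    coefficients: dict | None = None,
    noise_sd: float = 0.25,
    seed: int = 0,
    intercept: float = DEFAULT_DAMAGE_INTERCEPT,
    rain_soil_interaction: float = 0.0,
) -> np.ndarray:
    """The true proportion-of-AGB-lost surface in [0, 1].

    damage = logistic(intercept + Σ wᵢ·zᵢ [+ w_rs·z_rain·z_soil] + noise),
    where zᵢ are standardized risk factors (geology enters through centered
    per-class effects).  Defaults weight rainfall above canopy height above
    wind, with curvature and exposure near zero.
    """
    coeffs = dict(DEFAULT_DAMAGE_COEFFS if coefficients is None else coefficients)
    unknown = set(coeffs) - set(RISK_FACTORS)
    if unknown:
        raise ValueError(f"unknown risk factor(s) in coefficients: {sorted(unknown)}")
    lin = np.full(landscape.shape, float(intercept))
    for name, w in coeffs.items():
        raster = landscape.risk_rasters[name]
        if name == "geology":
            # centered per-class effects spanning ~2 standardized units
            levels = np.array([-1.0, -0.3, 0.3, 1.0])
            lin += w * levels[raster.astype(int)]
        else:
            lin += w * _standardize(raster)
    if rain_soil_interaction:
        lin += rain_soil_interaction * _standardize(
            landscape.risk_rasters["storm_rainfall"]
        ) * _standardize(landscape.risk_rasters["soil_water"])
    if noise_sd > 0:
        lin = lin + stage_rng(seed, "damage").normal(0.0, noise_sd, landscape.shape)
    damage = np.clip(expit(lin), 0.0, 1.0)
    landscape.damage = damage
    return damage


def apply_damage_to_fractions(
    landscape: TrueLandscape, pre_fractions: tuple = (0.6, 0.1, 0.3)
) -> None:
    """Fill pre/post endmember fractions from the true damage surface.

    Damage moves the share ``d`` of the GV fraction into NPV; shade is
    untouched, so fractions stay closed and the normalized index change is
    a monotone, invertible function of d.
    """
    if landscape.damage is None:
        raise ValueError("generate the damage surface first")
    gv, npv, shade = (float(v) for v in pre_fractions)
    shape = landscape.shape
    d = landscape.damage
    pre = np.empty((3, *shape))
    pre[0], pre[1], pre[2] = gv, npv, shade
    post = np.empty_like(pre)
    post[0] = gv * (1.0 - d)
    post[1] = npv + gv * d
    post[2] = shade
    landscape.fractions_pre = pre
    landscape.fractions_post = post


def true_calibration_slope(pre_fractions: tuple = (0.6, 0.1, 0.3)) -> float:
    """Slope of true damage regressed on ΔNPV under the fraction model.

    ΔNPV = d·(1−c) with c the pre-storm normalized NPV, so the slope is
    1/(1−c) and the intercept 0.
    """
    gv, npv, _ = (float(v) for v in pre_fractions)
    c = npv / (gv + npv)
    return 1.0 / (1.0 - c)


def _cloud_mask(rng: np.random.Generator, shape: tuple, cloud_fraction: float) -> np.ndarray:
    """Validity mask with one uniformly placed rectangular cloud block."""
    valid = np.ones(shape, dtype=bool)
    if cloud_fraction <= 0:
        return valid
    rows, cols = shape
    h = min(max(int(round(rows * np.sqrt(cloud_fraction))), 1), rows)
    w = min(max(int(round(cols * np.sqrt(cloud_fraction))), 1), cols)
    i = int(rng.integers(0, rows - h + 1))
    j = int(rng.integers(0, cols - w + 1))
    valid[i : i + h, j : j + w] = False
    return valid


def render_scenes(
    landscape: TrueLandscape, endmembers: EndmemberSet, config: SceneConfig
) -> tuple:
    """Render pre- and post-storm image stacks from the fraction rasters.

    Each pixel is E·f plus Gaussian sensor noise; each image carries one
    rectangular cloud gap of ≈ ``cloud_fraction`` of its area (the first
    image per period stays cloud-free when ``ensure_coverage`` is set).
    """
    if landscape.fractions_pre is None or landscape.fractions_post is None:
        raise ValueError("landscape has no endmember fractions; run apply_damage_to_fractions")
    if endmembers.n_bands != config.n_bands:
        raise ValueError(
            f"endmembers have {endmembers.n_bands} bands but config expects {config.n_bands}"
        )
    E = endmembers.spectra

    def render(fractions: np.ndarray, period: str) -> list:
        rng = stage_rng(config.seed, f"render:{period}")
        clean = np.einsum("bk,kij->bij", E, fractions)
        images = []
        for m in range(config.n_images_per_period):
            refl = clean.copy()
            if config.noise_sd > 0:
                refl = refl + rng.normal(0.0, config.noise_sd, clean.shape)
            if m == 0 and config.ensure_coverage:
                mask = np.ones(landscape.shape, dtype=bool)
            else:
                mask = _cloud_mask(rng, landscape.shape, config.cloud_fraction)
            images.append(BandImage(refl, mask))
        return images

    return render(landscape.fractions_pre, "pre"), render(landscape.fractions_post, "post")


def render_return_rasters(
    landscape: TrueLandscape, config: SceneConfig, terrain_relief_m: float = 300.0
) -> tuple:
    """First/last-return elevation rasters consistent with canopy height.

    Last returns follow a smooth synthetic terrain; first returns add the
    true canopy-height raster, so differencing recovers height exactly.
    """
    rng = stage_rng(config.seed, "returns")
    terrain = terrain_relief_m * (
        correlated_field(rng, landscape.shape, max(config.spatial_corr_length, 1.0)) * 0.5 + 1.0
    )
    first = terrain + landscape.risk_rasters["canopy_height"]
    return first, terrain


def default_plot_specs(
    landscape: TrueLandscape,
    n_plots: int = 25,
    area_ha: float = 0.25,
    stems_per_ha: float = 450.0,
    seed: int = 0,
) -> list:
    """Random non-overlapping square plot footprints inside the raster."""
    rng = stage_rng(seed, "plots")
    side = int(round(np.sqrt(area_ha / PIXEL_AREA_HA)))
    rows, cols = landscape.shape
    if rows < side or cols < side:
        raise ValueError("raster too small for the requested plot area")
    specs, taken = [], set()
    attempts = 0
    while len(specs) < n_plots and attempts < 10000:
        attempts += 1
        i = int(rng.integers(0, rows - side + 1))
        j = int(rng.integers(0, cols - side + 1))
        cells = {(i + di, j + dj) for di in range(side) for dj in range(side)}
        if cells & taken:
            continue
        taken |= cells
        specs.append(((i, j), area_ha, int(round(stems_per_ha * area_ha))))
    if len(specs) < n_plots:
        raise ValueError("could not place the requested number of non-overlapping plots")
    return specs


def _gen_stems(
    rng: np.random.Generator,
    n_stems: int,
    allometry: AllometryParams,
    dbh_scale_cm: float,
    palm_fraction: float,
    plot_id: str,
) -> list:
    trees = []
    for s in range(n_stems):
        dbh = 10.0 + float(rng.exponential(dbh_scale_cm))
        dbh = min(dbh, 150.0)
        group = "palm" if rng.random() < palm_fraction else "dicot"
        if group == "palm":
            c0, c1 = allometry.palm_height
            height = c0 + c1 * dbh
        else:
            height = min(2.5 * dbh**0.53 * float(rng.uniform(0.9, 1.1)), 38.0)
        trees.append(
            TreeRecord(
                dbh_cm=dbh,
                group=group,
                height_m=height,
                stem_id=f"{plot_id}-{s:04d}",
            )
        )
    return trees


def _assign_damage(
    rng: np.random.Generator,
    trees: list,
    target: float,
    allometry: AllometryParams,
    leaf_loss: bool,
    record_details: bool,
) -> None:
    """Assign statuses/classes so standard-accounting loss ≈ target (in place).

    Greedy: starting from all-standing/low, flip stems to BUD whenever that
    moves the plot loss closer to the target share of plot AGB (overshoot is
    allowed when it is the nearer outcome, keeping the matching error
    centred on zero), then fine-tune with canopy-class upgrades of the
    remaining standing stems under the same rule.
    """
    comps = [tree_agb(t, allometry) for t in trees]
    total = sum(c["total"] for c in comps)
    base = [
        c["branch"] * 0.125 + (c["leaf"] if leaf_loss else 0.0) for c in comps
    ]
    current = sum(base)
    goal = target * total
    order = rng.permutation(len(trees))
    for idx in order:
        gain = comps[idx]["total"] - base[idx]
        if abs(current + gain - goal) < abs(current - goal):
            status = rng.choice(BUD_CHOICES, p=BUD_PROBS)
            trees[idx].status = str(status)
            current += gain
    # fine-tune with canopy-class upgrades on standing stems
    for idx in order:
        if trees[idx].status != "standing":
            continue
        branch = comps[idx]["branch"]
        best, best_dist = None, abs(current - goal)
        for cls, frac in (("moderate", 0.50), ("severe", 0.875)):
            gain = branch * (frac - 0.125)
            dist = abs(current + gain - goal)
            if dist < best_dist:
                best, best_dist, best_gain = cls, dist, gain
        if best is not None:
            trees[idx].canopy_class = best
            current += best_gain
    for t in trees:
        if t.status == "broken" and record_details:
            t.break_height_m = float(rng.uniform(0.2, 0.7)) * t.height_m
        if record_details:
            t.branch_pct = CANOPY_PCTS[t.canopy_class]


BUD_CHOICES = np.array(["broken", "uprooted", "dead"])
BUD_PROBS = (0.45, 0.30, 0.25)
CANOPY_PCTS = {"low": 12.5, "moderate": 50.0, "severe": 87.5}


def gen_inventory(
    landscape: TrueLandscape,
    plot_specs: list | None = None,
    allometry: AllometryParams | None = None,
    seed: int = 0,
    n_with_break_data: int | None = None,
    leaf_loss: bool = True,
    dbh_scale_cm: float = 12.0,
    palm_fraction: float = 0.15,
    couple_height: bool = True,
) -> list:
    """Generate stem censuses consistent with the local true damage.

    Each plot's stems are drawn with DBH 10 cm plus a truncated-exponential
    excess (scale tied to local canopy height when ``couple_height``, so
    taller stands carry more biomass), and damage statuses are assigned so
    the plot's standard-accounting proportion of AGB lost matches the mean
    of the true damage surface over the plot footprint to within a few
    percent.  Break heights and branch-loss percents are recorded for the
    first ``n_with_break_data`` plots (default: all but 6, emulating a
    19-of-25 survey subset).
    """
    if landscape.damage is None:
        raise ValueError("generate the damage surface before the inventory")
    allometry = allometry or AllometryParams.default()
    if plot_specs is None:
        plot_specs = default_plot_specs(landscape, seed=seed)
    if n_with_break_data is None:
        n_with_break_data = max(len(plot_specs) - 6, 0)
    rows, cols = landscape.shape
    mean_height = float(landscape.risk_rasters["canopy_height"].mean())
    plots = []
    for p, ((i0, j0), area_ha, n_stems) in enumerate(plot_specs):
        side = int(round(np.sqrt(area_ha / PIXEL_AREA_HA)))
        if not (0 <= i0 <= rows - side and 0 <= j0 <= cols - side):
            raise ValueError(f"plot at ({i0}, {j0}) falls outside the raster extent")
        plot_id = f"P{p:02d}"
        rng = stage_rng(seed, f"inventory:{plot_id}")
        pixels = [(i0 + di, j0 + dj) for di in range(side) for dj in range(side)]
        local_damage = float(np.mean([landscape.damage[i, j] for i, j in pixels]))
        scale = dbh_scale_cm
        if couple_height:
            h_local = float(
                np.mean([landscape.risk_rasters["canopy_height"][i, j] for i, j in pixels])
            )
            scale = dbh_scale_cm * float(np.clip(0.4 + 0.6 * h_local / mean_height, 0.4, 1.8))
        trees = _gen_stems(rng, n_stems, allometry, scale, palm_fraction, plot_id)
        _assign_damage(
            rng, trees, local_damage, allometry, leaf_loss, record_details=p < n_with_break_data
        )
        geometry = shapely.box(j0, i0, j0 + side, i0 + side)
        plots.append(
            PlotRecord(plot_id=plot_id, area_ha=area_ha, trees=trees, geometry=geometry, pixels=pixels)
        )
    return plots
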