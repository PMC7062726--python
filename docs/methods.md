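# Methods

## Damage index

Spectral mixture analysis assumes each pixel's reflectance is a convex
combination of GV, NPV and shade endmember spectra. The unmixing operator
solves the sum-to-one-constrained least-squares problem in closed form (a
Lagrange correction of the OLS solution), then clips negative fractions to
zero and renormalizes. This keeps the default path linear-algebraic and
vectorized over whole rasters; a fully simplex-constrained per-pixel NNLS
solve is available via `method="simplex"`. On noiseless mixtures both agree
with a brute-force simplex grid search to within the grid step.

The built-in endmember spectra are synthetic: GV with a strong NIR plateau
and red absorption, NPV flat and moderately bright, shade near zero. Their
condition number is ≈8, so unmixing noise amplification is modest. Real
analyses should substitute image-derived or library endmembers via the CSV
interface; no endmember extraction is provided.

Median compositing uses the median over cloud-free observations per pixel
and band, averaging the central pair for even counts; a pixel is valid if
observed at least once. Composites are therefore invariant to image order
and duplication. Normalization `NPV/(GV+NPV)` removes the shade fraction so
that illumination differences cancel; a pure-shade pixel (denominator 0) is
marked invalid. ΔNPV is post − pre, so damage is positive. Negative values
denote re-greening and are retained on the risk-model path (exposed as a
flag) but zeroed for biomass estimation, where only damage is of interest.

## Plot accounting

Component allometries are ln-linear (`ln AGB_kg = a + b·ln driver`), driver
DBH (cm) for dicots and modelled height (m) for palms
(`height = c0 + c1·DBH`). The shipped coefficients are synthetic defaults
chosen to produce wet-tropical magnitudes — a 20 cm dicot carries ≈132 kg,
split ≈83/15/2% among stem/branch/leaf — and live in a JSON-serializable
parameter object precisely because site-calibrated coefficients must replace
them for real use. Stems under the 10 cm census threshold raise rather than
being dropped silently: a sub-threshold record signals a data error, not a
small tree.

Loss accounting follows two schemes. Standard: whole-stem AGB of broken,
uprooted and dead stems, plus branch AGB × canopy-class midpoint
(12.5/50/87.5%) and full leaf AGB for standing stems. Conservative: broken
stems contribute stem AGB × the fraction of bole volume above the recorded
break height, with recorded branch-loss percents overriding class midpoints.
The bole profile is `r(h) = r_bh·((H−h)/(H−1.3))^γ`, anchored at breast
height, integrated as n (default 100) truncated cones; γ defaults to 1 (a
true cone, for which the frustum sum is exact at any segment count) and the
integral converges to <1e-4 of the quadrature value by n = 100 for γ up to 3.
A broken stem without a break height raises an error naming the stem, so
plots lacking break data are excluded explicitly, never silently downgraded.
Stems both broken and uprooted are recorded as uprooted (uprooting
dominates). Uprooted stems alive at census count as lost under both schemes;
the ~45% of uprooted stems that may survive is carried as a caveat field on
every summary and never subtracted.

## Upscaling

Both calibrations are ordinary least squares with the sufficient statistics
(n, x̄, Sxx, residual variance) stored for the CI of the *mean response*:
`ŷ ± t(n−2)·s·sqrt(1/n + (x−x̄)²/Sxx)`. The interval of the mean response —
not a prediction interval — is used deliberately, and landscape bounds are
the sums of per-pixel bounds. That propagation treats pixel-level errors as
perfectly correlated (a single miscalibrated line shifts every pixel
together), which is coherent for calibration error but overstates the width
relative to any treatment with independent pixel noise; the two regressions'
uncertainties are propagated independently (loss bound = damage bound × AGB
bound) since no joint error model is available. Proportion-loss predictions
are clipped to [0,1] and negative AGB predictions (possible at very low
canopy height) to 0, with a count of clipped pixels reported. The
damage calibration is fit on zero-clamped plot ΔNPV. Canopy height is
first-return minus last-return elevation, with values outside 0–40 m marked
invalid as physically implausible. Carbon is exactly 50% of AGB everywhere.

## Risk attribution

The forest fit delegates to scikit-learn's `RandomForestRegressor`
(mtry = p/3, the regression convention), but all four statistics are
computed by this package from tree structures and predictions so that their
conventions are explicit and testable:

- **VIMP**: Δ mean-squared error ×1000 on a seed-fixed 25% holdout when one
  factor's columns are permuted jointly. A raw ΔMSE is reported, with no
  normalization beyond the ×1000 scaling. The holdout replaces per-tree
  out-of-bag evaluation, which the underlying library does not expose
  per-tree without refitting machinery.
- **Minimal depth**: mean depth of the shallowest split on a factor
  (root = 0); trees never splitting on it contribute max-depth + 1, the
  standard penalty convention.
- **Partial dependence** defaults to conditioning at the mean of the other
  factors — a single synthetic row per grid value — with the classical
  data-averaged variant behind `conditioning="data"`. For additive signals
  the two agree up to centering.
- **Friedman's H** uses classical (data-averaged) partial dependence
  evaluated at a subsample's own points, as the H decomposition requires:
  `H² = Σ(PDjk − PDj − PDk)²/ΣPDjk²` over centered functions, clipped to
  [0,1]. The two-way function costs O(n²) predictions, hence the subsample
  (3,000 points at full scale; tests use 200–300).

Geology is one-hot encoded internally and reported as one factor (columns
permuted together; minimal depth over any level). With very few predictors
and mtry = p/3 = 1, minimal depth is uninformative because root splits are
random; rankings are meaningful from roughly 4+ encoded features upward.

## Synthetic study systems

The generator emulates the study design, not the physics. Continuous risk
factors are Gaussian random fields (white noise smoothed at an 8-pixel
correlation length, min-max rescaled to plausible physical ranges: wind
100–210 km h⁻¹, storm rainfall 200–1,500 mm, antecedent rainfall 50–400 mm,
slope 0–45°, soil water storage 50–300 mm, canopy height 5–35 m); exposure
is a thresholded binary field and geology a four-class partition. The true
damage surface is a logistic transform of the standardized factors with
weights fixed at rainfall 1.2 > canopy height 0.7 > wind 0.45 > antecedent
rainfall = soil water 0.3 > slope 0.15 > curvature = exposure 0.02 (plus an
optional rainfall×soil-water interaction, off by default), matching the
qualitative structure the attribution stage is expected to recover.

Damage maps to fractions by moving the share d of GV into NPV with shade
untouched, and pre-storm fractions are spatially constant (0.6/0.1/0.3), so
ΔNPV = d(1−c) with c = 1/7 — the calibration slope has the known true value
7/6, identifiable without auxiliary assumptions. Scenes add Gaussian sensor
noise (σ = 0.01 reflectance) and one uniformly placed rectangular cloud
block per image (≈10% of area; the first image per period stays clean so
every pixel is observable). Each 0.25 ha plot draws ~112 stems with DBH
10 cm + a truncated-exponential excess (scale 12 cm, modulated by local
canopy height so taller stands carry more biomass and the height–AGB
regression has signal), 15% palms; statuses are assigned greedily so the
standard-accounting loss matches the local mean damage, flipping stems to
BUD whenever that moves the plot closer to the target and fine-tuning with
canopy-class upgrades. The symmetric flip rule keeps the matching error
centred on zero; a one-sided rule attenuates the calibration slope
measurably. Break heights and branch percents are recorded for all but six
plots, mirroring a 19-of-25 survey subset. All randomness flows from one
root seed through independent per-stage streams keyed by stage name.

What the generator does **not** emulate: radiative transfer, sensor PSFs,
atmospheric or BRDF effects, realistic storm wind fields, within-plot
damage heterogeneity (stems are exchangeable within a plot), spatially
structured inventory error, or endmember uncertainty. Passing tests
therefore demonstrate that the estimators recover truth under the stated
observation model — not that the defaults are calibrated to any particular
real forest.

## Problem sizes and determinism

The default validation scale is a 100×100-pixel landscape with 25 plots;
calibration-recovery experiments use 200 seeded replicates, importance
ordering 50 replicates at 200 trees and n = 2,000 samples, and H
discrimination 3 seeds per response type at n = 2,000 — sizes at which every
experiment is reproducible in minutes on one CPU while leaving the
statistics comfortably clear of their thresholds. All stochastic results are
bit-reproducible given a seed.

## Known limitations

- CI totals inherit the perfect-correlation propagation described above;
  asymmetric intervals (e.g. from fitting on a transformed scale) are not
  produced by the natural-scale height–AGB fit.
- The clip-and-renormalize unmixing is not the exact simplex projection for
  pixels far outside the simplex; the `simplex` method is, at per-pixel cost.
- Feature masking operates on pixel centers in raster coordinates; there is
  no CRS handling or reprojection anywhere in the package.
- Minimal depth and VIMP share the caveats of all impurity/permutation
  measures under correlated predictors; the generator's factors are
  independent by construction, real landscapes' are not.
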