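"""Calibration regressions and island-scale biomass / carbon totals.

Two ordinary-least-squares calibrations link the field plots to the rasters:
ΔNPV → proportion of AGB lost, and area-weighted canopy height → pre-storm
AGB (Mg ha⁻¹).  Each fitted model stores the sufficient statistics for the
95% confidence interval of its *mean response*; applying both to every valid
pixel and summing points and bounds (× pixel area) gives landscape totals in
Tg, with carbon taken as 50% of AGB throughout.

Summing per-pixel CI bounds reproduces the published propagation scheme; it
treats pixel errors as perfectly correlated and therefore overstates the
width of the total's interval relative to an independent-error treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import stats

#: Carbon mass fraction of aboveground biomass.
CARBON_FRACTION = 0.5

MAX_CANOPY_HEIGHT_M = 40.0


@dataclass
class LinearCalibration:
    """An OLS fit y = intercept + slope·x with CI-of-mean-response support."""

    slope: float
    intercept: float
    r_squared: float
    residual_variance: float
    n: int
    x_mean: float
    sxx: float

    def predict(self, x_new) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x_new, dtype=float)


@dataclass
class IslandTotals:
    """Landscape sums (Tg) of pre-storm AGB, AGB loss and carbon loss."""

    total_pre_agb_tg: float
    pre_agb_ci_tg: tuple
    total_agb_loss_tg: float
    agb_loss_ci_tg: tuple
    total_carbon_loss_tg: float
    carbon_loss_ci_tg: tuple
    pixel_area_ha: float
    n_pixels: int
    n_clipped_negative_agb: int = 0


@dataclass
class PixelEstimates:
    """Per-pixel point estimates and 95% bounds (NaN where invalid)."""

    pre_agb: np.ndarray
    pre_agb_lo: np.ndarray
    pre_agb_hi: np.ndarray
    prop_loss: np.ndarray
    prop_loss_lo: np.ndarray
    prop_loss_hi: np.ndarray
    agb_loss: np.ndarray
    agb_loss_lo: np.ndarray
    agb_loss_hi: np.ndarray

    @property
    def carbon_loss(self) -> np.ndarray:
        return CARBON_FRACTION * self.agb_loss


def carbon_from_agb(agb):
    """Carbon mass as the fixed 50% fraction of aboveground biomass."""
    out = CARBON_FRACTION * np.asarray(agb, dtype=float)
    return float(out) if out.ndim == 0 else out


def derive_canopy_height(
    first_return: np.ndarray,
    last_return: np.ndarray,
    max_height: float = MAX_CANOPY_HEIGHT_M,
) -> np.ndarray:
    """Canopy height = first-return − last-return elevation.

    Heights below 0 m or above ``max_height`` (default 40 m) are physically
    implausible and are returned as NaN (invalid).
    """
    first_return = np.asarray(first_return, dtype=float)
    last_return = np.asarray(last_return, dtype=float)
    if first_return.shape != last_return.shape:
        raise ValueError("first/last return rasters differ in shape")
    h = first_return - last_return
    return np.where((h < 0) | (h > max_height), np.nan, h)


def area_weighted_height(geometry, height: np.ndarray, pixel_size: float = 1.0) -> float:
    """Area-weighted mean of valid height pixels overlapping a plot polygon.

    The geometry lives in raster pixel coordinates (x = column, y = row)
    scaled by ``pixel_size``; each pixel contributes its height weighted by
    the area of its overlap with the polygon.
    """
    height = np.asarray(height, dtype=float)
    minx, miny, maxx, maxy = geometry.bounds
    j0 = max(int(np.floor(minx / pixel_size)), 0)
    i0 = max(int(np.floor(miny / pixel_size)), 0)
    j1 = min(int(np.ceil(maxx / pixel_size)), height.shape[1])
    i1 = min(int(np.ceil(maxy / pixel_size)), height.shape[0])
    wsum = hsum = 0.0
    for i in range(i0, i1):
        for j in range(j0, j1):
            if not np.isfinite(height[i, j]):
                continue
            cell = shapely.box(
                j * pixel_size, i * pixel_size, (j + 1) * pixel_size, (i + 1) * pixel_size
            )
            w = geometry.intersection(cell).area
            if w > 0:
                wsum += w
                hsum += w * height[i, j]
    if wsum == 0:
        raise ValueError("plot geometry overlaps no valid height pixels")
    return hsum / wsum


def fit_linear(x, y) -> LinearCalibration:
    """Ordinary least squares of y on x with CI sufficient statistics."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points to fit and assess a line")
    x_mean = x.mean()
    sxx = float(np.sum((x - x_mean) ** 2))
    if sxx == 0:
        raise ValueError("x is constant; slope is not identifiable")
    sxy = float(np.sum((x - x_mean) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x_mean)
    resid = y - (intercept + slope * x)
    rss = float(np.sum(resid**2))
    syy = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - rss / syy if syy > 0 else 1.0
    return LinearCalibration(
        slope=float(slope),
        intercept=intercept,
        r_squared=float(np.clip(r_squared, 0.0, 1.0)),
        residual_variance=rss / (n - 2),
        n=n,
        x_mean=float(x_mean),
        sxx=sxx,
    )


def predict_with_ci(
    model: LinearCalibration,
    x_new,
    level: float = 0.95,
    clip: str | None = None,
):
    """Point estimate and CI of the mean response at new predictor values.

    bounds = ŷ ± t(n−2) · sqrt(s²·(1/n + (x−x̄)²/Sxx)).  ``clip='proportion'``
    clips everything to [0, 1] (for proportion-of-AGB-lost predictions);
    ``clip='nonnegative'`` clips below at 0 (for biomass predictions).
    """
    x_new = np.asarray(x_new, dtype=float)
    point = model.predict(x_new)
    tcrit = stats.t.ppf(0.5 + level / 2.0, model.n - 2)
    se = np.sqrt(
        model.residual_variance * (1.0 / model.n + (x_new - model.x_mean) ** 2 / model.sxx)
    )
    lower = point - tcrit * se
    upper = point + tcrit * se
    if clip == "proportion":
        point, lower, upper = (np.clip(v, 0.0, 1.0) for v in (point, lower, upper))
    elif clip == "nonnegative":
        point, lower, upper = (np.clip(v, 0.0, None) for v in (point, lower, upper))
    elif clip is not None:
        raise ValueError(f"unknown clip mode {clip!r}")
    return point, lower, upper


def slope_ci(model: LinearCalibration, level: float = 0.95) -> tuple:
    """Confidence interval for the fitted slope."""
    tcrit = stats.t.ppf(0.5 + level / 2.0, model.n - 2)
    se = np.sqrt(model.residual_variance / model.sxx)
    return model.slope - tcrit * se, model.slope + tcrit * se


def estimate_landscape(
    delta,
    height: np.ndarray,
    cal_damage: LinearCalibration,
    cal_agb: LinearCalibration,
    pixel_area_ha: float,
    level: float = 0.95,
):
    """Per-pixel biomass loss and landscape totals from the two calibrations.

    ``delta`` is the zero-clamped ΔNPV raster (a DeltaNPVRaster or plain
    array); ``height`` the canopy-height raster in metres.  For each pixel
    valid in both: proportion lost = damage calibration at ΔNPV (clipped to
    [0, 1]); pre-AGB = height calibration (negative predictions clipped to 0
    and counted); loss = product; carbon = 0.5 × loss.  Totals and their
    bounds are pixel sums × pixel area, in Tg.
    """
    darr = np.asarray(getattr(delta, "delta", delta), dtype=float)
    height = np.asarray(height, dtype=float)
    if darr.shape != height.shape:
        raise ValueError("ΔNPV and height rasters are misaligned")
    valid = np.isfinite(darr) & np.isfinite(height)

    nan = np.full(darr.shape, np.nan)
    prop, prop_lo, prop_hi = (nan.copy() for _ in range(3))
    pre, pre_lo, pre_hi = (nan.copy() for _ in range(3))

    p, lo, hi = predict_with_ci(cal_damage, darr[valid], level, clip="proportion")
    prop[valid], prop_lo[valid], prop_hi[valid] = p, lo, hi
    raw_point = cal_agb.predict(height[valid])
    n_clipped = int(np.sum(raw_point < 0))
    a, alo, ahi = predict_with_ci(cal_agb, height[valid], level, clip="nonnegative")
    pre[valid], pre_lo[valid], pre_hi[valid] = a, alo, ahi

    loss = prop * pre
    loss_lo = prop_lo * pre_lo
    loss_hi = prop_hi * pre_hi

    to_tg = pixel_area_ha * 1e-6  # Mg ha^-1 per pixel -> Tg
    totals = IslandTotals(
        total_pre_agb_tg=float(np.nansum(pre)) * to_tg,
        pre_agb_ci_tg=(float(np.nansum(pre_lo)) * to_tg, float(np.nansum(pre_hi)) * to_tg),
        total_agb_loss_tg=float(np.nansum(loss)) * to_tg,
        agb_loss_ci_tg=(float(np.nansum(loss_lo)) * to_tg, float(np.nansum(loss_hi)) * to_tg),
        total_carbon_loss_tg=float(np.nansum(loss)) * to_tg * CARBON_FRACTION,
        carbon_loss_ci_tg=(
            float(np.nansum(loss_lo)) * to_tg * CARBON_FRACTION,
            float(np.nansum(loss_hi)) * to_tg * CARBON_FRACTION,
        ),
        pixel_area_ha=pixel_area_ha,
        n_pixels=int(valid.sum()),
        n_clipped_negative_agb=n_clipped,
    )
    estimates = PixelEstimates(
        pre_agb=pre, pre_agb_lo=pre_lo, pre_agb_hi=pre_hi,
        prop_loss=prop, prop_loss_lo=prop_lo, prop_loss_hi=prop_hi,
        agb_loss=loss, agb_loss_lo=loss_lo, agb_loss_hi=loss_hi,
    )
    return estimates, totals
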