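"""Cloud-free compositing and the spectral-mixture damage index (ΔNPV).

The damage index is built in four steps: (1) median-composite a stack of
partly cloudy multiband images into one cloud-free image per period,
(2) linearly unmix every pixel into green-vegetation (GV),
non-photosynthetic-vegetation (NPV) and shade endmember fractions,
(3) normalize NPV against shade as NPV/(GV+NPV), and (4) difference the
post-storm and pre-storm normalized fractions.  Positive ΔNPV means newly
exposed wood and dead material, i.e. storm damage; negative values mean
re-greening and are zeroed only on the biomass-estimation path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

ENDMEMBER_NAMES = ("gv", "npv", "shade")

# Reference reflectance profiles on a 6-band grid (blue, green, red, NIR,
# SWIR1, SWIR2); interpolated when another band count is requested.
_GV_PROFILE = np.array([0.03, 0.06, 0.04, 0.50, 0.25, 0.12])
_NPV_PROFILE = np.array([0.12, 0.18, 0.25, 0.30, 0.38, 0.33])
_SHADE_PROFILE = np.array([0.02, 0.02, 0.02, 0.02, 0.02, 0.02])


@dataclass
class BandImage:
    """A multiband reflectance image with a per-pixel validity mask.

    ``reflectance`` has shape ``(bands, rows, cols)``; ``valid_mask`` has
    shape ``(rows, cols)`` and is False where the pixel is cloud/shadow
    contaminated or otherwise unobserved.
    """

    reflectance: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.reflectance.ndim != 3:
            raise ValueError("reflectance must be (bands, rows, cols)")
        if self.valid_mask.shape != self.reflectance.shape[1:]:
            raise ValueError("valid_mask shape must match spatial shape")
        if not np.all(np.isfinite(self.reflectance[:, self.valid_mask])):
            raise ValueError("reflectance must be finite wherever valid")

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.reflectance.shape[1:]


@dataclass
class EndmemberSet:
    """Endmember spectra as a ``(bands, 3)`` matrix, columns GV, NPV, shade."""

    spectra: np.ndarray

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2 or self.spectra.shape[1] != 3:
            raise ValueError("endmember matrix must have shape (bands, 3)")
        if np.linalg.matrix_rank(self.spectra) < 3:
            raise ValueError(
                "endmember spectra are collinear (rank < 3); "
                "unmixing into 3 fractions is not identifiable"
            )

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[0]


@dataclass
class DeltaNPVRaster:
    """Per-pixel change in normalized NPV; NaN marks invalid pixels."""

    delta: np.ndarray

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        valid = np.isfinite(self.delta)
        if np.any(np.abs(self.delta[valid]) > 1 + 1e-9):
            raise ValueError("ΔNPV must lie in [-1, 1] wherever valid")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.delta)

    @property
    def shape(self) -> tuple[int, int]:
        return self.delta.shape


def default_endmembers(n_bands: int = 6) -> EndmemberSet:
    """Synthetic GV/NPV/shade spectra: GV high-NIR/low-red, NPV flat and
    moderately bright, shade near zero.  Well conditioned (cond < 50)."""
    if n_bands < 3:
        raise ValueError("need at least 3 bands to unmix 3 endmembers")
    grid = np.linspace(0.0, 5.0, n_bands)
    base = np.arange(6.0)
    spectra = np.column_stack(
        [np.interp(grid, base, p) for p in (_GV_PROFILE, _NPV_PROFILE, _SHADE_PROFILE)]
    )
    return EndmemberSet(spectra)


def build_composite(images: list[BandImage]) -> BandImage:
    """Median composite: per pixel and band, the median over valid
    observations; even counts average the two central values.  A pixel is
    valid in the output iff at least one input observes it."""
    if not images:
        raise ValueError("cannot composite an empty image list")
    shapes = {im.reflectance.shape for im in images}
    if len(shapes) > 1:
        raise ValueError(f"image shapes differ: {sorted(shapes)}")
    stack = np.stack([im.reflectance for im in images])  # (n, bands, rows, cols)
    masks = np.stack([im.valid_mask for im in images])  # (n, rows, cols)
    stack = np.where(masks[:, None, :, :], stack, np.nan)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="All-NaN slice")
        med = np.nanmedian(stack, axis=0)
    valid = masks.any(axis=0)
    med[:, ~valid] = 0.0
    return BandImage(med, valid)


def _constrained_lstsq(spectra: np.ndarray, endmembers: EndmemberSet) -> np.ndarray:
    """Sum-to-one constrained least squares for a (bands, n) spectra block.

    Closed form via a Lagrange correction of the unconstrained solution:
    f = f_ols - G^-1 1 (1' f_ols - 1) / (1' G^-1 1), with G = E'E.
    """
    E = endmembers.spectra
    G = E.T @ E
    Ginv = np.linalg.inv(G)
    ones = np.ones(3)
    g1 = Ginv @ ones
    f_ols = Ginv @ (E.T @ spectra)  # (3, n)
    corr = (ones @ f_ols - 1.0) / (ones @ g1)
    return f_ols - np.outer(g1, corr)


def _simplex_lstsq(spectrum: np.ndarray, endmembers: EndmemberSet) -> np.ndarray:
    """Fully constrained (non-negative, sum-to-one) unmixing of one pixel
    via NNLS on a system augmented with a heavily weighted sum row."""
    from scipy.optimize import nnls

    w = 1e5
    A = np.vstack([endmembers.spectra, w * np.ones((1, 3))])
    b = np.concatenate([spectrum, [w]])
    f, _ = nnls(A, b)
    s = f.sum()
    return f / s if s > 0 else f


def unmix_image(
    reflectance: np.ndarray, endmembers: EndmemberSet, method: str = "clip"
) -> np.ndarray:
    """Unmix a (bands, rows, cols) stack into (3, rows, cols) fractions.

    ``method='clip'`` (default) solves the sum-to-one least-squares problem
    and then clips negative fractions to zero and renormalizes; ``'simplex'``
    solves the fully constrained problem per pixel.
    """
    reflectance = np.asarray(reflectance, dtype=float)
    if reflectance.shape[0] != endmembers.n_bands:
        raise ValueError(
            f"spectrum has {reflectance.shape[0]} bands, "
            f"endmembers have {endmembers.n_bands}"
        )
    spatial = reflectance.shape[1:]
    flat = reflectance.reshape(reflectance.shape[0], -1)
    if method == "clip":
        f = _constrained_lstsq(flat, endmembers)
        f = np.clip(f, 0.0, None)
        f /= f.sum(axis=0, keepdims=True)
    elif method == "simplex":
        f = np.column_stack(
            [_simplex_lstsq(flat[:, i], endmembers) for i in range(flat.shape[1])]
        )
    else:
        raise ValueError(f"unknown unmixing method: {method!r}")
    return f.reshape((3, *spatial))


def unmix_pixel(
    spectrum: np.ndarray, endmembers: EndmemberSet, method: str = "clip"
) -> np.ndarray:
    """Unmix a single band vector into (f_gv, f_npv, f_shade)."""
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.ndim != 1:
        raise ValueError("unmix_pixel expects a 1-D band vector")
    return unmix_image(spectrum[:, None], endmembers, method=method)[:, 0]


def normalize_npv(fractions: np.ndarray) -> np.ndarray | float:
    """Shade-normalized NPV fraction, NPV/(GV+NPV).

    Accepts a single fraction triple or a (3, ...) array.  Where GV+NPV is
    zero (a pure-shade pixel) the result is NaN, marking the pixel invalid.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape[0] != 3:
        raise ValueError("fractions must have leading axis of length 3")
    gv, npv = fractions[0], fractions[1]
    denom = gv + npv
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, npv / np.where(denom > 0, denom, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def compute_delta_npv(pre: np.ndarray, post: np.ndarray) -> DeltaNPVRaster:
    """ΔNPV = post − pre on the normalized NPV rasters (positive = damage).

    A pixel is valid only where both periods observed it; NaN propagates.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError(f"shape mismatch: pre {pre.shape} vs post {post.shape}")
    return DeltaNPVRaster(post - pre)


def clamp_for_biomass(delta: DeltaNPVRaster) -> DeltaNPVRaster:
    """Zero out negative ΔNPV (re-greening) for the biomass-loss path.

    The raw signed raster is kept for risk-factor modelling; only the
    biomass estimate treats re-greened pixels as undamaged.
    """
    return DeltaNPVRaster(np.where(delta.delta < 0, 0.0, delta.delta))


def apply_feature_mask(
    valid_mask: np.ndarray,
    geometries: list,
    buffer: float = 0.0,
) -> np.ndarray:
    """Invalidate pixels whose centers fall within buffered geometries.

    Used to mask roads and streams out of the damage raster.  Geometries are
    shapely objects in raster pixel coordinates (x = column, y = row); pixel
    (i, j) has its center at (j + 0.5, i + 0.5).
    """
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if not geometries:
        return valid_mask.copy()
    merged = shapely.union_all([shapely.buffer(g, buffer) if buffer else g for g in geometries])
    rows, cols = valid_mask.shape
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    hit = shapely.intersects_xy(merged, jj.ravel() + 0.5, ii.ravel() + 0.5)
    out = valid_mask.copy()
    out[hit.reshape(valid_mask.shape)] = False
    return out
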