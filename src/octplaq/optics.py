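"""Single-scattering optical model of the depth-resolved OCT signal and
least-squares inversion of the attenuation coefficient.

The detected A-line intensity is modelled as

    I(r) = I0 * T(r) * s(r) * exp(-mu_t * r)

where ``r`` is depth into the tissue, ``mu_t`` (mm^-1) the total attenuation
coefficient, ``I0`` a backscatter-dependent scale, ``T(r)`` the confocal
longitudinal point-spread function of the focused beam, and ``s(r)`` the
Gaussian sensitivity roll-off of the detection system.  Absorption is
negligible at OCT wavelengths, so mu_t is dominated by scattering.  After
dividing out T and s and taking logarithms the model is linear in depth,

    log I(r) - log T(r) - log s(r) = log I0 - mu_t * r,

and (mu_t, log I0) follow from an ordinary least-squares line fit.  A single
mu_t multiplies r in both the forward model and the fitter, so recovered
slopes are directly comparable to simulated truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_oct import PolarImage

__all__ = [
    "SystemParams",
    "OpticalFit",
    "BackscatterResult",
    "AttenuationMaps",
    "confocal_psf",
    "rolloff",
    "compensate_log_signal",
    "fit_attenuation",
    "attenuation_map",
    "backscatter_coefficient",
    "estimate_noise_floor",
]


def estimate_noise_floor(img: "PolarImage", boundary,
                         percentile: float = 99.0) -> float:
    """Noise-floor threshold from the lumen region of a B-scan.

    Pixels in front of the lumen boundary carry no tissue signal; the
    high percentile of their intensity distribution bounds the noise
    floor, and fit pixels at or below it should be masked.  A lumen
    boundary one pixel inside the true lumen otherwise leaks a floor-level
    pixel into every boundary-anchored fit window and biases mu_t low.
    """
    boundary = np.asarray(boundary, dtype=int)
    vals = np.concatenate([img.pixels[i, :boundary[i]]
                           for i in range(img.n_alines) if boundary[i] > 0])
    if vals.size == 0:
        return 0.0
    return float(np.percentile(vals, percentile))


@dataclass
class SystemParams:
    """Imaging-system beam and sampling parameters.

    Attributes
    ----------
    z0 : beam-waist position (mm)
    zR : Rayleigh length (mm, > 0)
    zC : centre of the depth-scan roll-off (mm)
    zW : half width of the roll-off function (mm, > 0)
    axial_spacing : mm per depth pixel (> 0)
    n_alines : A-lines per frame
    """

    z0: float = 1.0
    zR: float = 1.2
    zC: float = 1.0
    zW: float = 2.5
    axial_spacing: float = 0.01
    n_alines: int = 96

    def __post_init__(self) -> None:
        if not self.zR > 0:
            raise ValueError("zR must be positive")
        if not self.zW > 0:
            raise ValueError("zW must be positive")
        if not self.axial_spacing > 0:
            raise ValueError("axial_spacing must be positive")
        if self.n_alines < 8:
            raise ValueError("n_alines must be at least 8")

    def to_meta(self) -> dict:
        return {"axial_spacing_mm": self.axial_spacing,
                "n_alines": self.n_alines, "z0_mm": self.z0,
                "zR_mm": self.zR, "zC_mm": self.zC, "zW_mm": self.zW}

    @classmethod
    def from_meta(cls, meta: dict) -> "SystemParams":
        return cls(z0=meta.get("z0_mm", 1.0), zR=meta.get("zR_mm", 1.2),
                   zC=meta.get("zC_mm", 1.0), zW=meta.get("zW_mm", 2.5),
                   axial_spacing=meta["axial_spacing_mm"],
                   n_alines=meta["n_alines"])


@dataclass
class OpticalFit:
    """Result of one windowed line fit: attenuation, intercept, fit quality."""

    mu_t: float
    log_i0: float
    r2: float
    window: tuple[int, int]

    def __post_init__(self) -> None:
        if self.window[1] - self.window[0] < 3:
            raise ValueError("fit window must span at least 3 pixels")


@dataclass
class BackscatterResult:
    """Backscattering coefficient mu_b derived from I0 = I' * mu_b."""

    mu_b: float
    i_prime: float


def confocal_psf(r, z0: float, zR: float):
    """Longitudinal confocal PSF T(r) = [((r - z0)/zR)^2 + 1]^(-1/2).

    Peaks at 1 at the beam waist ``z0``; ``zR`` is the Rayleigh length.
    """
    if not zR > 0:
        raise ValueError("zR must be positive")
    r = np.asarray(r, dtype=np.float64)
    return 1.0 / np.sqrt(((r - z0) / zR) ** 2 + 1.0)


def rolloff(r, zC: float, zW: float):
    """Depth-scan sensitivity roll-off s(r) = exp[-((r - zC)/zW)^2]."""
    if not zW > 0:
        raise ValueError("zW must be positive")
    r = np.asarray(r, dtype=np.float64)
    return np.exp(-(((r - zC) / zW) ** 2))


def compensate_log_signal(profile, sys: SystemParams,
                          noise_floor: float | None = None,
                          r: np.ndarray | None = None) -> np.ndarray:
    """Log-transform an intensity profile and divide out T(r) and s(r).

    Returns ``log I(r) - log T(r) - log s(r)`` per depth pixel, which is
    linear in ``r`` with slope ``-mu_t`` under the single-scattering model.
    Pixels at or below ``noise_floor`` (and any non-positive pixel) are
    returned as NaN and must be excluded from fits.

    Parameters
    ----------
    profile : intensity per depth pixel (linear scale)
    sys : system parameters supplying z0/zR/zC/zW and the depth grid
    noise_floor : intensities <= this value are masked (default: mask only
        non-positive pixels)
    r : optional explicit depth grid in mm (default ``col * axial_spacing``)
    """
    profile = np.asarray(profile, dtype=np.float64)
    if r is None:
        r = np.arange(profile.size) * sys.axial_spacing
    mask = profile > 0
    if noise_floor is not None:
        mask &= profile > noise_floor
    if not mask.any():
        raise ValueError("no fit support: all pixels masked")
    out = np.full(profile.shape, np.nan)
    out[mask] = (np.log(profile[mask])
                 - np.log(confocal_psf(r[mask], sys.z0, sys.zR))
                 - np.log(rolloff(r[mask], sys.zC, sys.zW)))
    return out


def fit_attenuation(corrected: np.ndarray, window: tuple[int, int],
                    axial_spacing: float) -> OpticalFit:
    """Ordinary least squares of the corrected log signal on depth.

    ``mu_t`` is the negated slope, ``log_i0`` the intercept at r = 0, and
    ``r2`` the coefficient of determination.  NaN pixels inside the
    half-open ``window`` are excluded; at least 3 valid points are required.
    """
    s, e = window
    y = np.asarray(corrected, dtype=np.float64)[s:e]
    x = np.arange(s, e) * axial_spacing
    ok = np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 unmasked points in the fit window")
    x, y = x[ok], y[ok]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid ** 2) / ss_tot
    return OpticalFit(mu_t=-slope, log_i0=intercept,
                      r2=float(np.clip(r2, 0.0, 1.0)), window=(s, e))


def backscatter_coefficient(log_i0: float, i_prime: float) -> BackscatterResult:
    """Backscattering coefficient from the fitted intercept: mu_b = I0 / I'.

    ``i_prime`` is the locally available intensity, which must be supplied
    by the caller (it is not estimable from a single A-line).
    """
    if not i_prime > 0:
        raise ValueError("i_prime must be positive")
    return BackscatterResult(mu_b=float(np.exp(log_i0) / i_prime),
                             i_prime=float(i_prime))


@dataclass
class AttenuationMaps:
    """Per-pixel optical parameter rasters over the analysis band."""

    mu_t: np.ndarray
    log_i0: np.ndarray
    r2: np.ndarray
    roi: np.ndarray  # boolean, True where a fit was assigned


def _sliding_ols(x: np.ndarray, y: np.ndarray, w: int):
    """Vectorized weighted OLS over all length-w windows of (x, y).

    NaNs in y get zero weight.  Returns (slope, intercept, r2, n_valid)
    arrays indexed by window start.
    """
    valid = np.isfinite(y)
    yz = np.where(valid, y, 0.0)
    wts = valid.astype(np.float64)

    def win_sum(a):
        c = np.concatenate(([0.0], np.cumsum(a)))
        return c[w:] - c[:-w]

    n = win_sum(wts)
    sx = win_sum(wts * x)
    sy = win_sum(yz)
    sxx = win_sum(wts * x * x)
    sxy = win_sum(x * yz)
    syy = win_sum(yz * yz)
    with np.errstate(divide="ignore", invalid="ignore"):
        den = n * sxx - sx * sx
        slope = (n * sxy - sx * sy) / den
        intercept = (sy - slope * sx) / n
        ss_tot = syy - sy * sy / n
        ss_res = ss_tot - slope * (sxy - sx * sy / n)
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    bad = (n < 3) | ~np.isfinite(slope)
    slope[bad] = np.nan
    intercept[bad] = np.nan
    r2[bad] = np.nan
    return slope, intercept, np.clip(r2, 0.0, 1.0), n


def attenuation_map(img: PolarImage, boundary: np.ndarray, sys: SystemParams,
                    window_len: float = 0.25, analysis_depth: float = 1.0,
                    noise_floor: float | None = None) -> AttenuationMaps:
    """Sliding-window attenuation fits over the analysis band of every A-line.

    For each A-line, length-``window_len`` (mm) windows slide with 1-px
    stride over the band ``[boundary, boundary + analysis_depth)`` anchored
    at the lumen boundary.  Each band pixel receives the fit from the window
    centred on it; pixels too close to a band edge take the nearest window
    that still fits inside the band.  Pixels with no valid window (e.g. an
    A-line fully below the noise floor, as behind the guide wire) are NaN
    and excluded from the ROI mask.
    """
    if boundary is None:
        raise ValueError("lumen boundary is required")
    boundary = np.asarray(boundary, dtype=int)
    if boundary.size != img.n_alines:
        raise ValueError("boundary length must equal the number of A-lines")
    w = int(round(window_len / sys.axial_spacing))
    if w < 3:
        raise ValueError("window_len must span at least 3 pixels")
    depth_px = int(round(analysis_depth / sys.axial_spacing))
    shape = img.pixels.shape
    maps = AttenuationMaps(np.full(shape, np.nan), np.full(shape, np.nan),
                           np.full(shape, np.nan), np.zeros(shape, bool))
    for i in range(img.n_alines):
        b = boundary[i]
        band_end = min(b + depth_px, img.n_depth)
        if band_end - b < w:
            continue
        prof = img.pixels[i, b:band_end]
        r = (np.arange(b, band_end)) * sys.axial_spacing
        # depth in the attenuation fit is measured from the tissue entry
        # point, so intercepts are boundary-anchored
        r_fit = r - b * sys.axial_spacing
        with np.errstate(divide="ignore", invalid="ignore"):
            mask = prof > 0
            if noise_floor is not None:
                mask &= prof > noise_floor
            y = np.where(mask,
                         np.log(np.where(mask, prof, 1.0))
                         - np.log(confocal_psf(r, sys.z0, sys.zR))
                         - np.log(rolloff(r, sys.zC, sys.zW)),
                         np.nan)
        slope, intercept, r2, _ = _sliding_ols(r_fit, y, w)
        valid_starts = np.flatnonzero(np.isfinite(slope))
        if valid_starts.size == 0:
            continue
        cols = np.arange(b, band_end)
        centre_start = np.clip(cols - b - w // 2, 0, band_end - b - w)
        # snap to the nearest window with >= 3 valid points
        idx = np.searchsorted(valid_starts, centre_start)
        idx = np.clip(idx, 0, valid_starts.size - 1)
        left = np.clip(idx - 1, 0, valid_starts.size - 1)
        pick = np.where(
            np.abs(valid_starts[left] - centre_start)
            <= np.abs(valid_starts[idx] - centre_start),
            valid_starts[left], valid_starts[idx])
        maps.mu_t[i, cols] = -slope[pick]
        maps.log_i0[i, cols] = intercept[pick]
        maps.r2[i, cols] = r2[pick]
        maps.roi[i, cols] = True
    return maps
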