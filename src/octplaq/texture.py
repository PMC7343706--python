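"""Sliding-window texture features and per-pixel feature-stack assembly.

Five feature families feed the pixel classifier, 25 features in all:

* OP — the two optical parameters (mu_t, log I0) from the attenuation fits;
* FOS — first-order statistics of the local window (population moments);
* GLCM — gray-level co-occurrence features at distance 1, averaged over the
  0/45/90/135 degree directions (symmetric, normalized matrices; entropy in
  bits);
* NGTDM — Amadasun-King neighbourhood gray-tone difference features with
  3x3 neighbourhoods;
* FD — a four-scale differential box-counting signature of local surface
  roughness (the per-scale log box counts; their slope against log(1/s) is
  the fractal-dimension estimate);
* RP — relative position: depth from the lumen boundary (x) and A-line
  index (y).

GLCM, NGTDM and FD operate on the image quantized to ``levels`` gray bins
anchored at the global min-max, which makes them invariant to constant
intensity offsets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_oct import PolarImage
from .optics import AttenuationMaps

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_SETS",
    "feature_subset",
    "quantize",
    "fos_features",
    "glcm_features",
    "ngtdm_features",
    "fd_features",
    "fd_slope",
    "build_feature_stack",
]

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "OP": ("mu_t", "log_i0"),
    "FOS": ("mean", "variance", "median", "skewness", "kurtosis"),
    "GLCM": ("correlation", "contrast", "dissimilarity", "energy",
             "entropy", "homogeneity", "max_probability"),
    "NGTDM": ("busyness", "ngtdm_contrast", "complexity", "coarseness",
              "strength"),
    "FD": ("H1", "H2", "H3", "H4"),
    "RP": ("x", "y"),
}

#: Fixed order of the 25 emitted features.
FEATURE_NAMES: tuple[str, ...] = sum(FEATURE_SETS.values(), ())

# co-occurrence offsets (drow, dcol) for angles 0, 45, 90, 135 degrees
_GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
_EPS = 1e-12


def feature_subset(name: str) -> tuple[str, ...]:
    """Feature names of an ablation set: 'ALL' or '<SET>+RP' / '<SET>'."""
    if name.upper() == "ALL":
        return FEATURE_NAMES
    cols: list[str] = []
    for part in name.upper().split("+"):
        if part not in FEATURE_SETS:
            raise KeyError(f"unknown feature set {part!r}")
        cols.extend(FEATURE_SETS[part])
    return tuple(cols)


def quantize(image, levels: int, vmin: float | None = None,
             vmax: float | None = None) -> np.ndarray:
    """Quantize intensities to ``levels`` gray bins over [vmin, vmax].

    The anchors default to the global min and max of ``image``; a flat
    image quantizes to all zeros.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    img = np.asarray(image, dtype=np.float64)
    vmin = img.min() if vmin is None else vmin
    vmax = img.max() if vmax is None else vmax
    if vmax <= vmin:
        return np.zeros(img.shape, dtype=np.int64)
    q = np.floor((img - vmin) / (vmax - vmin) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def fos_features(window) -> tuple[float, float, float, float, float]:
    """(mean, variance, median, skewness, kurtosis) — population moments.

    Skewness and kurtosis are the standardized 3rd and 4th central moments
    (kurtosis not excess-corrected); both are 0 for a constant window.
    """
    w = np.asarray(window, dtype=np.float64).ravel()
    if w.size == 0:
        raise ValueError("window must be non-empty")
    mean = w.mean()
    var = w.var()
    med = float(np.median(w))
    if var == 0:
        return float(mean), 0.0, med, 0.0, 0.0
    z = w - mean
    sd = np.sqrt(var)
    skew = float(np.mean(z ** 3) / sd ** 3)
    kurt = float(np.mean(z ** 4) / var ** 2)
    return float(mean), float(var), med, skew, kurt


def _glcm_single(counts: np.ndarray, levels: int):
    """Features of one normalized symmetric co-occurrence matrix."""
    p = counts / counts.sum()
    nz = p > 0
    i, j = np.nonzero(nz)
    pv = p[nz]
    diff = i - j
    energy = float(np.sum(pv ** 2))
    entropy = float(-np.sum(pv * np.log2(pv)))
    contrast = float(np.sum(pv * diff ** 2))
    dissim = float(np.sum(pv * np.abs(diff)))
    homog = float(np.sum(pv / (1.0 + diff ** 2)))
    maxp = float(pv.max())
    mu = float(np.sum(pv * i))        # symmetric: row and col means equal
    var = float(np.sum(pv * (i - mu) ** 2))
    if var > 0:
        corr = float(np.sum(pv * (i - mu) * (j - mu)) / var)
    else:
        corr = 1.0
    return corr, contrast, dissim, energy, entropy, homog, maxp


def glcm_features(qwindow, levels: int):
    """Seven co-occurrence features averaged over the four directions.

    ``qwindow`` must already be quantized to integers in [0, levels).
    Each direction uses distance 1 and a symmetric, normalized matrix;
    directions with no valid pixel pair (degenerate window shapes) are
    dropped from the average.  Returns (correlation, contrast,
    dissimilarity, energy, entropy, homogeneity, max_probability).
    """
    q = np.asarray(qwindow)
    if q.ndim != 2 or q.shape[0] < 2 or q.shape[1] < 2:
        raise ValueError("window must be at least 2x2")
    if q.min() < 0 or q.max() >= levels:
        raise ValueError("window values must lie in [0, levels)")
    acc = np.zeros(7)
    n_used = 0
    for dr, dc in _GLCM_OFFSETS:
        r0, r1 = max(0, -dr), q.shape[0] - max(0, dr)
        c0, c1 = max(0, -dc), q.shape[1] - max(0, dc)
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        if a.size == 0:
            continue
        codes = np.concatenate((a * levels + b, b * levels + a))
        counts = np.bincount(codes, minlength=levels * levels
                             ).reshape(levels, levels).astype(np.float64)
        acc += _glcm_single(counts, levels)
        n_used += 1
    if n_used == 0:
        raise ValueError("window admits no co-occurrence pairs")
    return tuple(acc / n_used)


def ngtdm_features(qwindow):
    """Amadasun-King NGTDM features for 3x3 neighbourhoods.

    Interior pixels (those with a complete 3x3 neighbourhood inside the
    window) contribute ``|tone - mean of the 8 surrounding pixels|`` to
    ``s(i)`` of their gray tone i.  Returns (busyness, contrast,
    complexity, coarseness, strength); an epsilon of 1e-12 guards the
    zero-denominator cases, so a constant window yields coarseness 1/eps
    and zeros elsewhere.
    """
    q = np.asarray(qwindow, dtype=np.int64)
    if q.ndim != 2 or q.shape[0] < 3 or q.shape[1] < 3:
        raise ValueError("window must be at least 3x3")
    w = q.astype(np.float64)
    total = np.zeros((q.shape[0] - 2, q.shape[1] - 2))
    for dr in (0, 1, 2):
        for dc in (0, 1, 2):
            total += w[dr:dr + total.shape[0], dc:dc + total.shape[1]]
    centre = w[1:-1, 1:-1]
    a_mean = (total - centre) / 8.0
    tones = q[1:-1, 1:-1].ravel()
    dev = np.abs(centre.ravel() - a_mean.ravel())
    nbins = int(tones.max()) + 1
    n_i = np.bincount(tones, minlength=nbins).astype(np.float64)
    s_i = np.bincount(tones, weights=dev, minlength=nbins)
    N = tones.size
    p_i = n_i / N
    present = np.flatnonzero(p_i > 0)
    ng = present.size
    pi = p_i[present]
    si = s_i[present]
    lv = present.astype(np.float64)
    ps = float(np.sum(pi * si))
    coarseness = 1.0 / (_EPS + ps)
    if ng < 2:
        return 0.0, 0.0, 0.0, coarseness, 0.0
    dif = lv[:, None] - lv[None, :]
    pp = pi[:, None] * pi[None, :]
    contrast = (np.sum(pp * dif ** 2) / (ng * (ng - 1))) * (si.sum() / N)
    busy_den = np.sum(np.abs((lv * pi)[:, None] - (lv * pi)[None, :]))
    busyness = ps / busy_den if busy_den > _EPS else 0.0
    psum = pi[:, None] + pi[None, :]
    complexity = float(np.sum(np.abs(dif) / (N * psum)
                              * ((pi * si)[:, None] + (pi * si)[None, :])))
    strength = float(np.sum(psum * dif ** 2) / (_EPS + si.sum()))
    return float(busyness), float(contrast), complexity, coarseness, strength


def _box_count(window: np.ndarray, scale: int, gray_range: float) -> int:
    """Differential box count N(s) of the window surface at one scale."""
    m = min(window.shape)
    n_cells = m // scale
    if n_cells < 1:
        raise ValueError("window side must be >= 2 x the largest scale")
    crop = window[:n_cells * scale, :n_cells * scale].astype(np.float64)
    blocks = crop.reshape(n_cells, scale, n_cells, scale)
    bmax = blocks.max(axis=(1, 3))
    bmin = blocks.min(axis=(1, 3))
    if gray_range <= 0:
        return int(n_cells * n_cells)
    h = scale * gray_range / m
    nr = np.ceil(bmax / h) - np.ceil(bmin / h) + 1
    return int(nr.sum())


def fd_features(window, scales=(2, 3, 4, 5),
                gray_range: float | None = None):
    """Per-scale log differential box counts (H1..H4).

    The window is treated as an intensity surface; at scale ``s`` the plane
    is tiled with s x s cells and each cell contributes
    ``ceil(max/h) - ceil(min/h) + 1`` boxes of height ``h = s * G / M``
    (G = gray range, M = window side).  The least-squares slope of these
    log counts against ``log(1/s)`` (:func:`fd_slope`) estimates the
    fractal dimension; a flat surface gives exactly 2.  The emitted
    features are the four log counts themselves — a multiscale roughness
    signature.
    """
    w = np.asarray(window, dtype=np.float64)
    if min(w.shape) < 2 * max(scales):
        raise ValueError("window side must be >= 2 x the largest scale")
    if gray_range is None:
        gray_range = float(w.max() - w.min())
    return tuple(float(np.log(_box_count(w, s, gray_range)))
                 for s in scales)


def fd_slope(log_counts, scales=(2, 3, 4, 5)) -> float:
    """Fractal-dimension estimate: OLS slope of log N(s) on log(1/s)."""
    x = np.log(1.0 / np.asarray(scales, dtype=np.float64))
    return float(np.polyfit(x, np.asarray(log_counts, dtype=np.float64),
                            1)[0])


def build_feature_stack(img: PolarImage, optical: AttenuationMaps,
                        boundary, analysis_depth: float = 1.0,
                        window_px: int = 11, levels: int = 32,
                        pixels: np.ndarray | None = None) -> pd.DataFrame:
    """Assemble the 25-feature per-pixel stack over the analysis band.

    The ROI is the band ``[boundary, boundary + analysis_depth)`` of every
    A-line, restricted to pixels with valid optical fits (A-lines behind
    the guide-wire shadow drop out here).  Texture features use the
    ``window_px`` x ``window_px`` window centred on each pixel, padded
    across the angular seam (rows are periodic) and clipped at the depth
    edges.  Relative position is ``x`` = depth in pixels from the lumen
    boundary and ``y`` = raw A-line index.

    Parameters
    ----------
    pixels
        Optional ``(n, 2)`` array of (row, col) positions to restrict the
        stack to (e.g. a training subsample); default is every ROI pixel.

    Returns a DataFrame with columns ``row``, ``col`` and the 25 features.
    """
    if optical is None:
        raise ValueError("optical maps are required")
    boundary = np.asarray(boundary, dtype=int)
    depth_px = int(round(analysis_depth / img.axial_spacing))
    n_rows, n_cols = img.pixels.shape
    half = window_px // 2

    roi = optical.roi & np.isfinite(optical.mu_t)
    band = np.zeros_like(roi)
    for i in range(n_rows):
        band[i, boundary[i]:min(boundary[i] + depth_px, n_cols)] = True
    roi = roi & band
    if pixels is None:
        rows, cols_idx = np.nonzero(roi)
    else:
        pixels = np.asarray(pixels, dtype=int)
        sel = roi[pixels[:, 0], pixels[:, 1]]
        rows, cols_idx = pixels[sel, 0], pixels[sel, 1]

    q = quantize(img.pixels, levels)
    raw_pad = np.pad(img.pixels, ((half, half), (0, 0)), mode="wrap")
    q_pad = np.pad(q, ((half, half), (0, 0)), mode="wrap")

    n = rows.size
    out = np.empty((n, len(FEATURE_NAMES)))
    fd_ok = window_px >= 2 * 5
    for k in range(n):
        r, c = rows[k], cols_idx[k]
        c0, c1 = max(0, c - half), min(n_cols, c + half + 1)
        rw = raw_pad[r:r + window_px, c0:c1]
        qw = q_pad[r:r + window_px, c0:c1]
        fos = fos_features(rw)
        gl = glcm_features(qw, levels)
        ng = ngtdm_features(qw)
        if fd_ok and min(qw.shape) >= 10:
            fd = fd_features(qw, gray_range=float(levels - 1))
        else:  # narrow clipped window: fall back to the widest legal scales
            fd = fd_features(qw, scales=(1, 2, 2, 3) if min(qw.shape) >= 6
                             else (1, 1, 1, 1),
                             gray_range=float(levels - 1))
        out[k] = (optical.mu_t[r, c], optical.log_i0[r, c], *fos, *gl, *ng,
                  *fd, c - boundary[r], r)
    df = pd.DataFrame(out, columns=list(FEATURE_NAMES))
    df.insert(0, "col", cols_idx)
    df.insert(0, "row", rows)
    return df
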