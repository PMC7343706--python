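"""Guide-wire shadow masking and dynamic-programming lumen segmentation.

The lumen boundary in a polar B-scan is the dark-to-bright transition along
each A-line.  It is extracted as the minimum-cost closed path through a
per-pixel cost raster (negative axial gradient of a median-filtered image)
under a per-A-line smoothness constraint, solved exactly by dynamic
programming with circular closure.  A-lines shadowed by the guide wire
carry no usable edge and are interpolated from their neighbours.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import median_filter

from .io_oct import PolarImage

__all__ = ["detect_guidewire_shadow", "segment_lumen", "LumenBoundary",
           "minimal_closed_path"]


class LumenBoundary(np.ndarray):
    """Per-A-line lumen column indices (an integer ndarray subclass)."""

    def __new__(cls, radius_px):
        return np.asarray(radius_px, dtype=int).view(cls)


def detect_guidewire_shadow(img: PolarImage, k: float = 3.0,
                            min_span: int = 3) -> np.ndarray:
    """Flag the contiguous angular run shadowed by the guide wire.

    Per A-line the mean intensity is scored against the across-A-line
    median; A-lines falling more than ``k`` median-absolute-deviations
    below it are shadow candidates.  The longest contiguous circular run of
    candidates is returned if it spans at least ``min_span`` A-lines,
    otherwise the mask is empty.  A featureless (e.g. all-zero) image gives
    an empty mask, not an error.
    """
    if img.pixels.size == 0:
        return np.zeros(0, dtype=bool)
    score = img.pixels.mean(axis=1)
    med = np.median(score)
    mad = np.median(np.abs(score - med))
    if mad == 0:
        return np.zeros(img.n_alines, dtype=bool)
    flagged = score < med - k * mad
    if not flagged.any():
        return np.zeros(img.n_alines, dtype=bool)
    # longest circular run of flagged A-lines
    n = flagged.size
    ext = np.concatenate((flagged, flagged))
    best_len, best_start, run = 0, 0, 0
    for i in range(2 * n):
        if ext[i]:
            run += 1
            if run > best_len:
                best_len, best_start = run, i - run + 1
        else:
            run = 0
    best_len = min(best_len, n)
    mask = np.zeros(n, dtype=bool)
    if best_len >= min_span:
        idx = (np.arange(best_start, best_start + best_len)) % n
        mask[idx] = True
    return mask


def _edge_cost(pixels: np.ndarray) -> np.ndarray:
    """Dark-to-bright axial edge cost: negative forward gradient of the
    3x3 median-filtered image (lower is a stronger lumen edge)."""
    padded = np.pad(pixels, ((1, 1), (0, 0)), mode="wrap")
    sm = median_filter(padded, size=3, mode="nearest")[1:-1]
    grad = np.empty_like(sm)
    grad[:, :-1] = sm[:, 1:] - sm[:, :-1]
    grad[:, -1] = 0.0
    return -grad


def _dp_fixed_start(cost: np.ndarray, s: int, start_col: int):
    """Min-cost circular path with r_0 fixed; returns (total_cost, path)."""
    n, m = cost.shape
    INF = np.inf
    acc = np.full(m, INF)
    acc[start_col] = cost[0, start_col]
    back = np.zeros((n, m), dtype=np.int32)
    cols = np.arange(m)
    for i in range(1, n):
        # best predecessor within +-s; ties toward smaller radius
        best = np.full(m, INF)
        arg = np.zeros(m, dtype=np.int32)
        for d in range(-s, s + 1):
            shifted = np.full(m, INF)
            lo, hi = max(0, -d), min(m, m - d)
            shifted[lo:hi] = acc[lo + d:hi + d]
            take = shifted < best
            better_tie = (shifted == best) & (cols + d < arg)
            upd = take | better_tie
            best[upd] = shifted[upd]
            arg[upd] = cols[upd] + d
        acc = best + cost[i]
        back[i] = arg
    # closure back to the fixed start
    feas = np.abs(cols - start_col) <= s
    acc = np.where(feas, acc, INF)
    end = int(np.flatnonzero(acc == acc.min())[0])
    total = acc[end]
    path = np.empty(n, dtype=int)
    path[-1] = end
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return total, path


def minimal_closed_path(cost: np.ndarray, smoothness: int,
                        n_start_candidates: int = 8):
    """Minimum-cost closed path through a cost raster.

    Rows are chain positions (A-lines), columns are candidate radii; the
    path visits one column per row with ``|r_{i+1} - r_i| <= smoothness``
    including the wrap-around pair.  The DP is solved once per candidate
    start column (all columns when there are no more than
    ``n_start_candidates``, making the search exhaustive) and the cheapest
    closed path wins; ties prefer smaller radii.

    Returns ``(total_cost, path)``.
    """
    n, m = cost.shape
    if m <= n_start_candidates:
        candidates = list(range(m))
    else:
        col_score = cost.sum(axis=0)
        edges = np.linspace(0, m, n_start_candidates + 1).astype(int)
        candidates = sorted({int(lo + np.argmin(col_score[lo:hi]))
                             for lo, hi in zip(edges, edges[1:]) if hi > lo})
    best_total, best_path = np.inf, None
    for c0 in candidates:
        total, path = _dp_fixed_start(cost, smoothness, c0)
        if total < best_total or (total == best_total
                                  and best_path is not None
                                  and tuple(path) < tuple(best_path)):
            best_total, best_path = total, path
    return best_total, best_path


def segment_lumen(img: PolarImage, shadow_mask: np.ndarray | None = None,
                  smoothness: int = 2,
                  n_start_candidates: int = 8) -> LumenBoundary:
    """Dynamic-programming lumen boundary extraction.

    Minimizes the total edge cost subject to ``|r_{i+1} - r_i| <=
    smoothness`` including the wrap-around pair.  Circular closure is
    handled by solving the DP once per candidate start column — the best
    column in each of ``n_start_candidates`` depth bands (all columns when
    the raster is narrow, which makes the search exhaustive) — and keeping
    the cheapest closed path.  Shadowed A-lines are excluded from the
    optimization and assigned circularly interpolated radii.
    """
    if smoothness < 1:
        raise ValueError("smoothness must be >= 1")
    n, m = img.pixels.shape
    if m < 3:
        raise ValueError("image must have at least 3 depth columns")
    if shadow_mask is None:
        shadow_mask = np.zeros(n, dtype=bool)
    shadow_mask = np.asarray(shadow_mask, dtype=bool)
    keep = ~shadow_mask
    if keep.sum() < 3:
        raise ValueError("too few unshadowed A-lines to segment")
    cost = _edge_cost(img.pixels)[keep]
    _, best_path = minimal_closed_path(cost, smoothness, n_start_candidates)

    radii = np.zeros(n, dtype=float)
    radii[keep] = best_path
    if shadow_mask.any():
        # circular linear interpolation across shadowed A-lines
        idx_keep = np.flatnonzero(keep)
        radii = np.rint(np.interp(np.arange(n), idx_keep, radii[idx_keep],
                                  period=n))
    return LumenBoundary(radii.astype(int))
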