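"""Independent brute-force oracles used to cross-check the feature and
segmentation code.  These deliberately use plain Python loops and naive
enumeration so they share no code path with the implementations they test.
"""

from __future__ import annotations

import math

import numpy as np

GLCM_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_matrix_bruteforce(qw: np.ndarray, levels: int, angle: int):
    """Symmetric normalized co-occurrence matrix by explicit pair listing."""
    dr, dc = GLCM_OFFSETS[angle]
    h, w = qw.shape
    counts = [[0] * levels for _ in range(levels)]
    total = 0
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                a, b = int(qw[r, c]), int(qw[r2, c2])
                counts[a][b] += 1
                counts[b][a] += 1
                total += 2
    return [[v / total for v in row] for row in counts] if total else None


def glcm_features_bruteforce(qw: np.ndarray, levels: int):
    """The seven co-occurrence features, averaged over the four angles."""
    feats = []
    for angle in (0, 45, 90, 135):
        P = glcm_matrix_bruteforce(qw, levels, angle)
        if P is None:
            continue
        energy = entropy = contrast = dissim = homog = 0.0
        maxp = 0.0
        mu = 0.0
        for i in range(levels):
            for j in range(levels):
                mu += P[i][j] * i
        var = 0.0
        for i in range(levels):
            for j in range(levels):
                var += P[i][j] * (i - mu) ** 2
        corr_num = 0.0
        for i in range(levels):
            for j in range(levels):
                p = P[i][j]
                if p > 0:
                    energy += p * p
                    entropy -= p * math.log2(p)
                    contrast += p * (i - j) ** 2
                    dissim += p * abs(i - j)
                    homog += p / (1 + (i - j) ** 2)
                    maxp = max(maxp, p)
                    corr_num += p * (i - mu) * (j - mu)
        corr = corr_num / var if var > 0 else 1.0
        feats.append((corr, contrast, dissim, energy, entropy, homog, maxp))
    return tuple(sum(f[k] for f in feats) / len(feats) for k in range(7))


def ngtdm_bruteforce(qw: np.ndarray):
    """Amadasun-King NGTDM features by direct neighbourhood enumeration."""
    eps = 1e-12
    h, w = qw.shape
    s = {}
    n = {}
    count = 0
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            tone = int(qw[r, c])
            nb = [int(qw[r + dr, c + dc])
                  for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                  if not (dr == 0 and dc == 0)]
            a = sum(nb) / 8.0
            s[tone] = s.get(tone, 0.0) + abs(tone - a)
            n[tone] = n.get(tone, 0) + 1
            count += 1
    p = {i: n[i] / count for i in n}
    tones = sorted(p)
    ng = len(tones)
    ps = sum(p[i] * s[i] for i in tones)
    coarseness = 1.0 / (eps + ps)
    if ng < 2:
        return 0.0, 0.0, 0.0, coarseness, 0.0
    ssum = sum(s.values())
    contrast = (sum(p[i] * p[j] * (i - j) ** 2
                    for i in tones for j in tones) / (ng * (ng - 1))
                ) * (ssum / count)
    busy_den = sum(abs(i * p[i] - j * p[j]) for i in tones for j in tones)
    busyness = ps / busy_den if busy_den > eps else 0.0
    complexity = sum(abs(i - j) / (count * (p[i] + p[j]))
                     * (p[i] * s[i] + p[j] * s[j])
                     for i in tones for j in tones)
    strength = sum((p[i] + p[j]) * (i - j) ** 2
                   for i in tones for j in tones) / (eps + ssum)
    return busyness, contrast, complexity, coarseness, strength


def fos_streaming(values) -> tuple[float, float]:
    """Streaming (Welford) mean and population variance."""
    mean = 0.0
    m2 = 0.0
    k = 0
    for v in np.asarray(values, dtype=np.float64).ravel():
        k += 1
        d = v - mean
        mean += d / k
        m2 += d * (v - mean)
    return mean, m2 / k


def moments_direct(values):
    """Direct population moments: mean, var, median, skewness, kurtosis."""
    v = sorted(np.asarray(values, dtype=np.float64).ravel().tolist())
    k = len(v)
    mean = sum(v) / k
    var = sum((x - mean) ** 2 for x in v) / k
    med = (v[k // 2] if k % 2 else 0.5 * (v[k // 2 - 1] + v[k // 2]))
    if var == 0:
        return mean, 0.0, med, 0.0, 0.0
    sd = math.sqrt(var)
    skew = sum((x - mean) ** 3 for x in v) / k / sd ** 3
    kurt = sum((x - mean) ** 4 for x in v) / k / var ** 2
    return mean, var, med, skew, kurt


def box_count_recipe(surface: np.ndarray, scale: int, gray_range: float):
    """Differential box counting by explicit cell loops."""
    m = min(surface.shape)
    cells = m // scale
    total = 0
    for bi in range(cells):
        for bj in range(cells):
            block = surface[bi * scale:(bi + 1) * scale,
                            bj * scale:(bj + 1) * scale]
            if gray_range <= 0:
                total += 1
                continue
            hgt = scale * gray_range / m
            total += int(math.ceil(block.max() / hgt)
                         - math.ceil(block.min() / hgt) + 1)
    return total


def exhaustive_closed_path(cost: np.ndarray, smoothness: int):
    """Enumerate every closed path satisfying the smoothness constraint."""
    n, m = cost.shape
    best = math.inf
    best_path = None
    for r0 in range(m):
        frontier = [((r0,), cost[0, r0])]
        for i in range(1, n):
            nxt = []
            for path, tot in frontier:
                last = path[-1]
                for r in range(max(0, last - smoothness),
                               min(m, last + smoothness + 1)):
                    nxt.append((path + (r,), tot + cost[i, r]))
            frontier = nxt
        for path, tot in frontier:
            if abs(path[-1] - path[0]) <= smoothness and (
                    tot < best or (tot == best and path < best_path)):
                best, best_path = tot, path
    return best, best_path
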