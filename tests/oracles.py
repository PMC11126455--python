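"""Independent brute-force reference implementations for the texture engine.

Everything here is deliberately written as plain Python loops over pixels,
pairs, runs, zones and neighbourhoods — no shared code with the package —
so it can serve as an oracle for the vectorised builders and the feature
formulas.
"""

from __future__ import annotations

import math

import numpy as np

EPS = 2.2e-16

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_oracle(levels, n_g, delta, angle, symmetric=True):
    """Count co-occurring level pairs by looping over every pixel."""
    levels = np.asarray(levels)
    h, w = levels.shape
    dr, dc = OFFSETS[angle]
    dr, dc = dr * delta, dc * delta
    P = np.zeros((n_g, n_g), dtype=int)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < h and 0 <= c2 < w):
                continue
            a, b = levels[r, c], levels[r2, c2]
            if a > 0 and b > 0:
                P[a - 1, b - 1] += 1
                if symmetric:
                    P[b - 1, a - 1] += 1
    return P


def glrlm_oracle(levels, n_g, theta):
    """Enumerate maximal runs by walking every lattice line."""
    levels = np.asarray(levels)
    h, w = levels.shape
    step = {0: (0, 1), 90: (1, 0), 135: (1, 1), 45: (1, -1)}[theta]
    dr, dc = step
    runs = []
    for r0 in range(h):
        for c0 in range(w):
            rp, cp = r0 - dr, c0 - dc
            if 0 <= rp < h and 0 <= cp < w:
                continue  # not a line start
            line = []
            r, c = r0, c0
            while 0 <= r < h and 0 <= c < w:
                line.append(levels[r, c])
                r, c = r + dr, c + dc
            k = 0
            while k < len(line):
                v = line[k]
                length = 1
                while k + length < len(line) and line[k + length] == v:
                    length += 1
                if v > 0:
                    runs.append((v, length))
                k += length
    max_len = max((l for _, l in runs), default=1)
    P = np.zeros((n_g, max_len), dtype=int)
    for v, l in runs:
        P[v - 1, l - 1] += 1
    return P


def glszm_oracle(levels, n_g, connectivity=8):
    """Flood-fill connected equal-level zones."""
    levels = np.asarray(levels)
    h, w = levels.shape
    if connectivity == 8:
        neigh = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for r0 in range(h):
        for c0 in range(w):
            if seen[r0, c0] or levels[r0, c0] == 0:
                continue
            v = levels[r0, c0]
            stack = [(r0, c0)]
            seen[r0, c0] = True
            size = 0
            while stack:
                r, c = stack.pop()
                size += 1
                for a, b in neigh:
                    r2, c2 = r + a, c + b
                    if 0 <= r2 < h and 0 <= c2 < w and not seen[r2, c2] and levels[r2, c2] == v:
                        seen[r2, c2] = True
                        stack.append((r2, c2))
            zones.append((v, size))
    max_size = max((s for _, s in zones), default=1)
    P = np.zeros((n_g, max_size), dtype=int)
    for v, s in zones:
        P[v - 1, s - 1] += 1
    return P


def gldm_oracle(levels, n_g, alpha=0, delta=1):
    """Count dependent neighbours pixel by pixel."""
    levels = np.asarray(levels)
    h, w = levels.shape
    entries = []
    for r in range(h):
        for c in range(w):
            v = levels[r, c]
            if v == 0:
                continue
            d = 0
            for a in range(-delta, delta + 1):
                for b in range(-delta, delta + 1):
                    if a == 0 and b == 0:
                        continue
                    r2, c2 = r + a, c + b
                    if 0 <= r2 < h and 0 <= c2 < w and levels[r2, c2] > 0:
                        if abs(int(levels[r2, c2]) - int(v)) <= alpha:
                            d += 1
            entries.append((v, d))
    max_d = max((d for _, d in entries), default=0)
    P = np.zeros((n_g, max_d + 1), dtype=int)
    for v, d in entries:
        P[v - 1, d] += 1
    return P


# ---------------------------------------------------------------------------
# direct formula evaluation on an oracle matrix (loops, no numpy reductions)


def _log2e(x):
    return math.log2(x + EPS)


def glcm_features_oracle(P):
    """Eight GLCM features evaluated with explicit loops from counts P."""
    n_g = P.shape[0]
    total = P.sum()
    p = P / total
    px = [sum(p[i][j] for j in range(n_g)) for i in range(n_g)]
    py = [sum(p[i][j] for i in range(n_g)) for j in range(n_g)]
    mu_x = sum(px[i] * (i + 1) for i in range(n_g))
    mu_y = sum(py[j] * (j + 1) for j in range(n_g))
    sig_x = math.sqrt(sum(px[i] * ((i + 1) - mu_x) ** 2 for i in range(n_g)))
    sig_y = math.sqrt(sum(py[j] * ((j + 1) - mu_y) ** 2 for j in range(n_g)))
    p_diff = [0.0] * n_g
    p_sum = [0.0] * (2 * n_g + 1)
    for i in range(n_g):
        for j in range(n_g):
            p_diff[abs(i - j)] += p[i][j]
            p_sum[(i + 1) + (j + 1)] += p[i][j]
    contrast = sum((i - j) ** 2 * p[i][j] for i in range(n_g) for j in range(n_g))
    if sig_x > 0 and sig_y > 0:
        corr = sum(
            p[i][j] * ((i + 1) * (j + 1) - mu_x * mu_y) / (sig_x * sig_y)
            for i in range(n_g)
            for j in range(n_g)
        )
    else:
        corr = 1.0
    da = sum(k * p_diff[k] for k in range(n_g))
    return {
        "Contrast": contrast,
        "Correlation": corr,
        "IDM": sum(p_diff[k] / (1 + k**2) for k in range(n_g)),
        "MaximumProbability": max(p[i][j] for i in range(n_g) for j in range(n_g)),
        "DifferenceAverage": da,
        "DifferenceVariance": sum((k - da) ** 2 * p_diff[k] for k in range(n_g)),
        "SumEntropy": -sum(p_sum[k] * _log2e(p_sum[k]) for k in range(2, 2 * n_g + 1)),
        "DifferenceEntropy": -sum(p_diff[k] * _log2e(p_diff[k]) for k in range(n_g)),
    }


def glrlm_features_oracle(P):
    n_g, max_j = P.shape
    n_r = P.sum()
    p = P / n_r
    mu_i = sum(p[i][j] * (i + 1) for i in range(n_g) for j in range(max_j))
    mu_j = sum(p[i][j] * (j + 1) for i in range(n_g) for j in range(max_j))
    return {
        "GrayLevelNonUniformity": sum(
            sum(P[i][j] for j in range(max_j)) ** 2 for i in range(n_g)
        )
        / n_r,
        "GrayLevelVariance": sum(
            p[i][j] * ((i + 1) - mu_i) ** 2 for i in range(n_g) for j in range(max_j)
        ),
        "RunVariance": sum(
            p[i][j] * ((j + 1) - mu_j) ** 2 for i in range(n_g) for j in range(max_j)
        ),
        "RunEntropy": -sum(
            p[i][j] * _log2e(p[i][j]) for i in range(n_g) for j in range(max_j)
        ),
    }


def glszm_features_oracle(P):
    n_g, max_j = P.shape
    n_z = P.sum()
    p = P / n_z
    mu_i = sum(p[i][j] * (i + 1) for i in range(n_g) for j in range(max_j))
    mu_j = sum(p[i][j] * (j + 1) for i in range(n_g) for j in range(max_j))
    return {
        "GrayLevelNonUniformity": sum(
            sum(P[i][j] for j in range(max_j)) ** 2 for i in range(n_g)
        )
        / n_z,
        "SizeZoneNonUniformity": sum(
            sum(P[i][j] for i in range(n_g)) ** 2 for j in range(max_j)
        )
        / n_z,
        "GrayLevelVariance": sum(
            p[i][j] * ((i + 1) - mu_i) ** 2 for i in range(n_g) for j in range(max_j)
        ),
        "ZoneVariance": sum(
            p[i][j] * ((j + 1) - mu_j) ** 2 for i in range(n_g) for j in range(max_j)
        ),
        "ZoneEntropy": -sum(
            p[i][j] * _log2e(p[i][j]) for i in range(n_g) for j in range(max_j)
        ),
    }


def gldm_features_oracle(P):
    n_g, n_cols = P.shape
    total = P.sum()
    p = P / total
    mu_i = sum(p[i][d] * (i + 1) for i in range(n_g) for d in range(n_cols))
    mu_d = sum(p[i][d] * d for i in range(n_g) for d in range(n_cols))
    return {
        "GrayLevelNonUniformity": sum(
            sum(P[i][d] for d in range(n_cols)) ** 2 for i in range(n_g)
        )
        / total,
        "DependenceNonUniformity": sum(
            sum(P[i][d] for i in range(n_g)) ** 2 for d in range(n_cols)
        )
        / total,
        "GrayLevelVariance": sum(
            p[i][d] * ((i + 1) - mu_i) ** 2 for i in range(n_g) for d in range(n_cols)
        ),
        "DependenceVariance": sum(
            p[i][d] * (d - mu_d) ** 2 for i in range(n_g) for d in range(n_cols)
        ),
        "DependenceEntropy": -sum(
            p[i][d] * _log2e(p[i][d]) for i in range(n_g) for d in range(n_cols)
        ),
    }


def fos_oracle(x, c=0.0):
    """First-order statistics from explicit sums."""
    x = [float(v) for v in np.asarray(x).ravel()]
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    if var > 0:
        skew = (sum((v - mean) ** 3 for v in x) / n) / var**1.5
        kurt = (sum((v - mean) ** 4 for v in x) / n) / var**2
    else:
        skew = kurt = 0.0
    counts = {}
    for v in x:
        counts[v] = counts.get(v, 0) + 1
    p = [cnt / n for cnt in counts.values()]
    return {
        "Mean": mean,
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "RootMeanSquared": math.sqrt(sum((v + c) ** 2 for v in x) / n),
        "Uniformity": sum(q**2 for q in p),
        "Entropy": -sum(q * _log2e(q) for q in p),
        "Energy": sum((v + c) ** 2 for v in x),
    }
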