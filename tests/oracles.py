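"""Independent brute-force oracles for the texture-matrix builders.

Everything here is written by direct enumeration over pixels/pairs/windows,
deliberately sharing no code with the implementation under test.
"""

import itertools
import math

import numpy as np


def glcm_oracle(img_q, distances, angles, n_levels):
    """Pair enumeration: symmetric, normalized co-occurrence averaged over offsets."""
    h, w = img_q.shape
    mats = []
    for d in distances:
        for theta in angles:
            dr = int(round(math.sin(theta) * d))
            dc = int(round(math.cos(theta) * d))
            P = np.zeros((n_levels, n_levels))
            for r in range(h):
                for c in range(w):
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < h and 0 <= c2 < w:
                        i, j = img_q[r, c] - 1, img_q[r2, c2] - 1
                        P[i, j] += 1
                        P[j, i] += 1
            if P.sum() > 0:
                P /= P.sum()
            mats.append(P)
    return np.mean(mats, axis=0)


def glcm_features_oracle(P):
    energy = sum(p * p for p in P.ravel())
    entropy = -sum(p * math.log(p) for p in P.ravel() if p > 0)
    maximum = max(P.ravel())
    contrast = sum((i - j) ** 2 * P[i, j] for i in range(P.shape[0]) for j in range(P.shape[1]))
    homogeneity = sum(P[i, j] / (1 + abs(i - j)) for i in range(P.shape[0]) for j in range(P.shape[1]))
    return energy, entropy, maximum, contrast, homogeneity


def _lines(img_q, direction):
    h, w = img_q.shape
    if direction == "0":
        return [list(img_q[r, :]) for r in range(h)]
    if direction == "90":
        return [list(img_q[:, c]) for c in range(w)]
    if direction == "135":
        return [list(np.diagonal(img_q, k)) for k in range(-(h - 1), w)]
    if direction == "45":
        return [list(np.diagonal(np.fliplr(img_q), k)) for k in range(-(h - 1), w)]
    raise ValueError(direction)


def glrm_oracle(img_q, directions, n_levels):
    """Maximal-run enumeration via groupby along every line of every direction."""
    max_len = max(img_q.shape)
    r = np.zeros((n_levels, max_len), dtype=int)
    for direction in directions:
        for line in _lines(img_q, direction):
            for value, group in itertools.groupby(line):
                r[value - 1, len(list(group)) - 1] += 1
    return r, int(r.sum())


def glrm_features_oracle(r, n_runs):
    spe = lpe = 0.0
    for g in range(r.shape[0]):
        for l0 in range(r.shape[1]):
            spe += r[g, l0] / (l0 + 1) ** 2
            lpe += r[g, l0] * (l0 + 1) ** 2
    glu = sum(r[g, :].sum() ** 2 for g in range(r.shape[0]))
    plu = sum(r[:, l0].sum() ** 2 for l0 in range(r.shape[1]))
    return spe / n_runs, lpe / n_runs, glu / n_runs, plu / n_runs


def ngtdm_oracle(img_q, radius, n_levels):
    """Direct sliding-window accumulation over interior pixels."""
    h, w = img_q.shape
    s = np.zeros(n_levels)
    counts = np.zeros(n_levels)
    for r in range(radius, h - radius):
        for c in range(radius, w - radius):
            window = [
                img_q[r + dr, c + dc]
                for dr in range(-radius, radius + 1)
                for dc in range(-radius, radius + 1)
                if not (dr == 0 and dc == 0)
            ]
            level = img_q[r, c]
            s[level - 1] += abs(level - sum(window) / len(window))
            counts[level - 1] += 1
    return counts / counts.sum(), s, int(counts.sum())


def ngtdm_features_oracle(p, s, n_pixels, epsilon):
    coarseness = 1.0 / (epsilon + sum(p[i] * s[i] for i in range(len(p))))
    present = [i for i in range(len(p)) if p[i] > 0]
    ngp = len(present)
    if ngp <= 1:
        return coarseness, 0.0, 0.0, 0.0
    contrast = (
        sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
        / (ngp * (ngp - 1))
        * (sum(s) / n_pixels)
    )
    complexity = (
        sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in present
            for j in present
        )
        / n_pixels
    )
    strength = sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / (
        epsilon + sum(s)
    )
    return coarseness, contrast, complexity, strength


def first_order_oracle(img):
    x = [float(v) for v in np.asarray(img).ravel()]
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    std = math.sqrt(var)
    skew = sum((v - mean) ** 3 for v in x) / n / std**3
    kurt = sum((v - mean) ** 4 for v in x) / n / std**4
    return mean, std, skew, kurt
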