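"""Per-image texture features: first-order, GLCM, GLRM and NGTDM families.

Seventeen features are computed per image: four first-order moments of the
gray-level distribution; energy, entropy, maximum, contrast and homogeneity
of the gray-level co-occurrence matrix (GLCM); short/long primitive emphasis
and gray-level / primitive-length uniformity of the gray-level run-length
(primitives) matrix (GLRM); and coarseness, contrast, complexity and strength
of the neighborhood gray tone difference matrix (NGTDM).

Matrix features operate on a uniformly quantized image. GLCMs are
symmetrized, normalized and averaged over the configured offsets and angles
(making the feature set invariant under 90-degree rotations when the full
angle set is used); GLRM runs are pooled over the configured directions;
NGTDM uses a square neighborhood window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.ndimage import uniform_filter
from skimage.feature import graycomatrix

FEATURE_NAMES = [
    "mean", "std", "skewness", "kurtosis",
    "glcm_energy", "glcm_entropy", "glcm_maximum", "glcm_contrast", "glcm_homogeneity",
    "glrm_spe", "glrm_lpe", "glrm_glu", "glrm_plu",
    "ngtdm_coarseness", "ngtdm_contrast", "ngtdm_complexity", "ngtdm_strength",
]

_DEG = np.pi / 180.0


@dataclass
class TextureConfig:
    """Quantization and matrix parameters shared by all matrix features."""

    n_gray_levels: int = 16
    glcm_distances: tuple[int, ...] = (1,)
    glcm_angles: tuple[float, ...] = (0.0, 45 * _DEG, 90 * _DEG, 135 * _DEG)
    glrm_directions: tuple[str, ...] = ("0", "45", "90", "135")   # degrees
    ngtdm_neighborhood: int = 1    # window radius
    epsilon: float = 1e-6          # coarseness stabilizer

    def validate(self) -> None:
        if self.n_gray_levels < 2:
            raise ValueError("n_gray_levels must be at least 2")
        if not self.glcm_distances or not self.glcm_angles or not self.glrm_directions:
            raise ValueError("offset/angle/direction lists must be nonempty")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        bad = set(self.glrm_directions) - {"0", "45", "90", "135"}
        if bad:
            raise ValueError(f"unknown GLRM directions: {sorted(bad)}")


@dataclass
class TextureFeatureVector:
    mean: float
    std: float
    skewness: float
    kurtosis: float
    glcm_energy: float
    glcm_entropy: float
    glcm_maximum: float
    glcm_contrast: float
    glcm_homogeneity: float
    glrm_spe: float
    glrm_lpe: float
    glrm_glu: float
    glrm_plu: float
    ngtdm_coarseness: float
    ngtdm_contrast: float
    ngtdm_complexity: float
    ngtdm_strength: float
    flags: list = field(default_factory=list)   # names of undefined (NaN) entries

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=np.float64)

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in FEATURE_NAMES}


def quantize_gray_levels(img: np.ndarray, n_levels: int) -> np.ndarray:
    """Uniformly bin the image's value range into integer labels 1..n_levels."""
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    img = np.asarray(img, dtype=np.float64)
    vmin, vmax = img.min(), img.max()
    if vmax == vmin:
        return np.ones(img.shape, dtype=np.int64)
    q = np.floor((img - vmin) / (vmax - vmin) * n_levels).astype(np.int64) + 1
    return np.minimum(q, n_levels)


def first_order_features(img: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean, std, skewness and (non-excess) kurtosis of the pixels.

    A constant image has zero std; its skewness and kurtosis are undefined and
    returned as NaN for the caller to flag.
    """
    x = np.asarray(img, dtype=np.float64).ravel()
    mean = float(x.mean())
    std = float(x.std())
    if std == 0.0:
        return mean, 0.0, math.nan, math.nan
    return (
        mean,
        std,
        float(sp_stats.skew(x)),
        float(sp_stats.kurtosis(x, fisher=False)),
    )


def glcm(img_q: np.ndarray, cfg: TextureConfig) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix averaged over offsets/angles."""
    cfg.validate()
    img_q = np.asarray(img_q)
    mats = graycomatrix(
        (img_q - 1).astype(np.uint8 if cfg.n_gray_levels <= 256 else np.uint16),
        distances=list(cfg.glcm_distances),
        angles=list(cfg.glcm_angles),
        levels=cfg.n_gray_levels,
        symmetric=True,
        normed=True,
    )
    return mats.mean(axis=(2, 3))


def glcm_features(P: np.ndarray) -> tuple[float, float, float, float, float]:
    """(energy, entropy, maximum, contrast, homogeneity) of a normalized GLCM."""
    P = np.asarray(P, dtype=np.float64)
    if abs(P.sum() - 1.0) > 1e-8:
        raise ValueError("co-occurrence matrix is not normalized to sum 1")
    i, j = np.indices(P.shape)
    nz = P > 0
    energy = float(np.sum(P**2))
    entropy = float(-np.sum(P[nz] * np.log(P[nz])))
    maximum = float(P.max())
    contrast = float(np.sum((i - j) ** 2 * P))
    homogeneity = float(np.sum(P / (1.0 + np.abs(i - j))))
    return energy, entropy, maximum, contrast, homogeneity


def _direction_lines(img_q: np.ndarray, direction: str) -> list[np.ndarray]:
    h, w = img_q.shape
    if direction == "0":
        return list(img_q)
    if direction == "90":
        return list(img_q.T)
    if direction == "135":
        return [np.diagonal(img_q, k) for k in range(-(h - 1), w)]
    if direction == "45":
        flipped = np.fliplr(img_q)
        return [np.diagonal(flipped, k) for k in range(-(h - 1), w)]
    raise ValueError(f"unknown direction {direction!r}")


def glrm(img_q: np.ndarray, cfg: TextureConfig) -> tuple[np.ndarray, int]:
    """Run-length (primitives) matrix pooled over directions, plus total run count.

    ``r[g-1, l-1]`` counts maximal runs of label ``g`` with length ``l`` along
    each configured direction.
    """
    cfg.validate()
    img_q = np.asarray(img_q)
    n_levels = cfg.n_gray_levels
    max_len = max(img_q.shape)
    r = np.zeros((n_levels, max_len), dtype=np.int64)
    sentinel = -1
    for direction in cfg.glrm_directions:
        lines = _direction_lines(img_q, direction)
        flat = np.concatenate([np.append(line, sentinel) for line in lines])
        change = np.flatnonzero(np.diff(flat) != 0)
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change, [flat.size - 1]))
        values = flat[starts]
        lengths = ends - starts + 1
        keep = values != sentinel
        np.add.at(r, (values[keep] - 1, lengths[keep] - 1), 1)
    return r, int(r.sum())


def glrm_features(r: np.ndarray, n_runs: int) -> tuple[float, float, float, float]:
    """(SPE, LPE, GLU, PLU) of a run-length matrix with ``n_runs`` total runs."""
    if n_runs <= 0:
        raise ValueError("run-length matrix has no runs")
    r = np.asarray(r, dtype=np.float64)
    lengths = np.arange(1, r.shape[1] + 1, dtype=np.float64)
    spe = float(np.sum(r / lengths**2) / n_runs)
    lpe = float(np.sum(r * lengths**2) / n_runs)
    glu = float(np.sum(r.sum(axis=1) ** 2) / n_runs)
    plu = float(np.sum(r.sum(axis=0) ** 2) / n_runs)
    return spe, lpe, glu, plu


def ngtdm(img_q: np.ndarray, cfg: TextureConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-level occurrence probabilities p_i and neighborhood difference sums s_i.

    For each interior pixel, the absolute difference between its level and the
    mean of the surrounding window (center excluded) accumulates into the
    pixel's level bin; p_i is the fraction of interior pixels at level i.
    """
    cfg.validate()
    img_q = np.asarray(img_q, dtype=np.float64)
    d = cfg.ngtdm_neighborhood
    if min(img_q.shape) < 2 * d + 1:
        raise ValueError("image smaller than the NGTDM window")
    w = 2 * d + 1
    win_sum = uniform_filter(img_q, size=w, mode="constant") * (w * w)
    neigh_mean = (win_sum - img_q) / (w * w - 1)
    diff = np.abs(img_q - neigh_mean)
    interior = (slice(d, img_q.shape[0] - d), slice(d, img_q.shape[1] - d))
    levels = img_q[interior].astype(np.int64)
    diffs = diff[interior]
    n_levels = cfg.n_gray_levels
    s = np.zeros(n_levels, dtype=np.float64)
    counts = np.zeros(n_levels, dtype=np.float64)
    np.add.at(s, levels.ravel() - 1, diffs.ravel())
    np.add.at(counts, levels.ravel() - 1, 1.0)
    p = counts / counts.sum()
    return p, s


def ngtdm_features(
    p: np.ndarray, s: np.ndarray, cfg: TextureConfig, n_pixels: int | None = None
) -> tuple[float, float, float, float]:
    """(coarseness, contrast, complexity, strength) from NGTDM vectors.

    Canonical neighborhood gray-tone difference definitions; ``cfg.epsilon``
    stabilizes coarseness so a constant image yields 1/epsilon. ``n_pixels``
    is the interior pixel count the (p, s) vectors were accumulated over
    (needed by contrast and complexity); when omitted it is recovered from
    the occurrence probabilities, which is exact whenever some level occurs
    exactly once.
    """
    p = np.asarray(p, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("occurrence probabilities must sum to 1")
    if n_pixels is None:
        n_pixels = int(round(1.0 / p[p > 0].min()))
    levels = np.arange(1, p.size + 1, dtype=np.float64)
    nz = p > 0
    ngp = int(np.count_nonzero(nz))
    eps = cfg.epsilon

    coarseness = 1.0 / (eps + float(np.sum(p * s)))

    if ngp > 1:
        ii, jj = np.meshgrid(levels[nz], levels[nz], indexing="ij")
        pi, pj = np.meshgrid(p[nz], p[nz], indexing="ij")
        si, sj = np.meshgrid(s[nz], s[nz], indexing="ij")
        contrast = float(
            np.sum(pi * pj * (ii - jj) ** 2) / (ngp * (ngp - 1)) * (s.sum() / n_pixels)
        )
        complexity = float(
            np.sum(np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)) / n_pixels
        )
        strength = float(np.sum((pi + pj) * (ii - jj) ** 2) / (eps + s.sum()))
    else:
        contrast = 0.0
        complexity = 0.0
        strength = 0.0
    return coarseness, contrast, complexity, strength


def texture_feature_vector(img: np.ndarray, cfg: TextureConfig | None = None) -> TextureFeatureVector:
    """Compose the 17 named texture features for one image.

    Undefined entries on degenerate input (e.g. skewness of a constant image)
    are NaN with their names listed in ``flags`` -- never silent zeros.
    """
    cfg = cfg or TextureConfig()
    cfg.validate()
    img = np.asarray(img, dtype=np.float64)
    mean, std, skew, kurt = first_order_features(img)
    img_q = quantize_gray_levels(img, cfg.n_gray_levels)
    gl = glcm_features(glcm(img_q, cfg))
    r, n_runs = glrm(img_q, cfg)
    rl = glrm_features(r, n_runs)
    p, s = ngtdm(img_q, cfg)
    d = cfg.ngtdm_neighborhood
    n_interior = (img.shape[0] - 2 * d) * (img.shape[1] - 2 * d)
    ng = ngtdm_features(p, s, cfg, n_pixels=n_interior)
    vec = TextureFeatureVector(mean, std, skew, kurt, *gl, *rl, *ng)
    vec.flags = [n for n in FEATURE_NAMES if not np.isfinite(getattr(vec, n))]
    return vec


def texture_feature_table(ensemble, cfg: TextureConfig | None = None) -> pd.DataFrame:
    """17-column feature table, one row per image of an ensemble or image stack."""
    cfg = cfg or TextureConfig()
    images = ensemble.images if hasattr(ensemble, "images") else np.asarray(ensemble)
    rows = [texture_feature_vector(img, cfg).to_dict() for img in images]
    table = pd.DataFrame(rows)
    table.insert(0, "image", np.arange(len(rows)))
    return table
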