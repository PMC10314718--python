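"""Clustered lumpy background (CLB) simulator.

The CLB model synthesizes mammography-like random textures by superposing
small elliptical "blobs" whose centers cluster around randomly placed cluster
centers. One texture layer is built as

    f(r) = sum_k sum_n  b(r - r_k - d_kn ; theta_kn),

where cluster centers ``r_k`` form a homogeneous Poisson process, per-cluster
blob offsets ``d_kn`` are isotropic Gaussians, and each blob contributes an
exponential-of-power elliptical profile

    b(u; theta) = exp(-alpha * s(u, theta)**beta),
    s**2 = (u'/Lx)**2 + (v'/Ly)**2,

with ``(u', v')`` the offset rotated into the blob frame. Blob orientations
are either drawn uniformly per blob (isotropic variants) or share a preferred
per-cluster direction with angular jitter (oriented variants). Double-layer
variants sum two independent layers before gray mapping.

Five named configurations ship as editable flat-text config files; their
numeric parameter tables are package data, not code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from numba import njit

from .config import parse_flat_config
from .ensemble import ImageEnsemble, derive_image_seed

CONFIG_NAMES = ("opex99", "simpiso", "simpori", "doubiso", "doubori")

# Blob profile truncated where it falls below this fraction of its peak.
_PROFILE_CUTOFF = 1e-3


@dataclass
class CLBLayerParams:
    """Parameters of one CLB texture layer."""

    mean_cluster_count: float        # expected clusters per image field
    mean_blobs_per_cluster: float
    cluster_spread: float            # std of blob offsets about cluster center (px)
    blob_length_x: float             # blob characteristic half-length, long axis (px)
    blob_length_y: float             # blob characteristic half-length, short axis (px)
    blob_alpha: float                # radial decay coefficient
    blob_beta: float                 # radial decay exponent
    orientation_mode: str = "isotropic"      # "isotropic" | "oriented"
    orientation_params: dict = field(default_factory=dict)  # {"angular_jitter": rad}

    def validate(self) -> None:
        for name in ("mean_blobs_per_cluster", "cluster_spread", "blob_length_x",
                     "blob_length_y", "blob_alpha", "blob_beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CLB layer parameter {name} must be strictly positive")
        if self.mean_cluster_count < 0:
            raise ValueError("mean_cluster_count must be nonnegative")
        if self.orientation_mode not in ("isotropic", "oriented"):
            raise ValueError(f"orientation_mode must be 'isotropic' or 'oriented', got {self.orientation_mode!r}")


@dataclass
class GrayMapping:
    """Monotone affine map raw -> offset + scale*raw, clipped to [clip_low, clip_high]."""

    offset: float = 0.0
    scale: float = 1.0
    clip_low: float = 0.0
    clip_high: float = 255.0

    def validate(self) -> None:
        if not self.clip_low < self.clip_high:
            raise ValueError("gray mapping clip range must be ordered low < high")

    def apply(self, raw: np.ndarray) -> np.ndarray:
        return np.clip(self.offset + self.scale * raw, self.clip_low, self.clip_high)


@dataclass
class CLBConfig:
    layers: tuple[CLBLayerParams, ...]
    image_size: int = 256
    gray_mapping: GrayMapping = field(default_factory=GrayMapping)
    config_name: str = "custom"

    def validate(self) -> None:
        if len(self.layers) not in (1, 2):
            raise ValueError("CLB configs have one or two layers")
        for layer in self.layers:
            layer.validate()
        self.gray_mapping.validate()
        if self.image_size < 8:
            raise ValueError("image_size must be at least 8")


_LUT_SIZE = 4096


@njit(cache=True)
def _render_blobs(field, bx, by, bang, lx, ly, smax, lut):  # pragma: no cover - jit
    # lut tabulates exp(-alpha * s**beta) against q = s**2 on [0, smax**2];
    # linear interpolation keeps the profile error below ~1e-5 of the peak.
    size = field.shape[0]
    reach = smax * max(lx, ly)
    qmax = smax * smax
    scale = (lut.shape[0] - 1) / qmax
    for i in range(bx.shape[0]):
        cx = bx[i]
        cy = by[i]
        ca = math.cos(bang[i])
        sa = math.sin(bang[i])
        x0 = max(0, int(math.floor(cx - reach)))
        x1 = min(size - 1, int(math.ceil(cx + reach)))
        y0 = max(0, int(math.floor(cy - reach)))
        y1 = min(size - 1, int(math.ceil(cy + reach)))
        for x in range(x0, x1 + 1):
            dx = x - cx
            for y in range(y0, y1 + 1):
                dy = y - cy
                u = (ca * dx + sa * dy) / lx
                v = (-sa * dx + ca * dy) / ly
                q = u * u + v * v
                if q < qmax:
                    t = q * scale
                    j = int(t)
                    frac = t - j
                    field[x, y] += lut[j] * (1.0 - frac) + lut[j + 1] * frac
    return field


def blob_profile_lut(alpha: float, beta: float, smax: float, size: int = _LUT_SIZE) -> np.ndarray:
    """Tabulated elliptical blob profile exp(-alpha*s**beta) against s**2."""
    s = np.sqrt(np.linspace(0.0, smax**2, size))
    return np.exp(-alpha * s**beta)


def border_margin(params: CLBLayerParams) -> float:
    """Extension of the cluster-center field beyond the image border (pixels).

    Covers three blob characteristic lengths plus three cluster spreads, so
    clusters centered outside the image still contribute their blob mass near
    the border and edge statistics stay stationary.
    """
    return 3.0 * max(params.blob_length_x, params.blob_length_y) + 3.0 * params.cluster_spread


def sample_layer_geometry(
    params: CLBLayerParams, size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int]:
    """Draw blob positions and orientations for one layer.

    Cluster count is Poisson with the configured per-field mean scaled to the
    border-extended field area; centers are uniform over the extended field;
    per-cluster blob counts are Poisson and blob offsets isotropic Gaussians.
    Returns (positions, angles, n_clusters); positions are in image pixel
    coordinates (possibly outside [0, size)).
    """
    margin = border_margin(params)
    lo, hi = -margin, size + margin
    density = params.mean_cluster_count / size**2
    n_clusters = rng.poisson(density * (hi - lo) ** 2)
    if n_clusters == 0:
        return np.empty((0, 2)), np.empty(0), 0
    centers = rng.uniform(lo, hi, size=(n_clusters, 2))
    blob_counts = rng.poisson(params.mean_blobs_per_cluster, size=n_clusters)
    total = int(blob_counts.sum())
    if total == 0:
        return np.empty((0, 2)), np.empty(0), n_clusters
    cluster_of_blob = np.repeat(np.arange(n_clusters), blob_counts)
    offsets = rng.normal(0.0, params.cluster_spread, size=(total, 2))
    positions = centers[cluster_of_blob] + offsets
    if params.orientation_mode == "isotropic":
        angles = rng.uniform(0.0, math.pi, size=total)
    else:
        jitter = float(params.orientation_params.get("angular_jitter", 0.3))
        preferred = rng.uniform(0.0, math.pi, size=n_clusters)
        angles = preferred[cluster_of_blob] + rng.normal(0.0, jitter, size=total)
    return positions, angles, n_clusters


def sample_clb_layer(params: CLBLayerParams, size: int, seed) -> np.ndarray:
    """Draw one raw (pre-gray-mapping) CLB texture layer."""
    params.validate()
    if size < 8:
        raise ValueError("size must be at least 8")
    if seed is None:
        raise ValueError("a seed is required; all sampling must be reproducible")
    rng = np.random.default_rng(seed)
    smax = (math.log(1.0 / _PROFILE_CUTOFF) / params.blob_alpha) ** (1.0 / params.blob_beta)
    field = np.zeros((size, size), dtype=np.float64)
    positions, angles, _ = sample_layer_geometry(params, size, rng)
    if positions.shape[0] == 0:
        return field
    _render_blobs(
        field,
        np.ascontiguousarray(positions[:, 0]),
        np.ascontiguousarray(positions[:, 1]),
        np.ascontiguousarray(angles),
        params.blob_length_x,
        params.blob_length_y,
        smax,
        blob_profile_lut(params.blob_alpha, params.blob_beta, smax),
    )
    return field


def sample_clb_image(config: CLBConfig, seed) -> np.ndarray:
    """Sum the config's independently seeded layers and apply the gray mapping."""
    config.validate()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(config.layers))
    raw = sum(
        sample_clb_layer(layer, config.image_size, child)
        for layer, child in zip(config.layers, children)
    )
    return config.gray_mapping.apply(raw)


def generate_clb_ensemble(config: CLBConfig, n: int, seed: int) -> ImageEnsemble:
    """Generate ``n`` CLB images with per-image seeds derived from ``seed``."""
    if n < 1:
        raise ValueError("n must be at least 1")
    config.validate()
    # float32 storage keeps large evaluation ensembles in memory
    images = np.empty((n, config.image_size, config.image_size), dtype=np.float32)
    for i in range(n):
        images[i] = sample_clb_image(config, derive_image_seed(seed, i))
    return ImageEnsemble(
        images,
        pixel_pitch=None,
        provenance={"model": "clb", "config": config.config_name, "n": n, "seed": int(seed)},
    )


# -- config file handling ----------------------------------------------------

def _layer_from_flat(flat: dict[str, str], prefix: str) -> CLBLayerParams:
    get = lambda k: flat[f"{prefix}.{k}"]
    mode = flat.get(f"{prefix}.orientation_mode", "isotropic")
    oparams = {}
    if f"{prefix}.angular_jitter" in flat:
        oparams["angular_jitter"] = float(flat[f"{prefix}.angular_jitter"])
    return CLBLayerParams(
        mean_cluster_count=float(get("mean_cluster_count")),
        mean_blobs_per_cluster=float(get("mean_blobs_per_cluster")),
        cluster_spread=float(get("cluster_spread")),
        blob_length_x=float(get("blob_length_x")),
        blob_length_y=float(get("blob_length_y")),
        blob_alpha=float(get("blob_alpha")),
        blob_beta=float(get("blob_beta")),
        orientation_mode=mode,
        orientation_params=oparams,
    )


def load_clb_config(name_or_path: str | Path) -> CLBConfig:
    """Load a CLB config by built-in name (opex99, simpiso, ...) or file path."""
    if str(name_or_path) in CONFIG_NAMES:
        path = resources.files("simbench.configs") / f"{name_or_path}.cfg"
        name = str(name_or_path)
    else:
        path = Path(name_or_path)
        name = path.stem
    flat = parse_flat_config(path)
    n_layers = int(flat.get("n_layers", 1))
    layers = tuple(_layer_from_flat(flat, f"layer{i + 1}") for i in range(n_layers))
    gm = GrayMapping(
        offset=float(flat.get("gray.offset", 0.0)),
        scale=float(flat.get("gray.scale", 1.0)),
        clip_low=float(flat.get("gray.clip_low", 0.0)),
        clip_high=float(flat.get("gray.clip_high", 255.0)),
    )
    cfg = CLBConfig(
        layers=layers,
        image_size=int(flat.get("image_size", 256)),
        gray_mapping=gm,
        config_name=flat.get("config_name", name),
    )
    cfg.validate()
    return cfg
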