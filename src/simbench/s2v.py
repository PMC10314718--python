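"""Stylized 2-D breast-slice model: labels, attenuation, and the F:G statistic.

A breast slice is a 2-D map of tissue labels (fat, glandular, skin, vessels,
...). Assigning each tissue its linear X-ray attenuation coefficient at a
stated photon energy turns a label map into a grayscale attenuation image,
and the fat-to-glandular ratio rho_{F:G} = F/G -- the pixel counts within a
relative tolerance of the fat and glandular coefficients -- is the pertinent
per-image statistic: it separates the four clinical breast-composition types.

Because the external 3-D anthropomorphic phantom generator is out of scope, a
surrogate 2-D phantom generator produces label maps directly: a breast mask
with a skin rim whose interior is split into glandular and fat regions by
thresholding a smoothed Gaussian random field, so that the realized F:G ratio
hits a target drawn from a configurable four-mode mixture of log-ratios
mimicking the clinical breast-type prevalences. The surrogate preserves the
statistic under test, not anatomic realism.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import ndimage

from .ensemble import ImageEnsemble, derive_image_seed

logger = logging.getLogger(__name__)

TISSUE_LABELS = {
    0: "background",
    1: "fat",
    2: "glandular",
    3: "skin",
    4: "artery",
    5: "vein",
    6: "muscle",
    7: "ligament",
    8: "nipple",
    9: "tdlu",
}
LABEL_IDS = {name: i for i, name in TISSUE_LABELS.items()}


@dataclass
class AttenuationTable:
    """Linear attenuation coefficients (cm^-1) per tissue at a photon energy (keV)."""

    energy_kev: float
    coefficients: dict[str, float]   # tissue name -> mu (cm^-1)

    def validate(self, tolerance: float = 0.015) -> None:
        for name, mu in self.coefficients.items():
            if mu < 0:
                raise ValueError(f"attenuation coefficient for {name} must be nonnegative")
        fat, gland = self.coefficients["fat"], self.coefficients["glandular"]
        # separability: thresholding at +-tolerance (relative) must never
        # confuse fat with glandular
        if abs(fat - gland) <= 2 * tolerance * max(fat, gland):
            raise ValueError("fat and glandular coefficients too close for threshold separation")

    def __getitem__(self, tissue: str) -> float:
        return self.coefficients[tissue]

    @classmethod
    def from_csv(cls, path: str | Path, energy_kev: float = 30.0) -> "AttenuationTable":
        coeffs = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line or line.lower().startswith("tissue"):
                continue
            name, value = (s.strip() for s in line.split(",", 1))
            coeffs[name] = float(value)
        table = cls(energy_kev, coeffs)
        table.validate()
        return table

    @classmethod
    def default(cls) -> "AttenuationTable":
        """Editable default table at 30 keV shipped as package data."""
        path = resources.files("simbench.configs") / "attenuation_30kev.csv"
        return cls.from_csv(path)


@dataclass
class LabelSlice:
    """2-D grid of tissue labels (integer ids into TISSUE_LABELS)."""

    labels: np.ndarray
    pixel_pitch: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label slice must be 2-D")

    def counts(self) -> dict[str, int]:
        ids, n = np.unique(self.labels, return_counts=True)
        return {TISSUE_LABELS[int(i)]: int(c) for i, c in zip(ids, n)}


@dataclass
class RatioStats:
    """Fat and glandular pixel counts and their ratio for one image."""

    F: int
    G: int

    @property
    def ratio(self) -> float:
        if self.G == 0:
            return math.nan
        return self.F / self.G

    @property
    def log_ratio(self) -> float:
        r = self.ratio
        if math.isnan(r) or r <= 0:
            return math.nan
        return math.log(r)

    @property
    def defined(self) -> bool:
        return self.G > 0 and self.F > 0


def assign_attenuation(sl: LabelSlice, table: AttenuationTable) -> np.ndarray:
    """Pixelwise label -> attenuation lookup; output image in cm^-1."""
    ids = np.unique(sl.labels)
    lut = np.zeros(int(ids.max()) + 1, dtype=np.float64)
    for i in ids:
        name = TISSUE_LABELS.get(int(i))
        if name is None or name not in table.coefficients:
            raise KeyError(f"label {int(i)} ({name or 'unknown'}) not covered by attenuation table")
        lut[int(i)] = table.coefficients[name]
    return lut[sl.labels]


def extract_slices(
    volume: np.ndarray,
    inner_fraction_range: tuple[float, float] = (0.40, 0.70),
    spacing: int = 50,
    out_size: int = 512,
    pixel_pitch: float | None = None,
) -> list[LabelSlice]:
    """Extract equally spaced coronal label slices from a labeled 3-D stack.

    Plane indices run from the outermost (index 0) to the innermost coronal
    plane along axis 0. Selection starts at the first index at or beyond
    ``lo * depth`` and steps by ``spacing`` while staying within
    ``hi * depth``. Each slice is resampled to ``out_size`` square with
    nearest-neighbour (label-preserving) interpolation.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("expected a 3-D labeled volume")
    depth = volume.shape[0]
    if depth < spacing:
        raise ValueError(f"volume depth {depth} shorter than slice spacing {spacing}")
    lo, hi = inner_fraction_range
    indices = list(range(int(math.ceil(lo * depth)), int(math.floor(hi * depth)) + 1, spacing))
    if not indices:
        warnings.warn("slice selection is empty for the given range/spacing", stacklevel=2)
        return []
    out = []
    for idx in indices:
        plane = volume[idx]
        if plane.shape != (out_size, out_size):
            zoom = (out_size / plane.shape[0], out_size / plane.shape[1])
            plane = ndimage.zoom(plane, zoom, order=0, mode="nearest")
        out.append(LabelSlice(plane.copy(), pixel_pitch))
    return out


def fat_glandular_ratio(img: np.ndarray, table: AttenuationTable, tolerance: float = 0.015) -> RatioStats:
    """Count pixels within a relative tolerance of the fat / glandular coefficients.

    ``F`` counts pixels within ``+-tolerance`` (relative) of the fat
    coefficient, ``G`` likewise for glandular; the ratio is F/G, undefined
    (NaN, ``defined=False``) when G = 0.
    """
    img = np.asarray(img)
    fat, gland = table["fat"], table["glandular"]
    F = int(np.count_nonzero(np.abs(img - fat) <= tolerance * fat))
    G = int(np.count_nonzero(np.abs(img - gland) <= tolerance * gland))
    stats = RatioStats(F=F, G=G)
    if G == 0:
        logger.info("glandular count is zero: ratio undefined for this image")
    return stats


@dataclass
class SurrogatePhantomConfig:
    """Configuration of the surrogate 2-D label-map generator.

    The four-mode log-ratio mixture mimics the clinical breast-composition
    types: mode centers are log(F/G) values from almost-entirely-fatty down to
    extremely dense, with configurable prevalences.
    """

    image_size: int = 256
    skin_thickness: int = 3                      # pixels
    breast_radius_fraction: float = 0.46         # of image size
    mode_prevalences: tuple[float, ...] = (0.10, 0.40, 0.40, 0.10)
    mode_log_ratio_means: tuple[float, ...] = (2.2, 1.1, 0.1, -0.8)
    mode_log_ratio_stds: tuple[float, ...] = (0.15, 0.15, 0.15, 0.15)
    blob_scale: float = 8.0                      # glandular structure correlation length (px)
    ratio_tolerance: float = 0.05                # relative tolerance on realized F/G
    include_minor_tissues: bool = True
    pixel_pitch: float | None = None

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")
        if not math.isclose(sum(self.mode_prevalences), 1.0, abs_tol=1e-9):
            raise ValueError("mode prevalences must sum to 1")
        if not (len(self.mode_prevalences) == len(self.mode_log_ratio_means) == len(self.mode_log_ratio_stds)):
            raise ValueError("mixture component lists must have equal length")
        if self.skin_thickness < 1 or self.blob_scale <= 0 or self.ratio_tolerance <= 0:
            raise ValueError("skin_thickness, blob_scale and ratio_tolerance must be positive")


def sample_surrogate_phantom_slice(cfg: SurrogatePhantomConfig, seed) -> LabelSlice:
    """Draw one label map whose realized F:G ratio hits a sampled mixture target.

    The interior (non-skin) breast pixels are ranked by a smoothed Gaussian
    random field; the top ``G`` ranks become glandular and the rest fat, with
    ``G`` chosen from the target ratio, so the realized ratio is exact by
    construction up to the (optional) minor-tissue overwrites.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    size = cfg.image_size

    mode = rng.choice(len(cfg.mode_prevalences), p=np.asarray(cfg.mode_prevalences))
    target_log_ratio = rng.normal(cfg.mode_log_ratio_means[mode], cfg.mode_log_ratio_stds[mode])
    target_ratio = math.exp(target_log_ratio)

    yy, xx = np.mgrid[0:size, 0:size]
    cx = cy = (size - 1) / 2.0
    # mildly elliptical, randomly oriented breast outline
    ecc = rng.uniform(0.85, 1.0)
    ang = rng.uniform(0, np.pi)
    u = (xx - cx) * math.cos(ang) + (yy - cy) * math.sin(ang)
    v = -(xx - cx) * math.sin(ang) + (yy - cy) * math.cos(ang)
    radius = cfg.breast_radius_fraction * size
    r = np.sqrt((u / ecc) ** 2 + (v * ecc) ** 2)
    breast = r <= radius
    interior = r <= radius - cfg.skin_thickness

    labels = np.zeros((size, size), dtype=np.uint8)
    labels[breast] = LABEL_IDS["skin"]

    n_int = int(np.count_nonzero(interior))
    if n_int < 16:
        raise ValueError("breast interior too small for the requested geometry")
    n_gland = int(round(n_int / (1.0 + target_ratio)))
    n_gland = max(1, min(n_int - 1, n_gland))
    realized = (n_int - n_gland) / n_gland
    if abs(realized - target_ratio) / target_ratio > cfg.ratio_tolerance:
        raise ValueError(
            f"target F:G ratio {target_ratio:.3g} infeasible for interior of {n_int} pixels"
        )

    gfield = ndimage.gaussian_filter(rng.standard_normal((size, size)), cfg.blob_scale)
    # bias the glandular field toward the center, as in real breast anatomy
    gfield = gfield - 0.5 * (r / radius) * np.std(gfield)
    vals = gfield[interior]
    cut = np.partition(vals, n_int - n_gland)[n_int - n_gland]
    gland_mask = interior & (gfield >= cut)
    # ranking ties (rare, float field) may overshoot by a pixel; trim exactly
    idx = np.flatnonzero(gland_mask.ravel())
    if idx.size > n_gland:
        drop = rng.choice(idx, idx.size - n_gland, replace=False)
        gm = gland_mask.ravel()
        gm[drop] = False
        gland_mask = gm.reshape(gland_mask.shape)
    labels[interior] = LABEL_IDS["fat"]
    labels[gland_mask] = LABEL_IDS["glandular"]

    if cfg.include_minor_tissues:
        _add_minor_tissues(labels, interior, rng)

    return LabelSlice(labels, cfg.pixel_pitch)


def _add_minor_tissues(labels: np.ndarray, interior: np.ndarray, rng: np.random.Generator) -> None:
    """Overwrite a small fraction of interior pixels with thin vessel/ligament tracks."""
    size = labels.shape[0]
    for tissue in ("artery", "vein", "ligament"):
        x, y = rng.uniform(0.3 * size, 0.7 * size, 2)
        direction = rng.uniform(0, 2 * np.pi)
        for _ in range(size):
            xi, yi = int(x), int(y)
            if 0 <= xi < size and 0 <= yi < size and interior[yi, xi]:
                labels[yi, xi] = LABEL_IDS[tissue]
            direction += rng.normal(0, 0.2)
            x += math.cos(direction)
            y += math.sin(direction)


def generate_s2v_ensemble(
    cfg: SurrogatePhantomConfig,
    table: AttenuationTable,
    n: int,
    seed: int,
) -> ImageEnsemble:
    """Generate ``n`` attenuation images (cm^-1) from surrogate label maps."""
    if n < 1:
        raise ValueError("n must be at least 1")
    cfg.validate()
    images = np.empty((n, cfg.image_size, cfg.image_size), dtype=np.float64)
    for i in range(n):
        sl = sample_surrogate_phantom_slice(cfg, derive_image_seed(seed, i))
        images[i] = assign_attenuation(sl, table)
    return ImageEnsemble(
        images,
        pixel_pitch=cfg.pixel_pitch,
        provenance={"model": "s2v_surrogate", "n": n, "seed": int(seed),
                    "energy_kev": table.energy_kev},
    )
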