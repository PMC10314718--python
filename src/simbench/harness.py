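"""End-to-end comparison pipeline.

Scores a candidate image ensemble against a reference ensemble through the
statistics pertinent to the reference model: per-feature and aggregate
texture-feature JS divergences, the 2-D PDF over the first two principal
feature components, the speckle SNR² distribution, the fat-to-glandular
log-ratio distribution, the pooled gray-level PDF and the radial
autocorrelation profile. Every metric is computed identically on both
ensembles, and every comparison should be read against its *noise floor*:
the same metric computed between two independent draws of the reference
model, the attainable lower reference for finite ensembles.

Also provides the degradation and mixing operators used to build stylized
multi-class datasets (a blurred/low-passed class mixed with the regular class
at a chosen prevalence).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .ensemble import ImageEnsemble
from .s2v import AttenuationTable, fat_glandular_ratio
from .stats import (
    ensemble_snr2,
    gray_level_pdf,
    js_divergence,
    js_divergence_pmf,
    pca_feature_pdf,
    radial_autocorrelation,
)
from .texture import TextureConfig, texture_feature_table, FEATURE_NAMES

logger = logging.getLogger(__name__)

ALL_METRICS = ("features", "pca", "snr2", "ratio", "gray_pdf", "autocorr")

#: Default metric subsets per modality.
SUITES = {
    "clb": ("features", "pca", "gray_pdf", "autocorr"),
    "uss": ("snr2", "gray_pdf", "autocorr"),
    "s2v": ("ratio", "gray_pdf", "autocorr"),
}


def degrade_image(img: np.ndarray, blur_sigma: float = 2.0) -> np.ndarray:
    """Gaussian blur followed by an ideal low-pass at half the image bandwidth.

    The spectral mask zeroes every frequency with radial magnitude above
    0.25 cycles/pixel (half of Nyquist); the output is real-valued.
    """
    if blur_sigma <= 0:
        raise ValueError("blur_sigma must be positive")
    img = np.asarray(img, dtype=np.float64)
    blurred = gaussian_filter(img, blur_sigma, mode="reflect")
    fy = np.fft.fftfreq(img.shape[0])[:, None]
    fx = np.fft.fftfreq(img.shape[1])[None, :]
    mask = np.hypot(fy, fx) <= 0.25
    return np.fft.ifft2(np.fft.fft2(blurred) * mask).real


def degrade_ensemble(e: ImageEnsemble, blur_sigma: float = 2.0) -> ImageEnsemble:
    images = np.stack([degrade_image(img, blur_sigma) for img in e.images]).astype(e.images.dtype)
    prov = dict(e.provenance)
    prov["degraded"] = {"blur_sigma": blur_sigma, "lowpass_cutoff_cyc_per_px": 0.25}
    return ImageEnsemble(images, e.pixel_pitch, prov)


@dataclass
class MixtureSpec:
    """A stylized multi-class dataset: components drawn at given prevalences.

    ``components`` are generator callables ``f(n, seed) -> ImageEnsemble``
    (so each class is sampled independently and reproducibly).
    """

    components: tuple
    fractions: tuple[float, ...]
    n: int
    seed: int

    def validate(self) -> None:
        if len(self.components) != len(self.fractions):
            raise ValueError("components and fractions must align")
        if self.n < 1:
            raise ValueError("n must be at least 1")
        f = np.asarray(self.fractions, dtype=np.float64)
        if np.any(f <= 0) or np.any(f >= 1 + 1e-12) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must lie in (0, 1] and sum to 1")


def mix_ensembles(spec: MixtureSpec) -> ImageEnsemble:
    """Draw ``n`` images with class labels from the categorical prevalence law.

    Class labels are retained in provenance for diagnostics; metrics never see
    them.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(spec.seed), spawn_key=(0xA11,)))
    labels = rng.choice(len(spec.components), size=spec.n, p=np.asarray(spec.fractions))
    pieces = []
    for k, component in enumerate(spec.components):
        count = int(np.count_nonzero(labels == k))
        if count == 0:
            pieces.append(None)
            continue
        pieces.append(component(count, int(spec.seed) + 7919 * (k + 1)))
    shapes = {p.shape for p in pieces if p is not None}
    if len(shapes) != 1:
        raise ValueError("mixture components produced mismatched image shapes")
    (h, w) = shapes.pop()
    dtype = np.result_type(*[p.images.dtype for p in pieces if p is not None])
    images = np.empty((spec.n, h, w), dtype=dtype)
    cursors = [0] * len(spec.components)
    for i, k in enumerate(labels):
        images[i] = pieces[k][cursors[k]]
        cursors[k] += 1
    pitch = next(p.pixel_pitch for p in pieces if p is not None)
    return ImageEnsemble(
        images,
        pitch,
        provenance={
            "mixture": {
                "fractions": list(map(float, spec.fractions)),
                "realized_counts": [int(np.count_nonzero(labels == k)) for k in range(len(spec.components))],
                "seed": int(spec.seed),
            },
            "class_labels": labels.tolist(),
        },
    )


@dataclass
class ComparisonReport:
    """Per-statistic divergences between a reference and a candidate ensemble.

    ``metrics`` maps metric names to scalars (JS divergences in nats, except
    ``autocorr_max_abs_diff``); ``per_feature_js`` holds the 17 individual
    texture-feature divergences; ``noise_floor`` (same keys as ``metrics``,
    plus per-feature floors under ``per_feature_js``) is attached by
    :func:`noise_floor` comparisons.
    """

    metrics: dict = field(default_factory=dict)
    per_feature_js: dict = field(default_factory=dict)
    noise_floor: dict | None = None
    provenance_ref: dict = field(default_factory=dict)
    provenance_cand: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "metrics": self.metrics,
                "per_feature_js": self.per_feature_js,
                "noise_floor": self.noise_floor,
                "provenance_ref": self.provenance_ref,
                "provenance_cand": self.provenance_cand,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "ComparisonReport":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            metrics=d["metrics"],
            per_feature_js=d["per_feature_js"],
            noise_floor=d.get("noise_floor"),
            provenance_ref=d.get("provenance_ref", {}),
            provenance_cand=d.get("provenance_cand", {}),
        )

    def attach_floor(self, floor: "ComparisonReport") -> None:
        self.noise_floor = dict(floor.metrics)
        if floor.per_feature_js:
            self.noise_floor["per_feature_js"] = dict(floor.per_feature_js)


def compare_ensembles(
    ref: ImageEnsemble,
    cand: ImageEnsemble,
    metrics: tuple[str, ...] = SUITES["clb"],
    texture_cfg: TextureConfig | None = None,
    attenuation_table: AttenuationTable | None = None,
    bins: int = 64,
    feature_aggregate: str = "mean",
) -> ComparisonReport:
    """Run the configured metric subset identically on both ensembles."""
    if len(ref) == 0 or len(cand) == 0:
        raise ValueError("ensembles must be nonempty")
    if ref.shape != cand.shape:
        raise ValueError(f"image shape mismatch: {ref.shape} vs {cand.shape}")
    unknown = set(metrics) - set(ALL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    report = ComparisonReport(provenance_ref=dict(ref.provenance), provenance_cand=dict(cand.provenance))

    if "features" in metrics or "pca" in metrics:
        cfg = texture_cfg or TextureConfig()
        tref = texture_feature_table(ref, cfg)
        tcand = texture_feature_table(cand, cfg)
        if "features" in metrics:
            per = {
                name: js_divergence(tref[name], tcand[name], bins=bins)
                for name in FEATURE_NAMES
            }
            report.per_feature_js = per
            vals = np.array(list(per.values()))
            report.metrics["feature_js"] = float(vals.mean() if feature_aggregate == "mean" else vals.max())
        if "pca" in metrics:
            pref, pcand, _ = pca_feature_pdf(tref, tcand)
            report.metrics["pca_js"] = js_divergence_pmf(pref.mass, pcand.mass)

    if "snr2" in metrics:
        report.metrics["snr2_js"] = js_divergence(
            ensemble_snr2(ref.images), ensemble_snr2(cand.images), bins=bins
        )

    if "ratio" in metrics:
        if attenuation_table is None:
            attenuation_table = AttenuationTable.default()
        def _log_ratios(e):
            out = [fat_glandular_ratio(img, attenuation_table).log_ratio for img in e.images]
            return np.asarray(out)
        report.metrics["ratio_js"] = js_divergence(_log_ratios(ref), _log_ratios(cand), bins=bins)

    if "gray_pdf" in metrics:
        pooled_min = min(ref.images.min(), cand.images.min())
        pooled_max = max(ref.images.max(), cand.images.max())
        pr = gray_level_pdf(ref, bins=bins, value_range=(pooled_min, pooled_max))
        pc = gray_level_pdf(cand, bins=bins, value_range=(pooled_min, pooled_max))
        report.metrics["gray_level_js"] = js_divergence_pmf(pr.mass, pc.mass)

    if "autocorr" in metrics:
        ar = radial_autocorrelation(ref)
        ac = radial_autocorrelation(cand)
        report.metrics["autocorr_max_abs_diff"] = float(np.max(np.abs(ar.values - ac.values)))

    return report


def noise_floor(
    generator,
    n: int,
    seed_a: int,
    seed_b: int,
    metrics: tuple[str, ...] = SUITES["clb"],
    **kwargs,
) -> ComparisonReport:
    """Compare two independent draws of the same model: the metric noise floor.

    ``generator`` is a callable ``f(n, seed) -> ImageEnsemble``.
    """
    if seed_a == seed_b:
        raise ValueError("noise floor requires two different seeds")
    ea = generator(n, seed_a)
    eb = generator(n, seed_b)
    return compare_ensembles(ea, eb, metrics=metrics, **kwargs)
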