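"""Ensemble statistics and distribution comparisons.

Gray-level PDFs, Papoulis-windowed radial autocorrelation, empirical
Jensen-Shannon divergence between samples, per-image speckle SNR²/N-hat, the
least-squares Gaussian fit to an empirical PDF, and the joint PDF over the
first two principal components of texture-feature tables.

All divergences use natural logarithms, so they live in [0, ln 2].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal.windows import bohman
from scipy.spatial.distance import jensenshannon
from sklearn.decomposition import PCA

from .texture import FEATURE_NAMES

LN2 = math.log(2.0)


@dataclass
class EmpiricalPDF:
    """Histogram density over one or two dimensions."""

    edges: tuple[np.ndarray, ...]
    density: np.ndarray
    n_samples: int

    @property
    def mass(self) -> np.ndarray:
        """Per-bin probability mass (density times bin measure)."""
        widths = [np.diff(e) for e in self.edges]
        if len(widths) == 1:
            return self.density * widths[0]
        return self.density * np.outer(widths[0], widths[1])


@dataclass
class SpeckleStats:
    """Per-image intensity SNR and the scatterers-per-cell estimate."""

    snr: float
    snr2: float
    nhat: float      # NaN when snr2 >= 1 (estimator undefined)

    @property
    def defined(self) -> bool:
        return math.isfinite(self.nhat)


@dataclass
class GaussianFit:
    mu: float
    sigma: float
    mse: float       # mean squared error between empirical and fitted densities


@dataclass
class RadialProfile:
    lags: np.ndarray          # pixels
    values: np.ndarray        # autocorrelation, 1 at lag 0


def gray_level_pdf(ensemble, bins=64, value_range=None) -> EmpiricalPDF:
    """Density-normalized histogram of all pixels pooled over the ensemble."""
    images = ensemble.images if hasattr(ensemble, "images") else np.asarray(ensemble)
    if images.size == 0:
        raise ValueError("empty ensemble")
    density, edges = np.histogram(images.ravel(), bins=bins, range=value_range, density=True)
    return EmpiricalPDF((edges,), density, images.size)


def radial_autocorrelation(ensemble) -> RadialProfile:
    """Ensemble-averaged, radially averaged image autocorrelation.

    Each image is mean-subtracted and tapered with a 2-D Papoulis (Bohman)
    window before the spectral autocorrelation, which suppresses the boundary
    artifacts of the circular estimate; profiles are normalized to 1 at lag 0
    and averaged over integer-lag annuli.
    """
    images = ensemble.images if hasattr(ensemble, "images") else np.asarray(ensemble)
    n, h, w = images.shape
    window = np.outer(bohman(h), bohman(w))
    power = np.zeros((h, w))
    for img in images:
        x = (img - img.mean()) * window
        f = np.fft.fft2(x)
        power += (f * f.conj()).real
    acorr = np.fft.ifft2(power / n).real
    if acorr[0, 0] <= 0:
        raise ValueError("zero-variance ensemble: autocorrelation undefined")
    acorr /= acorr[0, 0]
    iy = np.minimum(np.arange(h), h - np.arange(h))
    ix = np.minimum(np.arange(w), w - np.arange(w))
    radius = np.hypot(iy[:, None], ix[None, :])
    max_lag = min(h, w) // 2
    ring = np.rint(radius).astype(int)
    keep = ring <= max_lag
    sums = np.bincount(ring[keep], weights=acorr[keep], minlength=max_lag + 1)
    counts = np.bincount(ring[keep], minlength=max_lag + 1)
    # lag coordinate = mean true radius in each annulus (ring k mixes radii
    # around k; the integer label would bias the profile inward)
    mean_radius = np.bincount(ring[keep], weights=radius[keep], minlength=max_lag + 1) / counts
    return RadialProfile(mean_radius, sums / counts)


def js_divergence_pmf(p: np.ndarray, q: np.ndarray) -> float:
    """JS divergence (natural log) between two probability mass vectors."""
    p = np.asarray(p, dtype=np.float64).ravel()
    q = np.asarray(q, dtype=np.float64).ravel()
    d = float(jensenshannon(p, q) ** 2)
    return min(max(d, 0.0), LN2)


def js_divergence(samples_p, samples_q, bins: int = 64) -> float:
    """Empirical JS divergence between two scalar samples.

    Histograms share equal-width bins over the pooled sample range; zero-count
    bins contribute nothing through the mixture. Result in [0, ln 2] nats.
    """
    samples_p = np.asarray(samples_p, dtype=np.float64).ravel()
    samples_q = np.asarray(samples_q, dtype=np.float64).ravel()
    samples_p = samples_p[np.isfinite(samples_p)]
    samples_q = samples_q[np.isfinite(samples_q)]
    if samples_p.size == 0 or samples_q.size == 0:
        raise ValueError("empty sample")
    lo = min(samples_p.min(), samples_q.min())
    hi = max(samples_p.max(), samples_q.max())
    if lo == hi:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    hp, _ = np.histogram(samples_p, bins=edges)
    hq, _ = np.histogram(samples_q, bins=edges)
    return js_divergence_pmf(hp / hp.sum(), hq / hq.sum())


def snr_and_nhat(intensity: np.ndarray) -> SpeckleStats:
    """SNR = mu_I / sigma_I of one intensity image and N-hat = SNR²/(1-SNR²).

    N-hat estimates the scatterers per resolution cell under a Poisson
    scatterer-number model; it is undefined (NaN) once SNR² >= 1, the fully
    developed regime where the estimator diverges.
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    mu = intensity.mean()
    sigma = intensity.std()
    if sigma == 0:
        raise ValueError("constant image: SNR undefined")
    snr = float(mu / sigma)
    snr2 = snr**2
    nhat = snr2 / (1.0 - snr2) if snr2 < 1.0 else math.nan
    return SpeckleStats(snr=snr, snr2=snr2, nhat=nhat)


def ensemble_snr2(images: np.ndarray) -> np.ndarray:
    """Per-image SNR² over a stack of *envelope* images (intensity = env²).

    Processes one image at a time so large ensembles need no intensity copy.
    """
    images = np.asarray(images)
    out = np.empty(images.shape[0], dtype=np.float64)
    for i, img in enumerate(images):
        intensity = img.astype(np.float64) ** 2
        mu = intensity.mean()
        sigma = intensity.std()
        if sigma == 0:
            raise ValueError("constant image in ensemble: SNR undefined")
        out[i] = (mu / sigma) ** 2
    return out


def fit_gaussian_pdf(samples, bins: int = 64) -> GaussianFit:
    """Least-squares fit of a Gaussian density to the binned empirical PDF.

    The fit is performed on density-normalized histogram values (not on the
    raw samples), initialized at the sample mean and standard deviation.
    """
    samples = np.asarray(samples, dtype=np.float64).ravel()
    samples = samples[np.isfinite(samples)]
    if samples.size < 30:
        raise ValueError("need at least 30 samples for a stable fit")
    m0, s0 = samples.mean(), samples.std()
    if s0 == 0:
        raise ValueError("degenerate samples: zero spread")
    density, edges = np.histogram(samples, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, mu, sigma):
        return np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) / (abs(sigma) * math.sqrt(2 * math.pi))

    popt, _ = curve_fit(gauss, centers, density, p0=(m0, s0), maxfev=10000)
    mu, sigma = float(popt[0]), float(abs(popt[1]))
    mse = float(np.mean((density - gauss(centers, mu, sigma)) ** 2))
    return GaussianFit(mu=mu, sigma=sigma, mse=mse)


def pca_feature_pdf(
    features_ref, features_cand, grid_bins: int = 24
) -> tuple[EmpiricalPDF, EmpiricalPDF, np.ndarray]:
    """Joint PDFs of both feature tables over the first two pooled principal axes.

    Features are standardized with pooled mean/std (symmetric in the two
    tables), the principal axes computed on the pooled standardized data, and
    both projections histogrammed on a shared 2-D grid. Returns the two PDFs
    and the explained-variance ratios of the two components.
    """
    ref = np.asarray(features_ref[FEATURE_NAMES], dtype=np.float64)
    cand = np.asarray(features_cand[FEATURE_NAMES], dtype=np.float64)
    pooled = np.vstack([ref, cand])
    if pooled.shape[0] < pooled.shape[1]:
        raise ValueError("fewer pooled rows than features")
    mean = pooled.mean(axis=0)
    std = pooled.std(axis=0)
    std[std == 0] = 1.0
    zref = (ref - mean) / std
    zcand = (cand - mean) / std
    pca = PCA(n_components=2)
    pca.fit(np.vstack([zref, zcand]))
    pref = pca.transform(zref)
    pcand = pca.transform(zcand)
    lo = np.minimum(pref.min(axis=0), pcand.min(axis=0))
    hi = np.maximum(pref.max(axis=0), pcand.max(axis=0))
    edges = [np.linspace(lo[k], hi[k], grid_bins + 1) for k in range(2)]
    href, _, _ = np.histogram2d(pref[:, 0], pref[:, 1], bins=edges, density=True)
    hcand, _, _ = np.histogram2d(pcand[:, 0], pcand[:, 1], bins=edges, density=True)
    return (
        EmpiricalPDF(tuple(edges), href, ref.shape[0]),
        EmpiricalPDF(tuple(edges), hcand, cand.shape[0]),
        pca.explained_variance_ratio_,
    )
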