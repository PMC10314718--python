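# Methods

This note records the models implemented in `simbench`, the conventions and
calibrations they rest on, and what the synthetic generators do and do not
emulate. Everything quantitative here is computed by the test suite or
`scripts/acceptance.py`; nothing is asserted that the code does not measure.

## Clustered lumpy background (CLB)

One texture layer is a doubly stochastic blob process:

    f(r) = Σ_k Σ_n b(r − r_k − d_kn ; θ_kn),
    b(u; θ) = exp(−α s^β),   s² = (u'/L_x)² + (v'/L_y)²,

with cluster centers `r_k` a homogeneous Poisson process, per-cluster blob
counts Poisson with mean λ̄, blob offsets `d_kn` isotropic Gaussians with
standard deviation σ_c, and `(u', v')` the offset rotated by the blob angle
θ. Isotropic variants draw θ uniformly on [0, π) per blob; oriented variants
draw one preferred direction per cluster and add Gaussian angular jitter
(default 0.25 rad) per blob. Double-layer configurations sum two independent
layers pixelwise *before* the gray mapping — the simplest composition
consistent with layering, and the one the layer-additivity test pins down.
The affine gray mapping (offset, scale, clip to [0, 255]) is part of each
configuration; shipped scales place the ensemble 99.9th percentile near 250.

Conventions and parameters:

- **Border extension.** Cluster centers are sampled on a field extended
  beyond the image by 3·max(L_x, L_y) + 3·σ_c, so clusters centered outside
  the image still deposit blob mass near the border. The extension includes
  the cluster-spread term (not only the blob length) because blob centers
  scatter σ_c away from their cluster; without it, border statistics would
  be visibly nonstationary. A 1000-image left/right-half comparison in the
  test suite bounds residual asymmetry below 1 % of the mean.
- **Parameter tables.** The `opex99` configuration uses the classical
  parameterization of the original model (K̄ = 150 clusters per 256² field,
  λ̄ = 20 blobs, σ_c = 12 px, L_x = 5, L_y = 2, α = 2.1, β = 0.5). The four
  single/double × isotropic/oriented variants are shipped as editable
  defaults chosen to look like their descriptions (a coarse structural layer
  plus a fine texture layer for the double variants) with compact blob
  support; they are placeholders validated by the model's invariants
  (determinism, additivity, stationarity, Poisson cluster statistics), not
  reproductions of any published table. All five live in flat key/value
  config files under `simbench/configs/` and are data, not code.
- **Rendering.** Blob profiles are evaluated from a 4096-entry lookup table
  in s² (linear interpolation, error < 1e−5 of the peak) inside a
  numba-compiled kernel, truncated where the profile falls below 1e−3 of its
  peak. Brute-force oracle tests at tiny sizes pin the rendering math.

## Ultrasound speckle (USS)

The complex field is a filtered random phasor sum: scatterers form a Poisson
point process in the image plane, each carrying unit amplitude and an
independent phase uniform on [0, 2π); the scatterer map is convolved
(spectrally, with periodic wrap — the PSF is far smaller than the image and
is truncated at ±4σ) with a complex PSF whose Gaussian envelope is set by
the axial and lateral resolutions and which is modulated axially by the
pulse-echo carrier. The envelope |E| is the B-mode image; intensity is
|E|². For a Poisson scatterer number with mean N per coherence cell the
intensity satisfies SNR² = N/(1+N), so N̂ = SNR²/(1−SNR²) estimates N.

Default physics: v = 1556 m/s, f_c = 3.5 MHz, N_c = 2, f-numbers 2 (y) and
3 (z), 100 µm pixels, 256×256 images, propagation along the image x-axis.
Derived quantities: λ = v/f_c = 0.4446 mm, AR = N_c λ/2, LR = λ·f-number.

**Width and density conventions (calibrated).** AR and LR do not uniquely
fix a 2-D simulator: the mapping from AR/LR to the Gaussian σ (FWHM vs σ),
and how a volumetric density (mm⁻³) collapses onto the 2-D plane, are
conventions. The package adopts σ = FWHM/2.355 with FWHM_x = AR and
FWHM_y = LR_y, and fixes the density mapping operationally as

    N_eff = CELL_EFFICIENCY · V_cell · (snd + DIFFUSE_SND),
    CELL_EFFICIENCY = 0.514,  DIFFUSE_SND = 1.61 mm⁻³,

where V_cell = AR·LR_y·LR_z is the textbook resolution-cell volume and
N_eff is the expected scatterer count per 2-D coherence cell (area
2π σ_x σ_y), which sets the areal scatterer density. The two constants were
fitted once, by weighted least squares against the published per-image SNR²
operating curve of this exact configuration across SND ∈ {1, 2, 3, 30}
(Gaussian-fit means and N̂), and then frozen. `DIFFUSE_SND` plays the role
of an always-present diffuse background scatter (any insonified medium
contributes sub-resolution scatter beyond the nominal point targets);
`CELL_EFFICIENCY` absorbs the elevational collapse. Both live in one
function (`effective_scatterers_per_cell`) so the convention can be swapped.
A medium with snd = 0 is treated as having no scatterers at all and yields
a zero field.

**Raw vs 8-bit statistics.** The top-1 % 8-bit conversion
(`quantize_ensemble_8bit`: 255 ↦ pooled 99th percentile, ~1 % of pixels
saturate) is provided for exporting training-style images. Speckle SNR²/N̂
statistics are computed on *raw* (pre-quantization) intensity: measured on
this simulator, saturation biases per-image SNR² upward by +0.03 to +0.07
in an SND-dependent way (clipping the intensity tail reduces σ_I more than
μ_I), pushing the fully developed value above 1 and making the known
operating curve unreachable; the raw convention reproduces it. This is the
package's fixed convention and the acceptance pipeline states it.

**Known limitation — N̂ at fully developed speckle.** As SNR² → 1 the
estimator N̂ diverges; with the per-image sampling spread at SND-30
(σ ≈ 0.04 around a mean ≈ 0.90), a few images per thousand land near
SNR² = 1 and dominate the ensemble mean, which is therefore large (≈ 11–17)
and volatile. No averaging convention defined on per-image N̂ values gives a
stable small number here — the estimator is simply outside its validity
range (it is accurate for SND 1–3, as the acceptance checks verify to
within 10 %). The fully-developed-limit tests use SNR² itself, which is
well behaved.

## Stylized breast slice (S2V)

A slice is a 2-D map of ten tissue labels; assigning each label its linear
attenuation coefficient at 30 keV (editable two-column CSV; defaults from
standard tissue-property ranges, with fat 0.227 cm⁻¹ and glandular
0.334 cm⁻¹ — separated far beyond the ±1.5 % thresholding tolerance, which
the table validator enforces) turns it into an attenuation image. The
pertinent statistic is ρ_F:G = F/G with F and G the pixel counts within
±1.5 % (relative) of the fat and glandular coefficients.

Slice extraction from a labeled 3-D stack selects plane indices from
⌈0.40·depth⌉ through ⌊0.70·depth⌋ in steps of 50, then resamples each plane
to the output size with nearest-neighbour interpolation. Labels are
downsampled *before* coefficient assignment so no partial-volume pseudo-
tissues appear; this ordering is the package's choice where the alternative
(assign, then average) would create values belonging to no tissue.

**Surrogate phantom.** The anthropomorphic 3-D phantom tool whose slices
the pipeline would normally consume is external; a surrogate 2-D generator
stands in for it. It builds a mildly elliptical breast mask with a skin rim,
draws a target log ρ_F:G from a four-mode Gaussian mixture (default
prevalences 0.10/0.40/0.40/0.10, mode centers 2.2/1.1/0.1/−0.8 in log
units, σ = 0.15 — spanning almost-entirely-fatty to extremely dense), and
splits the interior into glandular and fat by thresholding a
center-weighted smoothed Gaussian random field at the rank that realizes
the target ratio exactly; thin vessel/ligament tracks optionally overwrite
a small pixel fraction. The surrogate preserves the statistic under test —
a controllable per-image F:G ratio with a four-mode population structure —
and makes no claim to anatomic realism: glandular geometry, ductal
structure, and 3-D continuity are not emulated, so passing tests speak to
the ratio pipeline, not to anatomy.

## Texture features

Matrix features operate on a uniform quantization of each image's value
range into `n_gray_levels` labels (default 16). Defaults: GLCM distances
{1}, angles {0°, 45°, 90°, 135°}, symmetrized, normalized, averaged over
offsets and angles (making the set invariant under 90° rotations); GLRM
runs pooled over the four directions with the canonical run-length
features; NGTDM window radius 1 with the canonical coarseness / contrast /
complexity / strength definitions, ε = 1e−6 stabilizing coarseness (a
constant image yields 1/ε). Entropy uses natural logarithms. Degenerate
inputs produce defined limits where they exist (constant image: energy 1,
contrast 0) and flagged NaNs where they do not (skewness of a constant
image) — never silent zeros. The specific parameter values are deliberately
config-exposed: published texture studies vary in these choices, and the
oracle tests pin down *this* implementation's definitions.

## Ensemble statistics and comparisons

- **JS divergence** between two scalar samples uses shared equal-width bins
  over the pooled range (default 64), natural logarithm, so values lie in
  [0, ln 2]; zero-count bins contribute nothing through the mixture.
  Binning is a knob because no canonical choice exists; floors are always
  computed with the same binning as the comparison they accompany.
- **Radial autocorrelation**: per image, mean-subtract, taper with a 2-D
  Papoulis (Bohman) window to suppress the circular estimator's boundary
  artifacts, average the periodograms, normalize lag 0 to 1, and average
  over integer-radius annuli. The lag coordinate of each annulus is the
  mean true radius within it (the integer label would bias the profile
  inward by mixing e.g. lags 1 and √2 in ring 1). The scalar discrepancy
  reported by the harness is the maximum absolute profile difference — a
  summary the package adds, since curve overlays have no canonical scalar.
- **Gaussian fit** of an empirical PDF is least squares of a two-parameter
  Gaussian density against the density-normalized histogram (64 bins),
  initialized at the sample mean/std; the reported MSE is against the same
  binned densities.
- **PCA feature PDFs** standardize each feature by pooled (reference +
  candidate) mean/std — symmetric in the two ensembles — compute principal
  axes on the pooled data, and histogram both projections on a shared 2-D
  grid (default 24 bins/axis). Known limitation: a defect confined to one
  feature is diluted by ~1/√17 in any 2-component projection and can sit
  below the finite-sample floor; coherent multi-feature shifts (what real
  mode defects look like) are what this screen detects. The per-feature JS
  divergences are the sharper instrument for single-feature defects.
- **Aggregate feature divergence** is the mean of the 17 per-feature JS
  values (configurable to max); the aggregation is a package choice.
- **Noise floors**: every harness metric is paired with the same metric
  computed between two independent draws of the reference model with
  different seeds (identical seeds are rejected — the floor would be a
  degenerate 0). Floors decrease with ensemble size; comparisons should
  always quote them.

## Determinism and problem sizes

Every sampler is a pure function of (config, seed): per-image seeds derive
from the master seed via `SeedSequence(entropy=seed, spawn_key=(index,))`,
documented and stable. The test suite runs the headline checks at the sizes
a desk machine handles comfortably: the speckle operating table at 2000
images per density, harness detection at n = 2000 (CLB and USS) and
n = 1000 (surrogate slices at 96²), with ensembles stored as float32 and
per-image statistics streamed. Default evaluation size for the harness is
ensemble-limited only by memory; detection margins in the tests (e.g.
run-length short-primitive emphasis and NGTDM strength at ≥ 5× floor for a
half-degraded mixture) grow with n.
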