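"""Ensemble statistics: PDFs, autocorrelation, JS divergence, SNR², fits, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from simbench.stats import (
    LN2,
    ensemble_snr2,
    fit_gaussian_pdf,
    gray_level_pdf,
    js_divergence,
    js_divergence_pmf,
    pca_feature_pdf,
    radial_autocorrelation,
    snr_and_nhat,
)
from simbench.texture import FEATURE_NAMES


class TestGrayLevelPDF:
    def test_constant_image_single_occupied_bin(self):
        pdf = gray_level_pdf(np.full((1, 8, 8), 5.0), bins=10, value_range=(0, 10))
        assert np.count_nonzero(pdf.density) == 1
        assert pdf.mass.sum() == pytest.approx(1.0)

    def test_density_integrates_to_one(self, rng):
        pdf = gray_level_pdf(rng.random((5, 16, 16)), bins=32)
        assert np.sum(pdf.density * np.diff(pdf.edges[0])) == pytest.approx(1.0)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            gray_level_pdf(np.empty((0, 4, 4)))


class TestRadialAutocorrelation:
    def test_white_noise_is_delta_at_lag_zero(self, rng):
        profile = radial_autocorrelation(rng.standard_normal((200, 32, 32)))
        assert profile.values[0] == pytest.approx(1.0)
        assert np.all(np.abs(profile.values[1:]) < 0.05)

    def test_blur_widens_profile_as_predicted(self, rng):
        """Gaussian-blurred noise: autocorrelation should be Gaussian with sigma*sqrt(2)."""
        from scipy.ndimage import gaussian_filter

        for sigma in (1.0, 2.0):
            imgs = np.stack(
                [gaussian_filter(rng.standard_normal((64, 64)), sigma, mode="wrap") for _ in range(150)]
            )
            profile = radial_autocorrelation(imgs)
            # half-maximum lag of exp(-r^2/(4 sigma^2)) is 2 sigma sqrt(ln 2)
            predicted = 2.0 * sigma * np.sqrt(np.log(2.0))
            crossing = np.interp(0.5, profile.values[::-1], profile.lags[::-1])
            assert crossing == pytest.approx(predicted, rel=0.10)

    def test_constant_ensemble_rejected(self):
        with pytest.raises(ValueError):
            radial_autocorrelation(np.ones((4, 16, 16)))


class TestJSDivergence:
    def test_identical_samples_give_zero(self, rng):
        x = rng.random(500)
        assert js_divergence(x, x) == 0.0

    def test_disjoint_supports_give_ln2(self, rng):
        assert js_divergence(rng.random(500), rng.random(500) + 10) == pytest.approx(LN2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            js_divergence([], [1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=60),
        st.lists(st.floats(-5, 5), min_size=2, max_size=60),
    )
    def test_symmetry_and_bounds(self, xs, ys):
        d_ab = js_divergence(xs, ys)
        d_ba = js_divergence(ys, xs)
        assert d_ab == pytest.approx(d_ba, abs=1e-12)
        assert 0.0 <= d_ab <= LN2 + 1e-12

    def test_same_simulator_draws_sit_at_noise_floor(self, rng):
        a = rng.normal(size=2000)
        b = rng.normal(size=2000)
        c = rng.normal(size=2000)
        floor = js_divergence(b, c)
        assert js_divergence(a, b) < 3 * floor + 0.01


class TestSNRandNhat:
    @staticmethod
    def image_with_snr2(snr2):
        # half pixels at mu-sigma, half at mu+sigma with mu = sigma*sqrt(snr2)
        sigma = 1.0
        mu = np.sqrt(snr2) * sigma
        return np.array([[mu - sigma, mu + sigma] * 8] * 4)

    def test_snr2_half_gives_nhat_one(self):
        stats = snr_and_nhat(self.image_with_snr2(0.5))
        assert stats.snr2 == pytest.approx(0.5)
        assert stats.nhat == pytest.approx(1.0)

    def test_snr2_0888_gives_nhat_793(self):
        stats = snr_and_nhat(self.image_with_snr2(0.888))
        assert stats.nhat == pytest.approx(0.888 / 0.112, rel=1e-12)

    def test_matches_two_pass_oracle(self, rng):
        img = rng.random((16, 16))
        stats = snr_and_nhat(img)
        mu = sum(img.ravel()) / img.size
        var = sum((v - mu) ** 2 for v in img.ravel()) / img.size
        assert stats.snr == pytest.approx(mu / np.sqrt(var), rel=1e-12)

    def test_saturated_snr2_flagged_undefined(self):
        stats = snr_and_nhat(self.image_with_snr2(1.5))
        assert not stats.defined and np.isnan(stats.nhat)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            snr_and_nhat(np.ones((4, 4)))

    def test_nhat_round_trip_and_monotonicity(self):
        snr2 = np.linspace(0.05, 0.95, 50)
        nhat = snr2 / (1 - snr2)
        assert np.all(np.diff(nhat) > 0)
        np.testing.assert_allclose(nhat / (1 + nhat), snr2, rtol=1e-12)

    def test_ensemble_snr2_matches_per_image(self, rng):
        envs = rng.random((5, 12, 12)) + 0.1
        batch = ensemble_snr2(envs)
        singles = [snr_and_nhat(img**2).snr2 for img in envs]
        np.testing.assert_allclose(batch, singles, rtol=1e-12)


class TestGaussianFit:
    def test_exact_gaussian_density_recovered(self):
        mu, sigma = 2.0, 0.5
        x = np.linspace(0, 4, 5000)
        rng = np.random.default_rng(1)
        samples = rng.normal(mu, sigma, 40000)
        fit = fit_gaussian_pdf(samples, bins=60)
        assert fit.mu == pytest.approx(mu, abs=3 * sigma / np.sqrt(40000) + 0.01)
        assert fit.sigma == pytest.approx(sigma, rel=0.05)
        assert fit.mse < 0.005

    def test_parameter_recovery_within_sampling_error(self, rng):
        samples = rng.normal(-1.0, 2.0, 10000)
        fit = fit_gaussian_pdf(samples)
        assert abs(fit.mu - samples.mean()) < 3 * 2.0 / np.sqrt(10000) + 0.05

    def test_too_few_or_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_pdf(np.arange(10))
        with pytest.raises(ValueError):
            fit_gaussian_pdf(np.ones(100))


class TestPCAFeaturePDF:
    @staticmethod
    def random_table(rng, n=80, scale=None):
        data = rng.standard_normal((n, len(FEATURE_NAMES)))
        if scale is not None:
            data *= scale
        return pd.DataFrame(data, columns=FEATURE_NAMES)

    def test_identical_tables_give_identical_pdfs_and_zero_js(self, rng):
        t = self.random_table(rng)
        pref, pcand, evr = pca_feature_pdf(t, t.copy())
        np.testing.assert_array_equal(pref.density, pcand.density)
        assert js_divergence_pmf(pref.mass, pcand.mass) == 0.0
        assert evr[0] >= evr[1]

    @staticmethod
    def correlated_table(rng, n):
        """Low-rank feature table: two latent factors drive all 17 features."""
        latent = rng.standard_normal((n, 2))
        loadings = np.random.default_rng(0).standard_normal((2, len(FEATURE_NAMES)))
        data = latent @ loadings + 0.1 * rng.standard_normal((n, len(FEATURE_NAMES)))
        return pd.DataFrame(data, columns=FEATURE_NAMES)

    def test_coherent_shift_displaces_mode(self, rng):
        """A mode displaced along the latent feature structure is detected.

        A 2-component projection dilutes a shift of any single feature by
        ~1/sqrt(17); a defect that moves correlated features coherently (as a
        real mode shift does) displaces the joint PDF well above the floor.
        """
        n, bins = 600, 10
        loadings = np.random.default_rng(0).standard_normal((2, len(FEATURE_NAMES)))
        t = self.correlated_table(rng, n)
        shifted = t + 3.0 * loadings[0]  # displace along the first latent axis
        pref, pcand, _ = pca_feature_pdf(t, shifted, grid_bins=bins)
        floor_ref, floor_cand, _ = pca_feature_pdf(
            self.correlated_table(rng, n), self.correlated_table(rng, n), grid_bins=bins
        )
        floor = js_divergence_pmf(floor_ref.mass, floor_cand.mass)
        assert js_divergence_pmf(pref.mass, pcand.mass) > 5 * floor

    def test_affine_feature_rescaling_is_invariant(self, rng):
        t = self.random_table(rng, n=200)
        scaled = t.copy()
        scaled["mean"] = scaled["mean"] * 100.0
        t2 = t.copy()
        t2["mean"] = t2["mean"] * 100.0
        a_ref, a_cand, _ = pca_feature_pdf(t, t.copy())
        b_ref, b_cand, _ = pca_feature_pdf(t2, scaled)
        np.testing.assert_allclose(a_ref.density, b_ref.density, atol=1e-10)

    def test_insufficient_rows_rejected(self, rng):
        t = self.random_table(rng, n=5)
        with pytest.raises(ValueError):
            pca_feature_pdf(t, t)
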