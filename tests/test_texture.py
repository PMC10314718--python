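"""Texture-feature correctness against brute-force enumeration oracles."""

import numpy as np
import pytest

from simbench.texture import (
    FEATURE_NAMES,
    TextureConfig,
    first_order_features,
    glcm,
    glcm_features,
    glrm,
    glrm_features,
    ngtdm,
    ngtdm_features,
    quantize_gray_levels,
    texture_feature_vector,
)

import oracles


def random_label_image(rng, max_side=6, max_levels=4):
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    levels = int(rng.integers(2, max_levels + 1))
    return rng.integers(1, levels + 1, size=(h, w)).astype(np.int64), levels


class TestQuantize:
    def test_constant_image_maps_to_single_label(self):
        q = quantize_gray_levels(np.full((4, 4), 3.7), 8)
        assert np.all(q == 1)

    def test_linear_ramp_fills_levels_equally(self):
        img = np.repeat(np.arange(8.0)[None, :], 4, axis=0)
        q = quantize_gray_levels(img, 8)
        _, counts = np.unique(q, return_counts=True)
        assert np.all(counts == 4)
        assert q.min() == 1 and q.max() == 8

    def test_idempotent_up_to_relabeling(self, rng):
        for _ in range(50):
            img = rng.random((5, 5)) * rng.uniform(1, 100)
            n = int(rng.integers(2, 6))
            q1 = quantize_gray_levels(img, n)
            q2 = quantize_gray_levels(q1.astype(float), n)
            # requantizing must preserve the level partition (bijective relabel)
            for lvl in np.unique(q1):
                assert len(np.unique(q2[q1 == lvl])) == 1
            for lvl in np.unique(q2):
                assert len(np.unique(q1[q2 == lvl])) == 1


class TestFirstOrder:
    def test_two_value_image_population_convention(self):
        mean, std, _, _ = first_order_features(np.array([0.0, 0.0, 255.0, 255.0]))
        assert mean == pytest.approx(127.5)
        assert std == pytest.approx(127.5)

    def test_symmetric_distribution_has_zero_skewness(self, rng):
        x = rng.normal(size=4000)
        x = np.concatenate([x, -x]).reshape(80, 100)
        _, _, skew, _ = first_order_features(x)
        assert abs(skew) < 1e-12

    def test_constant_image_flags_undefined_moments(self):
        mean, std, skew, kurt = first_order_features(np.ones((3, 3)))
        assert std == 0.0 and np.isnan(skew) and np.isnan(kurt)

    def test_matches_direct_summation(self, rng):
        img = rng.random((5, 5))
        got = first_order_features(img)
        want = oracles.first_order_oracle(img)
        assert got == pytest.approx(want, rel=1e-12)


class TestMatrixBuildersAgainstOracles:
    """Property check: every builder equals brute-force enumeration on small images."""

    N_CASES = 200

    def test_glcm_matches_pair_enumeration(self, rng):
        cfg0 = TextureConfig()
        for _ in range(self.N_CASES):
            img, levels = random_label_image(rng)
            cfg = TextureConfig(
                n_gray_levels=levels,
                glcm_distances=cfg0.glcm_distances,
                glcm_angles=cfg0.glcm_angles,
            )
            got = glcm(img, cfg)
            want = oracles.glcm_oracle(img, cfg.glcm_distances, cfg.glcm_angles, levels)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_glrm_matches_run_enumeration(self, rng):
        for _ in range(self.N_CASES):
            img, levels = random_label_image(rng)
            cfg = TextureConfig(n_gray_levels=levels)
            r, n_runs = glrm(img, cfg)
            r_o, n_o = oracles.glrm_oracle(img, cfg.glrm_directions, levels)
            assert n_runs == n_o
            np.testing.assert_array_equal(r[:, : r_o.shape[1]], r_o)
            assert np.all(r[:, r_o.shape[1]:] == 0)

    def test_ngtdm_matches_sliding_window(self, rng):
        for _ in range(self.N_CASES):
            img, levels = random_label_image(rng, max_side=6)
            if min(img.shape) < 3:
                continue
            cfg = TextureConfig(n_gray_levels=levels)
            p, s = ngtdm(img, cfg)
            p_o, s_o, _ = oracles.ngtdm_oracle(img, cfg.ngtdm_neighborhood, levels)
            np.testing.assert_allclose(p, p_o, atol=1e-12)
            np.testing.assert_allclose(s, s_o, atol=1e-10)

    def test_features_match_direct_formulas(self, rng):
        for _ in range(self.N_CASES // 4):
            img, levels = random_label_image(rng, max_side=6)
            if min(img.shape) < 3:
                continue
            cfg = TextureConfig(n_gray_levels=levels)
            P = glcm(img, cfg)
            np.testing.assert_allclose(
                glcm_features(P), oracles.glcm_features_oracle(P), rtol=1e-10
            )
            r, n_runs = glrm(img, cfg)
            np.testing.assert_allclose(
                glrm_features(r, n_runs), oracles.glrm_features_oracle(r, n_runs), rtol=1e-10
            )
            p, s = ngtdm(img, cfg)
            n_int = (img.shape[0] - 2) * (img.shape[1] - 2)
            np.testing.assert_allclose(
                ngtdm_features(p, s, cfg, n_pixels=n_int),
                oracles.ngtdm_features_oracle(p, s, n_int, cfg.epsilon),
                rtol=1e-10,
            )


class TestDegenerateAndClosedForm:
    def test_constant_image_glcm_is_diagonal_delta(self):
        cfg = TextureConfig(n_gray_levels=4)
        P = glcm(np.ones((5, 5), dtype=np.int64), cfg)
        energy, entropy, maximum, contrast, homogeneity = glcm_features(P)
        assert P[0, 0] == pytest.approx(1.0)
        assert (energy, entropy, maximum, contrast, homogeneity) == pytest.approx((1, 0, 1, 0, 1))

    def test_checkerboard_glcm_mass_off_diagonal(self):
        img = np.array([[1, 2], [2, 1]], dtype=np.int64)
        cfg = TextureConfig(n_gray_levels=2, glcm_angles=(0.0,))
        P = glcm(img, cfg)
        assert P[0, 0] == 0 and P[1, 1] == 0
        assert P[0, 1] == pytest.approx(0.5) and P[1, 0] == pytest.approx(0.5)

    def test_uniform_glcm_closed_form(self):
        k = 4
        P = np.full((k, k), 1.0 / k**2)
        energy, entropy, *_ = glcm_features(P)
        assert energy == pytest.approx(1.0 / k**2)
        assert entropy == pytest.approx(np.log(k**2))

    def test_single_run_emphases(self):
        cfg = TextureConfig(n_gray_levels=2, glrm_directions=("0",))
        r, n = glrm(np.full((1, 8), 2, dtype=np.int64), cfg)
        assert n == 1 and r[1, 7] == 1
        spe, lpe, _, _ = glrm_features(r, n)
        assert spe == pytest.approx(1 / 64) and lpe == pytest.approx(64)

    def test_alternating_row_all_unit_runs(self):
        cfg = TextureConfig(n_gray_levels=2, glrm_directions=("0",))
        r, n = glrm(np.array([[1, 2, 1, 2, 1, 2, 1, 2]], dtype=np.int64), cfg)
        assert n == 8
        spe, lpe, _, _ = glrm_features(r, n)
        assert spe == 1.0 and lpe == 1.0

    def test_constant_image_ngtdm_limits(self):
        cfg = TextureConfig(n_gray_levels=4)
        p, s = ngtdm(np.ones((5, 5), dtype=np.int64), cfg)
        assert np.all(s == 0)
        coarseness, contrast, complexity, strength = ngtdm_features(p, s, cfg, n_pixels=9)
        assert coarseness == pytest.approx(1.0 / cfg.epsilon)
        assert contrast == 0.0 and strength == 0.0

    def test_unnormalized_inputs_rejected(self):
        cfg = TextureConfig()
        with pytest.raises(ValueError):
            glcm_features(np.ones((3, 3)))
        with pytest.raises(ValueError):
            ngtdm_features(np.array([0.5, 0.2]), np.zeros(2), cfg)
        with pytest.raises(ValueError):
            glrm_features(np.zeros((2, 2)), 0)


class TestFeatureVector:
    def test_has_exactly_17_named_finite_values(self, rng):
        img = rng.random((16, 16)) * 255
        vec = texture_feature_vector(img)
        assert len(FEATURE_NAMES) == 17
        arr = vec.as_array()
        assert arr.shape == (17,)
        assert np.all(np.isfinite(arr))
        assert vec.flags == []

    def test_deterministic_on_identical_images(self, rng):
        img = rng.random((16, 16))
        np.testing.assert_array_equal(
            texture_feature_vector(img).as_array(), texture_feature_vector(img.copy()).as_array()
        )

    def test_rotation_by_90_degrees_leaves_features_invariant(self, rng):
        img = rng.random((12, 12))
        a = texture_feature_vector(img).as_array()
        b = texture_feature_vector(np.rot90(img)).as_array()
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_constant_image_flags_undefined_never_poisons(self):
        vec = texture_feature_vector(np.full((8, 8), 7.0))
        assert "skewness" in vec.flags and "kurtosis" in vec.flags
        assert vec.glcm_energy == pytest.approx(1.0)
        assert vec.ngtdm_contrast == 0.0
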