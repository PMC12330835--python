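import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbench.glm import (
    CollinearityError,
    SummaryGLM,
    bootstrap_noise_cov,
    effect_size,
    fit_glm,
)


class TestFitGLM:
    def test_intercept_only_gives_column_means(self):
        rng = np.random.default_rng(0)
        Y = rng.uniform(0, 1, (200, 4))
        res = fit_glm(Y)
        assert np.allclose(res.beta_mean, Y.mean(axis=0), atol=1e-12)
        assert res.beta.shape == (0, 4)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 3))
    @settings(deadline=None, max_examples=20)
    def test_exact_recovery_noise_free(self, seed, q):
        rng = np.random.default_rng(seed)
        n, m = 50, 4
        X = rng.uniform(0, 1, (n, q))
        beta = rng.standard_normal((q + 1, m))
        design = np.column_stack([np.ones(n), X - X.mean(axis=0)])
        Y = design @ beta
        res = fit_glm(Y, X)
        assert np.allclose(res.beta_mean, beta[0], atol=1e-9)
        assert np.allclose(res.beta, beta[1:], atol=1e-9)

    def test_beta_mean_is_voxel_average(self):
        # demeaned covariates make the intercept row the mean summary vector
        rng = np.random.default_rng(1)
        Y = rng.uniform(0, 1, (500, 4))
        X = rng.uniform(0, 10, (500, 2))
        res = fit_glm(Y, X)
        assert np.allclose(res.beta_mean, Y.mean(axis=0), atol=1e-9)

    def test_duplicated_covariate_raises_naming_offender(self):
        import pandas as pd

        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 100)
        X = pd.DataFrame({"saf": x, "saf_copy": x})
        with pytest.raises(CollinearityError, match="saf"):
            fit_glm(rng.uniform(0, 1, (100, 4)), X)

    def test_needs_more_voxels_than_covariates(self):
        with pytest.raises(ValueError):
            fit_glm(np.ones((3, 4)), np.ones((3, 2)))


class TestEffectSize:
    def test_constant_covariate_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert effect_size(np.ones(2000)) == 0.0

    def test_even_grid_percentile_span(self):
        x = np.linspace(0, 1, 100_001)
        assert effect_size(x) == pytest.approx(0.998, abs=1e-9)

    def test_range_mode(self):
        # the simulated-data convention: raw covariate range, no percentiles
        assert effect_size(np.array([4, 48, 88, 168.0]), mode="range") == 164.0

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            effect_size(np.arange(100.0))


class TestBootstrap:
    def test_exact_linear_data_gives_zero_covariance(self):
        rng = np.random.default_rng(3)
        n = 400
        X = rng.uniform(0, 1, (n, 1))
        Y = np.column_stack([np.ones(n), X - X.mean()]) @ rng.standard_normal((2, 4))
        sigma = bootstrap_noise_cov(Y, X, n_iter=200, subsample_size=n, rng_seed=0)
        assert np.abs(sigma).max() < 1e-18

    def test_symmetric_psd_and_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, (300, 2))
        Y = rng.uniform(0, 1, (300, 4))
        a = bootstrap_noise_cov(Y, X, n_iter=150, subsample_size=100, rng_seed=9)
        b = bootstrap_noise_cov(Y, X, n_iter=150, subsample_size=100, rng_seed=9)
        assert np.array_equal(a, b)
        assert a.shape == (2, 4, 4)
        assert np.allclose(a, np.swapaxes(a, 1, 2))
        assert np.linalg.eigvalsh(a).min() >= -1e-15

    def test_subsample_too_small(self):
        with pytest.raises(ValueError):
            bootstrap_noise_cov(np.ones((50, 4)), np.ones((50, 2)),
                                n_iter=10, subsample_size=3)

    def test_subsample_cannot_exceed_n(self):
        with pytest.raises(ValueError):
            bootstrap_noise_cov(np.ones((50, 4)), np.ones((50, 1)),
                                n_iter=10, subsample_size=60)


class TestSummaryGLMEstimator:
    def test_fit_populates_attributes(self):
        import pandas as pd

        rng = np.random.default_rng(5)
        X = pd.DataFrame({"saf": rng.uniform(0, 1, 1500),
                          "odi": rng.uniform(0, 1, 1500)})
        Y = rng.uniform(0, 1, (1500, 4))
        est = SummaryGLM(n_boot=100, subsample_size=500, rng_seed=1).fit(X, Y)
        assert est.beta_mean_.shape == (4,)
        assert est.beta_.shape == (2, 4)
        assert est.delta_.shape == (2,)
        assert est.sigma_.shape == (2, 4, 4)
        assert est.covariate_names_ == ["saf", "odi"]

    def test_orthogonal_covariates_match_single_fits(self):
        """With orthogonal covariates the joint fit's beta_l equals each
        single-covariate fit's beta_l (the single- vs all-regressor
        contrast only matters when covariates are correlated)."""
        rng = np.random.default_rng(6)
        n = 512
        a = np.tile([1.0, -1.0], n // 2)
        b = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        X = np.column_stack([a, b])  # exactly orthogonal, zero-mean
        Y = rng.uniform(0, 1, (n, 4))
        joint = fit_glm(Y, X)
        single_a = fit_glm(Y, X[:, :1])
        single_b = fit_glm(Y, X[:, 1:])
        assert np.allclose(joint.beta[0], single_a.beta[0], atol=1e-9)
        assert np.allclose(joint.beta[1], single_b.beta[0], atol=1e-9)
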