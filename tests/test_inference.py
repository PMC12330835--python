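import numpy as np
import pytest
from scipy.stats import multivariate_normal

from cbench.changes import ChangeModel, ChangeModelRegressor, ChangeSpec
from cbench.inference import (
    MeasuredChange,
    change_likelihood,
    chi2_pattern_distance,
    log_marginal_likelihood,
    marginal_likelihood,
    posterior,
)


def _toy_model(mu, sigma_scale=0.0, name="toy", mag_range=(0.01, 0.1), seed=0):
    """A ChangeModel whose regressor predicts a fixed mu (and a residual
    covariance of scale sigma_scale) regardless of baseline."""
    rng = np.random.default_rng(seed)
    m = len(mu)
    S = rng.uniform(0, 1, (400, m))
    noise = sigma_scale * rng.standard_normal((400, m))
    dS = np.tile(mu, (400, 1)) + noise
    reg = ChangeModelRegressor(mean_degree=1, cov_degree=0).fit(S, dS)
    return ChangeModel(
        spec=ChangeSpec(name=name, signs={"ODI": 1.0}),
        regressor=reg, magnitude_range=mag_range,
    )


@pytest.fixture
def measured():
    rng = np.random.default_rng(1)
    A = rng.standard_normal((4, 4))
    return MeasuredChange(
        y=rng.uniform(0.1, 0.5, 4),
        delta_y=0.05 * rng.standard_normal(4),
        sigma=0.002 * (A @ A.T + 4 * np.eye(4)),
        name="x",
    )


class TestLikelihood:
    def test_matches_independent_mvn_density(self, measured):
        """Hand-rolled Cholesky log-density vs scipy's multivariate normal
        on random inputs, to 1e-12 relative."""
        model = _toy_model(np.array([0.2, -0.1, 0.15, -0.05]), 0.05)
        for s in (0.01, 0.05, 0.1):
            mu = model.predict_mu(measured.y[None])[0]
            cov = s**2 * model.predict_sigma(measured.y[None])[0] + measured.sigma
            # the implementation adds its documented 1e-10 mean-diagonal
            # ridge before inversion; give the oracle the same matrix
            cov = cov + 1e-10 * np.trace(cov) / 4 * np.eye(4)
            ours = change_likelihood(measured, model, s)
            ref = multivariate_normal.pdf(measured.delta_y, mean=s * mu, cov=cov)
            assert ours == pytest.approx(ref, rel=1e-12)

    def test_zero_magnitude_reduces_to_noise_density(self, measured):
        model = _toy_model(np.array([0.2, -0.1, 0.15, -0.05]), 0.05)
        ours = change_likelihood(measured, model, 0.0)
        ref = multivariate_normal.pdf(measured.delta_y, mean=np.zeros(4),
                                      cov=measured.sigma)
        assert ours == pytest.approx(ref, rel=1e-8)

    def test_maximised_when_prediction_exact(self):
        mu = np.array([0.3, -0.2, 0.25, -0.1])
        model = _toy_model(mu, 0.0)
        s = 0.05
        mc = MeasuredChange(y=np.full(4, 0.3), delta_y=s * mu,
                            sigma=1e-8 * np.eye(4))
        peak = change_likelihood(mc, model, s)
        for other in (0.4, 0.6, 1.5, 3.0):
            mc2 = MeasuredChange(y=np.full(4, 0.3), delta_y=s * mu * other,
                                 sigma=1e-8 * np.eye(4))
            assert change_likelihood(mc2, model, s) < peak


class TestMarginal:
    def test_constant_likelihood_gives_width_times_density(self, measured):
        # mu == 0 and residual scale 0: the density does not depend on the
        # magnitude, so the integral is the prior width times the density
        model = _toy_model(np.zeros(4), 0.0)
        marg = marginal_likelihood(measured, model, magnitude_prior=(0.02, 0.12))
        const = change_likelihood(measured, model, 0.07)
        assert marg == pytest.approx(0.1 * const, rel=1e-6)

    def test_quadrature_refinement(self, measured):
        model = _toy_model(np.array([0.2, -0.1, 0.15, -0.05]), 0.05)
        a = log_marginal_likelihood(measured, model, order=64)
        b = log_marginal_likelihood(measured, model, order=640)
        assert abs(a - b) < 1e-4

    def test_sign_flip_symmetry(self, measured):
        """Models with mu and -mu have equal marginals when the measured
        change is replaced by its negation (two-sided symmetry)."""
        import copy

        mu = np.array([0.2, -0.1, 0.15, -0.05])
        m_pos = _toy_model(mu, 0.02, seed=3)
        m_neg = copy.deepcopy(m_pos)
        m_neg.regressor.mean_coef_ = -m_neg.regressor.mean_coef_
        flipped = MeasuredChange(y=measured.y, delta_y=-measured.delta_y,
                                 sigma=measured.sigma, name="x")
        a = log_marginal_likelihood(measured, m_pos)
        b = log_marginal_likelihood(flipped, m_neg)
        assert a == pytest.approx(b, abs=1e-6)


class TestPosterior:
    def test_identical_models_uniform(self, measured):
        mu = np.array([0.2, -0.1, 0.15, -0.05])
        models = [_toy_model(mu, 0.05, name=f"m{i}", seed=7) for i in range(4)]
        post = posterior(measured, models)
        assert np.allclose(list(post["probabilities"].values()), 0.25, atol=1e-12)

    def test_probabilities_sum_to_one(self, measured):
        models = [
            _toy_model(np.array([0.2, -0.1, 0.15, -0.05]), 0.05, "a", seed=1),
            _toy_model(np.array([-0.1, 0.3, 0.05, 0.2]), 0.05, "b", seed=2),
            _toy_model(np.array([0.0, 0.1, -0.3, 0.1]), 0.05, "c", seed=3),
        ]
        post = posterior(measured, models)
        assert sum(post["probabilities"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_needs_two_models(self, measured):
        with pytest.raises(ValueError):
            posterior(measured, [_toy_model(np.zeros(4), 0.0)])

    def test_underflow_flagged_uniform(self):
        mc = MeasuredChange(y=np.full(4, 0.3), delta_y=np.full(4, 1e6),
                            sigma=1e-12 * np.eye(4))
        models = [
            _toy_model(np.array([0.1, 0, 0, 0]), 0.0, "a"),
            _toy_model(np.array([0, 0.1, 0, 0]), 0.0, "b"),
        ]
        post = posterior(mc, models)
        assert post["underflow"]
        assert np.allclose(list(post["probabilities"].values()), 0.5)


class TestChi2:
    def test_parallel_change_zero_distance(self):
        mu = np.array([0.3, -0.2, 0.25, -0.1])
        model = _toy_model(mu, 0.0)
        mc = MeasuredChange(y=np.full(4, 0.3), delta_y=0.05 * mu,
                            sigma=np.eye(4))
        assert chi2_pattern_distance(mc, model) < 1e-6

    def test_orthogonal_change_full_norm(self):
        mu = np.array([1.0, 0.0, 0.0, 0.0])
        model = _toy_model(mu, 0.0)
        dy = np.array([0.0, 0.03, 0.0, 0.0])  # orthogonal to mu
        mc = MeasuredChange(y=np.full(4, 0.3), delta_y=dy, sigma=0.01 * np.eye(4))
        # minimiser sits at |Dnu| = 0, so the distance is the Mahalanobis
        # norm of dy under the noise metric
        assert chi2_pattern_distance(mc, model) == pytest.approx(
            dy @ np.linalg.solve(0.01 * np.eye(4), dy), rel=1e-4
        )

    def test_ranking_consistent_with_marginal(self, measured):
        """On matched-covariance cases the model ranked best by chi-squared
        is also ranked best by marginal likelihood."""
        rng = np.random.default_rng(5)
        models = [
            _toy_model(rng.standard_normal(4) * 0.3, 0.02, f"m{i}", seed=i)
            for i in range(5)
        ]
        true = models[2]
        mc = MeasuredChange(
            y=measured.y,
            delta_y=0.05 * true.predict_mu(measured.y[None])[0],
            sigma=1e-4 * np.eye(4),
        )
        chi = [chi2_pattern_distance(mc, m) for m in models]
        marg = [log_marginal_likelihood(mc, m) for m in models]
        assert int(np.argmin(chi)) == int(np.argmax(marg)) == 2
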