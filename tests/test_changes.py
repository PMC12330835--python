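import numpy as np
import pytest

from cbench.changes import (
    ChangeModelRegressor,
    ChangeSpec,
    ChangeSpecError,
    TrainingConfigError,
    change_vector,
    generate_training_set,
    load_models,
    save_models,
    train_roster,
)
from cbench.forward import batch_signals
from cbench.summary import summary_vectors
from cbench.tissue import PriorSet, TissueParams, params_to_array


class TestChangeSpec:
    def test_fraction_pair_signs_sum_to_zero(self):
        spec = ChangeSpec.fraction_pair("f_in", "f_ex")
        assert sum(spec.signs.values()) == 0
        assert spec.name == "f_in-f_ex"

    def test_single_touches_one_parameter(self):
        spec = ChangeSpec.single("ODI")
        assert list(spec.signs) == ["ODI"]

    def test_unbalanced_fraction_signs_rejected(self):
        with pytest.raises(ChangeSpecError):
            ChangeSpec(name="bad", signs={"f_in": 1.0, "f_ex": 1.0})

    def test_mixed_types_rejected(self):
        with pytest.raises(ChangeSpecError):
            ChangeSpec(name="bad", signs={"f_in": 1.0, "ODI": -1.0})

    def test_flip(self):
        assert ChangeSpec.fraction_pair("f_in", "f_ex").flipped().name == "f_ex-f_in"
        assert ChangeSpec.single("ODI").flipped().name == "-ODI"

    def test_magnitude_range_symmetric_under_flip(self):
        priors = PriorSet()
        spec = ChangeSpec.fraction_pair("f_sph", "f_ex")
        assert spec.magnitude_range(priors) == spec.flipped().magnitude_range(priors)


class TestChangeVector:
    def test_ball_only_closed_form(self, protocol):
        """For a pure ball voxel the b-shell mean-signal response to
        D_ball is the analytic derivative of exp(-b D)."""
        p = TissueParams(f_in=0, f_ex=0, f_sph=0, f_dot=0, f_ball=1, D_ball=1.0)
        ts = change_vector(p, ChangeSpec.single("D_ball"), 1e-4, protocol)
        assert ts.change[0] == pytest.approx(-7 * np.exp(-7), rel=1e-3)
        assert ts.change[2] == pytest.approx(-10 * np.exp(-10), rel=1e-3)

    def test_fraction_pair_preserves_sum(self, protocol):
        p = TissueParams()
        ts = change_vector(p, ChangeSpec.fraction_pair("f_in", "f_ex"), 0.05,
                           protocol)
        assert np.all(np.isfinite(ts.change))

    def test_out_of_bounds_perturbation_rejected(self, protocol):
        p = TissueParams(ODI=0.49)
        with pytest.raises(ChangeSpecError):
            change_vector(p, ChangeSpec.single("ODI"), 0.05, protocol)

    def test_finite_difference_against_central_oracle(self, protocol):
        """Forward difference at magnitude 1e-3 vs an independent central
        difference at 1e-5, within 1% relative."""
        p = TissueParams(ODI=0.2)
        spec = ChangeSpec.single("ODI")
        ts = change_vector(p, spec, 1e-3, protocol)
        batch = params_to_array(p)
        h = 1e-5
        up, dn = dict(batch), dict(batch)
        up["ODI"] = batch["ODI"] + h
        dn["ODI"] = batch["ODI"] - h
        central = (
            summary_vectors(batch_signals(up, protocol), protocol)
            - summary_vectors(batch_signals(dn, protocol), protocol)
        )[0] / (2 * h)
        assert np.linalg.norm(ts.change - central) < 0.01 * np.linalg.norm(central)


class TestTrainingSet:
    def test_deterministic_for_fixed_seed(self, protocol):
        priors = PriorSet()
        spec = ChangeSpec.single("ODI")
        a = generate_training_set(spec, 10, priors, protocol, rng_seed=5)
        b = generate_training_set(spec, 10, priors, protocol, rng_seed=5)
        assert np.array_equal(a.baselines, b.baselines)
        assert np.array_equal(a.changes, b.changes)
        assert np.array_equal(a.magnitudes, b.magnitudes)

    def test_magnitudes_within_prior(self, protocol):
        priors = PriorSet()
        spec = ChangeSpec.fraction_pair("f_in", "f_ex")
        td = generate_training_set(spec, 200, priors, protocol, rng_seed=1)
        lo, hi = spec.magnitude_range(priors)
        assert len(td) == 200
        assert td.magnitudes.min() >= lo and td.magnitudes.max() <= hi

    def test_incompatible_spec_raises(self):
        # f_sph headroom (0.001) is always below the smallest magnitude the
        # f_sph-f_ex spec can draw (0.01, sized by the f_ex width), so every
        # perturbation leaves the range and the configuration is flagged
        from cbench.protocol import two_shell_protocol

        priors = PriorSet()
        tight = dict(priors.ranges)
        tight["f_sph"] = (0.0, 0.001)
        with pytest.raises(TrainingConfigError):
            generate_training_set(
                ChangeSpec.fraction_pair("f_sph", "f_ex"), 500,
                PriorSet(ranges=tight),
                two_shell_protocol(n_directions=12, n_b0=2), rng_seed=0,
            )


class TestRegressor:
    def _linear_samples(self, n=600, m=4, seed=0):
        rng = np.random.default_rng(seed)
        S = rng.uniform(0, 1, (n, m))
        W = rng.standard_normal((m, m))
        b = rng.standard_normal(m)
        return S, S @ W + b, W, b

    def test_recovers_linear_ground_truth(self):
        S, dS, W, b = self._linear_samples()
        reg = ChangeModelRegressor().fit(S[:500], dS[:500])
        assert np.abs(reg.predict(S[500:]) - dS[500:]).max() < 1e-6

    def test_duplicated_samples_leave_model_unchanged(self):
        S, dS, *_ = self._linear_samples()
        a = ChangeModelRegressor().fit(S, dS)
        b = ChangeModelRegressor().fit(np.vstack([S, S]), np.vstack([dS, dS]))
        probe = np.random.default_rng(1).uniform(0, 1, (50, 4))
        assert np.allclose(a.predict(probe), b.predict(probe), atol=1e-8)
        assert np.allclose(a.predict_cov(probe), b.predict_cov(probe), atol=1e-8)

    def test_covariance_predictions_psd(self):
        rng = np.random.default_rng(2)
        S = rng.uniform(0, 1, (800, 4))
        dS = S @ rng.standard_normal((4, 4)) + 0.1 * rng.standard_normal((800, 4))
        reg = ChangeModelRegressor().fit(S, dS)
        cov = reg.predict_cov(rng.uniform(0, 1, (100, 4)))
        eig = np.linalg.eigvalsh(cov)
        assert eig.min() >= -1e-9

    def test_needs_enough_samples(self):
        with pytest.raises(ValueError, match="10x"):
            ChangeModelRegressor().fit(np.ones((20, 4)), np.ones((20, 4)))

    def test_sklearn_api(self):
        from sklearn.base import clone

        reg = ChangeModelRegressor(mean_degree=1)
        assert clone(reg).get_params()["mean_degree"] == 1


class TestTrainedModels:
    def test_antisymmetry_of_reversed_pair(self, protocol):
        """The model for f_in-f_ex predicts the negation of f_ex-f_in at
        matched baselines (within regression error)."""
        priors = PriorSet(with_ball=False)
        models = train_roster(
            [ChangeSpec.fraction_pair("f_in", "f_ex"),
             ChangeSpec.fraction_pair("f_ex", "f_in")],
            priors, protocol, n_samples=4000, rng_seed=3,
        )
        probe = generate_training_set(
            ChangeSpec.single("ODI"), 50, priors, protocol, rng_seed=9
        ).baselines
        mu_a = models["f_in-f_ex"].predict_mu(probe)
        mu_b = models["f_ex-f_in"].predict_mu(probe)
        cos = np.sum(mu_a * -mu_b, axis=1) / (
            np.linalg.norm(mu_a, axis=1) * np.linalg.norm(mu_b, axis=1)
        )
        assert cos.min() > 0.99
        ratio = np.linalg.norm(mu_a, axis=1) / np.linalg.norm(mu_b, axis=1)
        assert np.all((ratio > 0.9) & (ratio < 1.1))

    def test_linearity_over_magnitude_decade(self, protocol):
        """Change vectors divided by magnitude agree within 5% across a
        decade of magnitudes below the prior cap (the linear-response
        assumption behind the finite-difference training)."""
        p = TissueParams(ODI=0.2)
        spec = ChangeSpec.fraction_pair("f_in", "f_ex")
        vecs = [
            change_vector(p, spec, m, protocol).change
            for m in (0.01, 0.02, 0.05, 0.1)
        ]
        for v in vecs[1:]:
            assert np.linalg.norm(v - vecs[0]) < 0.05 * np.linalg.norm(vecs[0])

    def test_roster_training_reproducible(self, protocol):
        priors = PriorSet(with_ball=False)
        roster = [ChangeSpec.single("ODI")]
        a = train_roster(roster, priors, protocol, n_samples=2000, rng_seed=11)
        b = train_roster(roster, priors, protocol, n_samples=2000, rng_seed=11)
        probe = np.random.default_rng(0).uniform(0.05, 0.5, (20, 4))
        assert np.array_equal(a["ODI"].predict_mu(probe), b["ODI"].predict_mu(probe))

    def test_serialisation_roundtrip(self, protocol, tmp_path):
        priors = PriorSet(with_ball=False)
        models = train_roster(
            [ChangeSpec.single("ODI"), ChangeSpec.fraction_pair("f_in", "f_ex")],
            priors, protocol, n_samples=2000, rng_seed=4,
        )
        save_models(models, tmp_path / "models")
        back = load_models(tmp_path / "models")
        assert set(back) == set(models)
        probe = np.random.default_rng(1).uniform(0.05, 0.5, (10, 4))
        for name in models:
            assert np.allclose(models[name].predict_mu(probe),
                               back[name].predict_mu(probe))
            assert np.allclose(models[name].predict_sigma(probe),
                               back[name].predict_sigma(probe))
            assert models[name].magnitude_range == back[name].magnitude_range
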