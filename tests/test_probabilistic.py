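"""Maximum-likelihood logistic fitting, probability maps and expected volumes."""
from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit

import ctp_infarct as ci
from ctp_infarct import (Group, Parameter, SampleSpaceError, SeparationError,
                         ValidationError, VoxelSampleSet)

from conftest import build_patient


def make_samples(x, y, parameter=Parameter.CBF, group=Group.RECANALIZED):
    x = np.asarray(x, dtype=float)
    return VoxelSampleSet(parameter, group, x, np.asarray(y),
                          np.repeat("p", x.size))


def loglik(b0, b1, x, y):
    eta = b0 + b1 * x
    return np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta))


def grid_mle(x, y, b0_range=(-10, 10), b1_range=(-6, 6), n_grid=41, n_zoom=7):
    """Independent likelihood oracle: iteratively refined (β₀, β₁) grid search."""
    (b0_lo, b0_hi), (b1_lo, b1_hi) = b0_range, b1_range
    for _ in range(n_zoom):
        b0s = np.linspace(b0_lo, b0_hi, n_grid)
        b1s = np.linspace(b1_lo, b1_hi, n_grid)
        eta = b0s[:, None, None] + b1s[None, :, None] * x[None, None, :]
        ll = (y * eta).sum(axis=2) - np.logaddexp(0.0, eta).sum(axis=2)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        span0 = (b0_hi - b0_lo) / (n_grid - 1)
        span1 = (b1_hi - b1_lo) / (n_grid - 1)
        b0_lo, b0_hi = b0s[i] - 2 * span0, b0s[i] + 2 * span0
        b1_lo, b1_hi = b1s[j] - 2 * span1, b1s[j] + 2 * span1
    return b0s[i], b1s[j]


class TestFitLogistic:
    def test_null_model_limit(self):
        """Outcome independent of x: slope ≈ 0, intercept ≈ logit(prevalence)."""
        rng = np.random.default_rng(0)
        n = 40_000
        y = np.zeros(n, dtype=int)
        y[: n // 4] = 1
        x = rng.normal(size=n)
        model = ci.fit_logistic(make_samples(x, y))
        assert model.coefficient == pytest.approx(0.0, abs=0.05)
        assert model.intercept == pytest.approx(np.log(1 / 3), abs=0.08)

    def test_matches_grid_likelihood_oracle(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 20:
            n = int(rng.integers(40, 101))
            x = rng.uniform(-2, 2, size=n)
            b0, b1 = rng.uniform(-1.5, 1.5), rng.uniform(-2, 2)
            y = (rng.random(n) < expit(b0 + b1 * x)).astype(int)
            if y.sum() < 5 or y.sum() > n - 5:
                continue
            try:
                model = ci.fit_logistic(make_samples(x, y))
            except SeparationError:
                continue
            b0_ref, b1_ref = grid_mle(x, y)
            assert model.intercept == pytest.approx(b0_ref, abs=1e-3)
            assert model.coefficient == pytest.approx(b1_ref, abs=1e-3)
            checked += 1

    def test_matches_statsmodels(self):
        """Cross-check against an established GLM implementation."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        x = rng.uniform(0, 80, size=5000)
        y = (rng.random(5000) < expit(-1.0 - 0.03 * x)).astype(int)
        model = ci.fit_logistic(make_samples(x, y))
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert model.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert model.coefficient == pytest.approx(ref.params[1], abs=1e-8)

    def test_recovers_generating_coefficients(self):
        """Sampling-error-level recovery of the generating model at n = 2×10⁵."""
        rng = np.random.default_rng(42)
        b0, b1 = -1.172, -0.0211
        x = rng.uniform(0, 80, size=200_000)
        y = (rng.random(x.size) < expit(b0 + b1 * x)).astype(int)
        model = ci.fit_logistic(make_samples(x, y))
        assert model.intercept == pytest.approx(b0, rel=0.05)
        assert model.coefficient == pytest.approx(b1, rel=0.05)

    def test_score_equation_self_consistency(self):
        """Σ π̂ = Σ y on the training voxels (intercept score equation)."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=3000)
        y = (rng.random(3000) < expit(0.5 - x)).astype(int)
        model = ci.fit_logistic(make_samples(x, y))
        assert model.predict_proba(x).sum() == pytest.approx(y.sum(),
                                                             abs=1e-8)

    def test_complete_separation_raises(self):
        with pytest.raises(SeparationError, match="CBF"):
            ci.fit_logistic(make_samples([1, 2, 3, 10, 11, 12],
                                         [1, 1, 1, 0, 0, 0]))

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValidationError):
            ci.fit_logistic(make_samples([3, 3, 3, 3], [0, 1, 0, 1]))

    def test_single_class_rejected(self):
        with pytest.raises(SampleSpaceError):
            ci.fit_logistic(make_samples([1, 2, 3], [0, 0, 0]))


class TestProbabilityMap:
    def test_reference_model_at_zero(self, make_patient):
        """π(0) = 1/(1+e^{1.172}) for the recanalized CBF reference model."""
        model = ci.LogisticModel(Parameter.CBF, Group.RECANALIZED,
                                 -1.172, -0.0211)
        patient = make_patient(values={Parameter.CBF: np.zeros((4, 4, 4))})
        prob = ci.predict_probability_map(model, patient.maps[Parameter.CBF],
                                          patient.hemisphere_mask)
        np.testing.assert_allclose(prob.values, 0.23645, atol=5e-5)

    def test_symmetric_identity(self, make_patient):
        model = ci.LogisticModel(Parameter.CBF, Group.RECANALIZED, 0.0, 0.0)
        patient = make_patient()
        prob = ci.predict_probability_map(model, patient.maps[Parameter.CBF],
                                          patient.hemisphere_mask)
        assert (prob.values == 0.5).all()

    def test_saturation_overflow_safe(self, make_patient):
        model = ci.LogisticModel(Parameter.MTT, Group.RECANALIZED, 0.0, 50.0)
        vals = np.full((4, 4, 4), 1e6)
        patient = make_patient(values={Parameter.MTT: vals})
        with np.errstate(over="raise"):
            prob = ci.predict_probability_map(
                model, patient.maps[Parameter.MTT], patient.hemisphere_mask)
        assert (prob.values == 1.0).all()

    def test_parameter_mismatch(self, make_patient):
        model = ci.LogisticModel(Parameter.CBF, Group.RECANALIZED, 0.0, 1.0)
        with pytest.raises(ValidationError):
            ci.predict_probability_map(model,
                                       make_patient().maps[Parameter.MTT],
                                       np.ones((4, 4, 4), bool))


class TestExpectedVolume:
    def test_uniform_probability(self):
        prob = ci.ProbabilityMap(np.full((25, 20, 20), 0.2),
                                 np.ones((25, 20, 20), bool), (2, 2, 2.5))
        assert ci.expected_volume_ml(prob, 0.01) == pytest.approx(20.0)

    def test_zero_probability(self):
        prob = ci.ProbabilityMap(np.zeros((4, 4, 4)), np.ones((4, 4, 4), bool),
                                 (1, 1, 1))
        assert ci.expected_volume_ml(prob) == 0.0

    def test_mask_excludes_voxels(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0] = True
        prob = ci.ProbabilityMap(np.where(mask, 0.5, 0.0), mask, (1, 1, 1))
        assert ci.expected_volume_ml(prob, 1.0) == pytest.approx(8.0)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValidationError):
            ci.ProbabilityMap(np.full((2, 2, 2), 1.5),
                              np.ones((2, 2, 2), bool), (1, 1, 1))

    def test_linear_and_order_invariant(self):
        rng = np.random.default_rng(8)
        p = rng.random((6, 6, 6))
        mask = np.ones(p.shape, bool)
        v1 = ci.expected_volume_ml(ci.ProbabilityMap(p, mask, (1, 1, 1)), 0.5)
        shuffled = rng.permutation(p.ravel()).reshape(p.shape)
        v2 = ci.expected_volume_ml(ci.ProbabilityMap(shuffled, mask,
                                                     (1, 1, 1)), 0.5)
        assert v1 == pytest.approx(v2, abs=1e-9)
        assert v1 == pytest.approx(0.5 * p.sum(), abs=1e-9)


class TestLopo:
    def test_two_identical_patients_symmetric(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(10, 70, size=(6, 6, 6))
        lesion = rng.random((6, 6, 6)) < expit(2.0 - 0.08 * vals)
        p1 = build_patient("a", values={Parameter.CBF: vals}, lesion=lesion)
        p2 = build_patient("b", values={Parameter.CBF: vals}, lesion=lesion)
        result = ci.lopo_cross_validate([p1, p2], Parameter.CBF,
                                        Group.RECANALIZED)
        assert result.n_folds == 2
        m_a, m_b = result.fold_models["a"], result.fold_models["b"]
        assert m_a.intercept == pytest.approx(m_b.intercept, abs=1e-10)
        assert m_a.coefficient == pytest.approx(m_b.coefficient, abs=1e-10)

    def test_fold_cardinality_and_dispersion(self):
        """One model per held-out patient; coefficients robust across folds."""
        cohort = ci.simulate_cohort(ci.SimulationConfig(
            n_recanalized=20, n_persistent=1, shape=(16, 16, 16), seed=13))
        result = ci.lopo_cross_validate(cohort.patients, Parameter.CBF,
                                        Group.RECANALIZED)
        assert result.n_folds == 20
        disp = result.coefficient_dispersion()
        assert disp["intercept_cv"] < 0.10
        assert disp["coefficient_cv"] < 0.10
        # out-of-fold predictions should still track observed volumes
        ids = list(result.predicted_ml)
        pred = np.array([result.predicted_ml[i] for i in ids])
        obs = np.array([result.observed_ml[i] for i in ids])
        assert np.abs(pred - obs).max() < 10.0

    def test_single_patient_rejected(self, make_patient):
        with pytest.raises(SampleSpaceError):
            ci.lopo_cross_validate([make_patient()], Parameter.CBF,
                                   Group.RECANALIZED)
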