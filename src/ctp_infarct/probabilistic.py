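"""Threshold-free probabilistic infarct-volume prediction.

Instead of binarizing the perfusion map, a univariate logistic regression
fitted on the pooled voxel sample assigns every voxel a conditional infarct
probability

    π(x) = 1 / (1 + exp(−(β₀ + β₁·x))),

and the expected infarct volume is the cumulative sum of these probabilities
over the sampled voxels times the voxel volume — equivalently, (number of
sampled voxels) × (mean π) × (voxel volume).  No threshold is applied at any
point.

A maximum-likelihood fit has a useful exact property: the intercept score
equation forces Σ π̂ = Σ y on the training voxels, so on its own training
sample space the method's group-total predicted volume equals the group-total
observed volume exactly.  Per-patient accuracy is probed out-of-sample with
leave-one-patient-out cross-validation.

Fitting is deterministic (Newton/IRLS); probabilities are never clipped, and
extreme linear predictors use an overflow-safe logistic evaluation so
expected-volume sums stay exact.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .exceptions import (ConvergenceError, SampleSpaceError, SeparationError,
                         ValidationError)
from .images import CohortPatient, Group, Parameter, PerfusionMap
from .samples import (DEFAULT_CBV_FLOOR, VoxelSampleSet, assemble_samples,
                      eligible_mask, observed_volume_ml)

#: Convergence tolerances of the iterative maximum-likelihood fit.
FIT_TOL = 1e-8
FIT_MAX_ITER = 100
#: Ridge added to the information matrix only to rescue a numerically
#: singular Newton step; never a substitute for a separation diagnosis.
RIDGE = 1e-6


@dataclass
class LogisticModel:
    """Univariate logit model for one parameter × group."""

    parameter: Parameter
    group: Group
    intercept: float
    coefficient: float
    n_samples: int = 0
    log_likelihood: float = float("nan")
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.parameter = Parameter(self.parameter)
        self.group = Group(self.group)
        if not (np.isfinite(self.intercept) and np.isfinite(self.coefficient)):
            raise ValidationError("logistic coefficients must be finite")

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.coefficient * np.asarray(x, dtype=float)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """π(x), overflow-safe for arbitrarily extreme linear predictors."""
        return expit(self.linear_predictor(x))


@dataclass
class ProbabilityMap:
    """Voxel-wise infarct-probability grid over an eligibility mask."""

    values: np.ndarray
    eligible_mask: np.ndarray
    voxel_dims: tuple[float, float, float]
    parameter: Parameter | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.eligible_mask = np.asarray(self.eligible_mask, dtype=bool)
        if self.values.shape != self.eligible_mask.shape:
            raise ValidationError("probability grid and mask shapes differ")
        probs = self.values[self.eligible_mask]
        if probs.size and (probs.min() < 0.0 or probs.max() > 1.0):
            raise ValidationError("probabilities outside [0, 1] on eligible voxels")


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # ll = Σ y·η − log(1 + e^η), computed without overflow
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def _check_separation(x: np.ndarray, y: np.ndarray, parameter: Parameter) -> None:
    pos, neg = x[y == 1], x[y == 0]
    if pos.max() <= neg.min() or pos.min() >= neg.max():
        raise SeparationError(
            f"{parameter.value}: outcome classes are (quasi-)completely "
            "separated along the predictor; the likelihood is unbounded"
        )


def fit_logistic(samples: VoxelSampleSet, tol: float = FIT_TOL,
                 max_iter: int = FIT_MAX_ITER) -> LogisticModel:
    """Fit β₀, β₁ by iterative maximum likelihood (Newton/IRLS).

    Convergence is declared when the log-likelihood improves by < ``tol`` or
    the coefficient change is < ``tol``; one extra Newton step is then taken
    so the score equations hold to machine precision (this is what makes the
    in-sample probability-sum identity Σ π̂ = Σ y exact).
    """
    x, y = samples.x, samples.y.astype(float)
    if y.min() == y.max():
        raise SampleSpaceError(
            f"{samples.parameter.value}: both outcome classes are required"
        )
    if np.ptp(x) == 0.0:
        raise ValidationError(
            f"{samples.parameter.value}: predictor is constant; slope is "
            "unidentifiable"
        )
    _check_separation(x, y, samples.parameter)

    # standardize the predictor for conditioning; transform back at the end
    x_mean, x_sd = float(x.mean()), float(x.std())
    z = (x - x_mean) / x_sd
    p0 = float(y.mean())
    beta = np.array([np.log(p0 / (1.0 - p0)), 0.0])

    ll = _bernoulli_loglik(y, np.full_like(z, beta[0]))
    converged = False
    polish = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = beta[0] + beta[1] * z
        mu = expit(eta)
        w = mu * (1.0 - mu)
        r = y - mu
        g = np.array([r.sum(), (r * z).sum()])
        sw, swz, swzz = w.sum(), (w * z).sum(), (w * z * z).sum()
        hess = np.array([[sw, swz], [swz, swzz]])
        try:
            step = np.linalg.solve(hess, g)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(hess + RIDGE * np.eye(2), g)
        # step-halving keeps the likelihood monotone
        new_beta = beta + step
        new_ll = _bernoulli_loglik(y, new_beta[0] + new_beta[1] * z)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll = _bernoulli_loglik(y, new_beta[0] + new_beta[1] * z)
            halvings += 1
        delta = float(np.max(np.abs(new_beta - beta)))
        improved = new_ll - ll
        beta, ll = new_beta, new_ll
        if not np.all(np.isfinite(beta)):
            raise SeparationError(
                f"{samples.parameter.value}: coefficients diverged during "
                "fitting (separation)"
            )
        if polish:
            converged = True
            break
        if improved < tol or delta < tol:
            polish = True  # one final Newton step to zero the score
    if not converged and not polish:
        raise ConvergenceError(
            f"{samples.parameter.value}: no convergence in {max_iter} "
            f"iterations (last Δll={improved:.3e}, Δβ={delta:.3e})"
        )

    b1 = beta[1] / x_sd
    b0 = beta[0] - b1 * x_mean
    return LogisticModel(samples.parameter, samples.group, float(b0), float(b1),
                         n_samples=len(samples), log_likelihood=ll,
                         n_iterations=n_iter)


def predict_probability_map(model: LogisticModel, pmap: PerfusionMap,
                            eligible: np.ndarray) -> ProbabilityMap:
    """Voxel-wise π over the eligible voxels of one map; no thresholding."""
    if Parameter(model.parameter) != pmap.parameter:
        raise ValidationError(
            f"model is for {Parameter(model.parameter).value}, "
            f"map is {pmap.parameter.value}"
        )
    eligible = np.asarray(eligible, dtype=bool)
    if eligible.shape != pmap.shape:
        raise ValidationError(
            f"eligible mask shape {eligible.shape} != map shape {pmap.shape}"
        )
    values = np.zeros(pmap.shape, dtype=float)
    values[eligible] = model.predict_proba(pmap.values[eligible])
    return ProbabilityMap(values, eligible, pmap.voxel_dims, pmap.parameter)


def expected_volume_ml(prob: ProbabilityMap, voxel_volume: float | None = None) -> float:
    """Expected infarct volume: Σ π over eligible voxels × voxel volume (ml)."""
    if voxel_volume is None:
        dx, dy, dz = prob.voxel_dims
        voxel_volume = dx * dy * dz / 1000.0
    probs = prob.values[prob.eligible_mask]
    if probs.size and (probs.min() < 0.0 or probs.max() > 1.0):
        raise ValidationError("probabilities outside [0, 1]")
    return float(probs.sum()) * float(voxel_volume)


def predicted_volume_ml(model: LogisticModel, patient: CohortPatient,
                        cbv_floor: float = DEFAULT_CBV_FLOOR) -> float:
    """Threshold-free predicted volume for one patient."""
    mask = eligible_mask(patient, model.parameter, cbv_floor)
    prob = predict_probability_map(model, patient.maps[Parameter(model.parameter)],
                                   mask)
    return expected_volume_ml(prob, patient.voxel_volume_ml)


# ---------------------------------------------------------------------------
# Leave-one-patient-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class LopoResult:
    """Per-fold models and out-of-fold volume predictions."""

    parameter: Parameter
    group: Group
    fold_models: dict[str, LogisticModel]
    predicted_ml: dict[str, float]
    observed_ml: dict[str, float]
    intercepts: np.ndarray = field(init=False)
    coefficients: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        ids = list(self.fold_models)
        self.intercepts = np.array([self.fold_models[i].intercept for i in ids])
        self.coefficients = np.array([self.fold_models[i].coefficient for i in ids])

    @property
    def n_folds(self) -> int:
        return len(self.fold_models)

    def coefficient_dispersion(self) -> dict[str, float]:
        """Coefficient of variation (SD/|mean|) of β₀ and β₁ across folds."""
        return {
            "intercept_cv": float(self.intercepts.std()
                                  / abs(self.intercepts.mean())),
            "coefficient_cv": float(self.coefficients.std()
                                    / abs(self.coefficients.mean())),
        }


def lopo_cross_validate(cohort: Sequence[CohortPatient], parameter: Parameter,
                        group: Group, cbv_floor: float = DEFAULT_CBV_FLOOR,
                        ) -> LopoResult:
    """Refit the logistic model leaving each patient out in turn.

    Each held-out patient's volume is predicted by the model trained on all
    other patients' voxels, giving an out-of-sample estimate of per-patient
    accuracy and of coefficient robustness.
    """
    parameter = Parameter(parameter)
    group = Group(group)
    members = [p for p in cohort if p.group == group]
    if len(members) < 2:
        raise SampleSpaceError(
            f"leave-one-patient-out needs ≥ 2 patients in {group.value}, "
            f"got {len(members)}"
        )
    fold_models: dict[str, LogisticModel] = {}
    predicted: dict[str, float] = {}
    observed: dict[str, float] = {}
    for held_out in members:
        train = [p for p in members if p.patient_id != held_out.patient_id]
        samples = assemble_samples(train, parameter, group, cbv_floor)
        if samples.y.min() == samples.y.max():
            raise SampleSpaceError(
                f"fold holding out {held_out.patient_id!r}: training voxels "
                "contain a single outcome class"
            )
        model = fit_logistic(samples)
        fold_models[held_out.patient_id] = model
        predicted[held_out.patient_id] = predicted_volume_ml(model, held_out,
                                                             cbv_floor)
        observed[held_out.patient_id] = observed_volume_ml(held_out)
    return LopoResult(parameter, group, fold_models, predicted, observed)
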