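"""Accuracy metrics and method comparison.

The unit of evaluation is the patient: each method produces one predicted
infarct volume per patient, compared against the observed (segmented) volume.
Group-wise accuracy is the root mean square error

    RMSE = √( Σᵢ (V_p,i − V_o,i)² / N ),

ideally 0 ml.  Uncertainty is quantified by a percentile bootstrap over
patients (default 100 000 resamples) and methods are compared with a paired
randomization test (default 100 000 samples): per patient, the two methods'
predictions are randomly relabelled, which generates the null distribution of
the RMSE difference without distributional assumptions.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import PairingError, ValidationError
from .images import CohortPatient, Group, Parameter
from .probabilistic import LogisticModel, predicted_volume_ml
from .samples import DEFAULT_CBV_FLOOR, eligible_mask, observed_volume_ml
from .thresholding import ThresholdModel, predict_binary, threshold_volume_ml

DEFAULT_N_BOOT = 100_000
DEFAULT_N_PERM = 100_000


class Method(str, Enum):
    THRESHOLD = "THRESHOLD"
    THRESHOLD_FREE = "THRESHOLD_FREE"


@dataclass
class VolumeRecord:
    """One patient's predicted vs observed volume under one method."""

    patient_id: str
    group: Group
    parameter: Parameter
    method: Method
    predicted_ml: float
    observed_ml: float

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.parameter = Parameter(self.parameter)
        self.method = Method(self.method)
        for name, v in (("predicted_ml", self.predicted_ml),
                        ("observed_ml", self.observed_ml)):
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and ≥ 0, got {v}")


@dataclass
class MethodEvaluation:
    """RMSE with bootstrap CI and, when compared, a randomization p-value."""

    rmse: float
    ci_low: float
    ci_high: float
    n_patients: int
    comparison_p: float | None = None


def _errors(records: Sequence[VolumeRecord]) -> np.ndarray:
    if len(records) == 0:
        raise ValidationError("no volume records supplied")
    return np.array([r.predicted_ml - r.observed_ml for r in records])


def rmse(records: Sequence[VolumeRecord]) -> float:
    """Root mean square volumetric prediction error over patients (ml)."""
    e = _errors(records)
    return float(np.sqrt(np.mean(e ** 2)))


def bootstrap_rmse_ci(records: Sequence[VolumeRecord],
                      n_boot: int = DEFAULT_N_BOOT,
                      seed: int | np.random.Generator = 0,
                      ) -> tuple[float, float]:
    """Percentile (2.5 %, 97.5 %) bootstrap interval of the RMSE.

    Patients (not voxels) are resampled with replacement, since the RMSE is a
    patient-level statistic.  Deterministic given ``seed``.
    """
    e = _errors(records)
    n = e.size
    if n < 2:
        raise ValidationError("bootstrap CI needs at least 2 patients")
    if n_boot < 1:
        raise ValidationError("n_boot must be ≥ 1")
    rng = np.random.default_rng(seed)
    sq = e ** 2
    stats = np.empty(n_boot)
    chunk = max(1, min(n_boot, 20_000_000 // n))
    for start in range(0, n_boot, chunk):
        stop = min(start + chunk, n_boot)
        idx = rng.integers(0, n, size=(stop - start, n))
        stats[start:stop] = np.sqrt(sq[idx].mean(axis=1))
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def randomization_test(records_a: Sequence[VolumeRecord],
                       records_b: Sequence[VolumeRecord],
                       n_perm: int = DEFAULT_N_PERM,
                       seed: int | np.random.Generator = 0) -> float:
    """Paired randomization test of RMSE(a) − RMSE(b).

    Records must pair by patient (same patients, two methods).  The null is
    generated by swapping, independently per patient, which method's
    prediction carries which label; the two-sided p-value uses the add-one
    correction p = (1 + #{|T*| ≥ |T|}) / (1 + n_perm), so p ≥ 1/(1+n_perm).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be ≥ 1")
    a = {r.patient_id: r for r in records_a}
    b = {r.patient_id: r for r in records_b}
    if len(a) != len(records_a) or len(b) != len(records_b):
        raise PairingError("duplicate patient_id within one record list")
    if set(a) != set(b):
        raise PairingError(
            "records are not paired by patient_id: "
            f"{sorted(set(a) ^ set(b))[:5]} ..."
        )
    ids = sorted(a)
    sa = np.array([(a[i].predicted_ml - a[i].observed_ml) ** 2 for i in ids])
    sb = np.array([(b[i].predicted_ml - b[i].observed_ml) ** 2 for i in ids])
    n = len(ids)
    observed = np.sqrt(sa.mean()) - np.sqrt(sb.mean())

    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(n_perm, 20_000_000 // n))
    for start in range(0, n_perm, chunk):
        stop = min(start + chunk, n_perm)
        swap = rng.random((stop - start, n)) < 0.5
        pa = np.where(swap, sb, sa)
        pb = np.where(swap, sa, sb)
        stat = np.sqrt(pa.mean(axis=1)) - np.sqrt(pb.mean(axis=1))
        count += int(np.count_nonzero(np.abs(stat) >= abs(observed) - 1e-12))
    return (1 + count) / (1 + n_perm)


def evaluate_method(records: Sequence[VolumeRecord],
                    n_boot: int = DEFAULT_N_BOOT,
                    seed: int | np.random.Generator = 0,
                    comparison_p: float | None = None) -> MethodEvaluation:
    """Bundle RMSE, bootstrap CI and an optional comparison p-value."""
    lo, hi = bootstrap_rmse_ci(records, n_boot=n_boot, seed=seed)
    return MethodEvaluation(rmse(records), lo, hi, len(records), comparison_p)


# ---------------------------------------------------------------------------
# Cohort-level prediction + summaries
# ---------------------------------------------------------------------------

def predict_cohort(cohort: Sequence[CohortPatient], parameter: Parameter,
                   group: Group, threshold_model: ThresholdModel | None = None,
                   logistic_model: LogisticModel | None = None,
                   cbv_floor: float = DEFAULT_CBV_FLOOR) -> list[VolumeRecord]:
    """Per-patient predicted vs observed volumes for the supplied models."""
    parameter = Parameter(parameter)
    group = Group(group)
    records: list[VolumeRecord] = []
    for patient in cohort:
        if patient.group != group:
            continue
        obs = observed_volume_ml(patient)
        if threshold_model is not None:
            mask = eligible_mask(patient, parameter, cbv_floor)
            binary = predict_binary(threshold_model, patient.maps[parameter], mask)
            records.append(VolumeRecord(
                patient.patient_id, group, parameter, Method.THRESHOLD,
                threshold_volume_ml(binary, patient.voxel_volume_ml), obs))
        if logistic_model is not None:
            records.append(VolumeRecord(
                patient.patient_id, group, parameter, Method.THRESHOLD_FREE,
                predicted_volume_ml(logistic_model, patient, cbv_floor), obs))
    return records


def records_to_frame(records: Sequence[VolumeRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "patient_id": r.patient_id,
        "group": r.group.value,
        "parameter": r.parameter.value,
        "method": r.method.value,
        "predicted_ml": r.predicted_ml,
        "observed_ml": r.observed_ml,
    } for r in records])


def summarize_group(records: Sequence[VolumeRecord]) -> pd.DataFrame:
    """Descriptive statistics of predicted and observed volumes.

    Mean, SD, median and IQR (Q3 − Q1, linear-interpolation quantiles) per
    parameter × method, for both the predicted and the observed volumes —
    the content of a per-group box plot.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValidationError("no volume records supplied")

    def _stats(s: pd.Series) -> pd.Series:
        q1, q3 = np.percentile(s, [25, 75])  # type-7 / linear interpolation
        return pd.Series({
            "mean": s.mean(), "sd": s.std(ddof=1) if len(s) > 1 else 0.0,
            "median": s.median(), "iqr": q3 - q1, "n": len(s),
        })

    out = []
    for (param, method), sub in df.groupby(["parameter", "method"], sort=True):
        for which in ("predicted_ml", "observed_ml"):
            row = _stats(sub[which])
            row["parameter"], row["method"], row["volume"] = param, method, which
            out.append(row)
    summary = pd.DataFrame(out).set_index(["parameter", "method", "volume"])
    return summary[["mean", "sd", "median", "iqr", "n"]]
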