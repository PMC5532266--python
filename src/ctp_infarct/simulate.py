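"""Synthetic stroke-cohort simulator.

Generates cohorts with the statistical structure the voxel-wise analysis
assumes, so the whole pipeline is testable without patient data:

* two recanalization groups with right-skewed infarct-volume distributions
  (lognormal lesion-severity draws);
* per patient, a smooth ischemic region in the affected hemisphere whose
  perfusion deviations scale with severity — CBF/CBV depressed, MTT/TTD
  elevated — plus spatially uncorrelated voxel noise with a configurable
  shared component linking the four maps;
* voxel-wise infarct labels drawn Bernoulli from a generating logistic model
  applied to a designated driver parameter map (default CBF, with the
  published reference coefficients), so the threshold-free method is
  correctly specified under the defaults and its calibration behaviour is a
  provable property of the simulation;
* a configurable fraction of hemisphere voxels forced below the CBV
  reliability floor, to exercise the MTT/TTD exclusion rule.

Everything is deterministic given ``SimulationConfig.seed``.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .exceptions import ValidationError
from .images import (CohortPatient, Group, LesionMask, Parameter, PerfusionMap,
                     voxel_volume_ml, write_volume)
from .reference import reference_coefficients

#: Baseline (non-ischemic parenchyma) mean value per parameter.
BASELINES: dict[Parameter, float] = {
    Parameter.CBF: 65.0,   # ml·100g⁻¹·min⁻¹
    Parameter.CBV: 4.0,    # ml·100g⁻¹
    Parameter.MTT: 4.5,    # s
    Parameter.TTD: 5.5,    # s
}

#: Full-severity ischemic deviation: fractional drop for flow parameters,
#: additive rise (in parameter units) for timing parameters.
ISCHEMIA_EFFECT: dict[Parameter, float] = {
    Parameter.CBF: -0.85,
    Parameter.CBV: -0.60,
    Parameter.MTT: +9.0,
    Parameter.TTD: +11.0,
}

#: Voxel-noise SD per parameter (parameter units).
DEFAULT_NOISE_SD: dict[Parameter, float] = {
    Parameter.CBF: 8.0,
    Parameter.CBV: 0.6,
    Parameter.MTT: 1.0,
    Parameter.TTD: 1.2,
}

#: Lognormal (mu, sigma) of the ischemic-core fraction of the hemisphere.
DEFAULT_SEVERITY: dict[Group, tuple[float, float]] = {
    Group.RECANALIZED: (float(np.log(0.10)), 0.9),
    Group.PERSISTENT: (float(np.log(0.45)), 0.5),
}


@dataclass
class SimulationConfig:
    """Cohort-level generating parameters; defaults are the study conditions."""

    n_recanalized: int = 93
    n_persistent: int = 68
    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_dims: tuple[float, float, float] = (2.0, 2.0, 5.0)
    #: generating (β₀, β₁) per (parameter, group); defaults to the published
    #: reference coefficients.
    coefficients: Mapping[tuple[Parameter, Group], tuple[float, float]] = field(
        default_factory=reference_coefficients)
    #: parameter whose (noisy) map drives the generating infarct probability.
    driver_parameter: Parameter = Parameter.CBF
    severity: Mapping[Group, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY))
    max_core_fraction: float = 0.95
    noise_sd: Mapping[Parameter, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD))
    #: correlation of the four maps' noise through a shared field, in [-1, 1].
    noise_correlation: float = 0.3
    smooth_sigma_mm: float = 6.0
    cbv_floor: float = 0.5
    #: fraction of hemisphere voxels forced below the CBV floor.
    low_cbv_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_recanalized < 1 or self.n_persistent < 1:
            raise ValidationError("patient counts must be ≥ 1")
        if any(s < 2 for s in self.shape):
            raise ValidationError(f"grid shape too small: {self.shape}")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValidationError(f"voxel dims must be positive: {self.voxel_dims}")
        if not 0.0 <= self.low_cbv_fraction <= 1.0:
            raise ValidationError("low_cbv_fraction must lie in [0, 1]")
        if not 0.0 < self.max_core_fraction <= 1.0:
            raise ValidationError("max_core_fraction must lie in (0, 1]")
        if not -1.0 <= self.noise_correlation <= 1.0:
            raise ValidationError("noise_correlation must lie in [-1, 1]")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValidationError("noise SDs must be ≥ 0")


@dataclass
class PatientTruth:
    """Generating-model ground truth for one synthetic patient."""

    severity: float               # target core fraction of the hemisphere
    probability: np.ndarray       # per-voxel true infarct probability


@dataclass
class SyntheticCohort:
    patients: list[CohortPatient]
    truth: dict[str, PatientTruth]
    config: SimulationConfig

    def patient(self, patient_id: str) -> CohortPatient:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(f"unknown patient_id {patient_id!r}")


def hemisphere_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Affected hemisphere: fixed left half of the grid along the first axis."""
    mask = np.zeros(shape, dtype=bool)
    mask[: shape[0] // 2] = True
    return mask


def truth_volume_ml(cohort: SyntheticCohort, patient_id: str) -> float:
    """Expected volume under the generating model: Σ true π × voxel volume."""
    try:
        truth = cohort.truth[patient_id]
    except KeyError:
        raise KeyError(f"unknown patient_id {patient_id!r}") from None
    return float(truth.probability.sum()) * voxel_volume_ml(
        cohort.config.voxel_dims)


def _simulate_patient(config: SimulationConfig, group: Group, patient_id: str,
                      rng: np.random.Generator,
                      ) -> tuple[CohortPatient, PatientTruth]:
    shape = config.shape
    dims = np.asarray(config.voxel_dims, dtype=float)
    hemi = hemisphere_mask(shape)
    n_hemi = int(hemi.sum())

    # (1) lesion severity: target core fraction of the hemisphere
    mu, sigma = config.severity[Group(group)]
    severity = float(np.exp(rng.normal(mu, sigma)))
    severity = min(severity, config.max_core_fraction)

    # (2) smooth ischemic field: the k hemisphere voxels nearest a random
    # center, k = severity × hemisphere size (ball truncated at boundaries
    # keeps the target core fraction exact), then blurred
    half = shape[0] // 2
    center = rng.uniform([0.15 * half, 0.15 * shape[1], 0.15 * shape[2]],
                         [0.85 * half, 0.85 * shape[1], 0.85 * shape[2]])
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    dist2 = sum(((g - c) * d) ** 2
                for g, c, d in zip(grids, center, dims))
    core = np.zeros(shape, dtype=bool)
    k = int(round(severity * n_hemi))
    if k > 0:
        hemi_flat = np.flatnonzero(hemi)
        nearest = np.argpartition(dist2.ravel()[hemi_flat], min(k, n_hemi) - 1)
        core.flat[hemi_flat[nearest[:k]]] = True
    field3d = gaussian_filter(core.astype(float),
                              sigma=config.smooth_sigma_mm / dims)
    peak = field3d.max()
    if peak > 0:
        field3d = field3d / peak
    field3d *= hemi

    # (3) perfusion maps: baseline + severity-scaled deviation + noise
    shared = rng.standard_normal(shape)
    rho = abs(config.noise_correlation)
    maps: dict[Parameter, PerfusionMap] = {}
    for parameter in Parameter:
        own = rng.standard_normal(shape)
        noise = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
        base = BASELINES[parameter]
        effect = ISCHEMIA_EFFECT[parameter]
        if parameter in (Parameter.CBF, Parameter.CBV):
            values = base * (1.0 + effect * field3d) \
                - config.noise_sd[parameter] * noise
        else:
            values = base + effect * field3d \
                + config.noise_sd[parameter] * noise
        values = np.clip(values, 0.05, None)
        maps[parameter] = PerfusionMap(parameter, values, tuple(dims),
                                       np.ones(shape, dtype=bool))

    # (4) unreliable-timing voxels: force CBV below the reliability floor
    k = int(round(config.low_cbv_fraction * n_hemi))
    if k > 0:
        flat_hemi = np.flatnonzero(hemi)
        chosen = rng.choice(flat_hemi, size=k, replace=False)
        cbv = maps[Parameter.CBV].values
        cbv.flat[chosen] = rng.uniform(0.0, 0.9 * config.cbv_floor, size=k)

    # (5) voxel-wise infarct probability from the driver map, Bernoulli lesion
    beta0, beta1 = config.coefficients[(Parameter(config.driver_parameter),
                                        Group(group))]
    prob = np.zeros(shape, dtype=float)
    driver = maps[Parameter(config.driver_parameter)].values
    prob[hemi] = expit(beta0 + beta1 * driver[hemi])
    lesion_grid = rng.random(shape) < prob

    patient = CohortPatient(
        patient_id, Group(group), maps,
        LesionMask(lesion_grid, tuple(dims)), hemi)
    return patient, PatientTruth(severity, prob)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full two-group cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    patients: list[CohortPatient] = []
    truth: dict[str, PatientTruth] = {}
    for group, n, tag in ((Group.RECANALIZED, config.n_recanalized, "rec"),
                          (Group.PERSISTENT, config.n_persistent, "per")):
        for i in range(n):
            pid = f"{tag}-{i + 1:03d}"
            patient, pt = _simulate_patient(config, group, pid, rng)
            patients.append(patient)
            truth[pid] = pt
    return SyntheticCohort(patients, truth, config)


def simulate_group(config: SimulationConfig, group: Group) -> SyntheticCohort:
    """Convenience: simulate only one group (the other count set to 1)."""
    group = Group(group)
    cfg = replace(config,
                  n_recanalized=config.n_recanalized
                  if group == Group.RECANALIZED else 1,
                  n_persistent=config.n_persistent
                  if group == Group.PERSISTENT else 1)
    cohort = simulate_cohort(cfg)
    keep = [p for p in cohort.patients if p.group == group]
    return SyntheticCohort(keep, {p.patient_id: cohort.truth[p.patient_id]
                                  for p in keep}, cfg)


# ---------------------------------------------------------------------------
# Cohort directory export (NIfTI volumes + manifest CSV + truth JSON)
# ---------------------------------------------------------------------------

_GROUP_MANIFEST_LABEL = {Group.RECANALIZED: "TICI 2b-3",
                         Group.PERSISTENT: "TICI 0-2a"}


def write_cohort(cohort: SyntheticCohort, out_dir: str | os.PathLike,
                 write_truth_maps: bool = False) -> Path:
    """Write a cohort directory consumable by :func:`ctp_infarct.read_cohort`.

    Returns the manifest path.  ``write_truth_maps`` additionally stores each
    patient's true probability grid as NIfTI.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    truth_json: dict[str, dict] = {}
    for p in cohort.patients:
        pdir = out / p.patient_id
        pdir.mkdir(exist_ok=True)
        row = {"patient_id": p.patient_id,
               "group": _GROUP_MANIFEST_LABEL[p.group]}
        for parameter, col in ((Parameter.CBF, "cbf_path"),
                               (Parameter.CBV, "cbv_path"),
                               (Parameter.MTT, "mtt_path"),
                               (Parameter.TTD, "ttd_path")):
            rel = f"{p.patient_id}/{parameter.value.lower()}.nii.gz"
            write_volume(out / rel, p.maps[parameter].values, p.voxel_dims)
            row[col] = rel
        rel = f"{p.patient_id}/lesion.nii.gz"
        write_volume(out / rel, p.lesion.values, p.voxel_dims)
        row["lesion_path"] = rel
        rel = f"{p.patient_id}/hemisphere.nii.gz"
        write_volume(out / rel, p.hemisphere_mask, p.voxel_dims)
        row["hemisphere_path"] = rel
        rows.append(row)
        t = cohort.truth[p.patient_id]
        truth_json[p.patient_id] = {
            "severity": t.severity,
            "truth_volume_ml": truth_volume_ml(cohort, p.patient_id),
        }
        if write_truth_maps:
            rel = f"{p.patient_id}/truth_probability.nii.gz"
            write_volume(out / rel, t.probability, p.voxel_dims)
            truth_json[p.patient_id]["probability_path"] = rel
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump({"seed": cohort.config.seed, "patients": truth_json}, fh,
                  indent=2)
    return manifest
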