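"""Voxel-wise sample-space assembly.

Both prediction methods are trained on a pooled voxel matrix: one row per
parenchymal voxel of the *ischemic hemisphere* of every patient in a
recanalization group, with the perfusion value as predictor and the binary
follow-up infarct label as response.  Restricting the sample space to the
affected hemisphere avoids the flood of meaningless true negatives that the
healthy hemisphere would contribute.

For the timing parameters (MTT, TTD) voxels whose cerebral blood volume is
too low for bolus timing to be measured are excluded from the sample space;
flow parameters (CBF, CBV) are unaffected by this rule.  Excluded voxels keep
their segmented lesion label when the *observed* volume is computed — the
observed volume comes from segmentation, not from any predictor's sample
space.
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ManifestError, SampleSpaceError, ValidationError
from .images import (CohortPatient, Group, Parameter, TIMING_PARAMETERS,
                     voxel_volume_ml)

#: Default CBV level (ml·100 g⁻¹) below which bolus timing is unreliable and
#: MTT/TTD voxels are dropped from the analysis.
DEFAULT_CBV_FLOOR = 0.5


@dataclass
class VoxelSampleSet:
    """Pooled (predictor, outcome, patient) triplets for one parameter × group."""

    parameter: Parameter
    group: Group
    x: np.ndarray
    y: np.ndarray
    patient_ids: np.ndarray

    def __post_init__(self) -> None:
        self.parameter = Parameter(self.parameter)
        self.group = Group(self.group)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y)
        self.patient_ids = np.asarray(self.patient_ids)
        if not (self.x.shape == self.y.shape == self.patient_ids.shape):
            raise ValidationError(
                "x, y and patient_ids must be aligned 1-D vectors; got shapes "
                f"{self.x.shape}, {self.y.shape}, {self.patient_ids.shape}"
            )
        if not np.isfinite(self.x).all():
            raise ValidationError("predictor values must be finite")
        uniq = np.unique(self.y)
        if not np.isin(uniq, [0, 1]).all():
            raise ValidationError(f"outcomes must be binary 0/1, got {uniq}")
        self.y = self.y.astype(np.int8)

    def __len__(self) -> int:
        return self.x.size

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    def to_frame(self) -> pd.DataFrame:
        """Flat (patient_id, x, y) table, e.g. for export to external tools."""
        return pd.DataFrame(
            {"patient_id": self.patient_ids, "x": self.x, "y": self.y}
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)


def eligible_mask(patient: CohortPatient, parameter: Parameter,
                  cbv_floor: float = DEFAULT_CBV_FLOOR) -> np.ndarray:
    """Boolean grid of voxels entering the sample space for one parameter.

    A voxel is eligible iff it lies in the patient's ischemic-hemisphere
    parenchyma mask, carries a valid value in the parameter map, and — for
    MTT/TTD only — has CBV ≥ ``cbv_floor``.
    """
    parameter = Parameter(parameter)
    pmap = patient.maps[parameter]
    mask = patient.hemisphere_mask & pmap.valid_mask
    if parameter in TIMING_PARAMETERS:
        mask = mask & (patient.maps[Parameter.CBV].values >= cbv_floor)
    return mask


def assemble_samples(cohort: Iterable[CohortPatient], parameter: Parameter,
                     group: Group, cbv_floor: float = DEFAULT_CBV_FLOOR,
                     ) -> VoxelSampleSet:
    """Pool the eligible voxels of every patient of ``group`` into one sample set.

    Patients are processed in cohort order; each contributes a contiguous
    block, so permuting patients permutes blocks without changing the
    multiset of (x, y) pairs.
    """
    parameter = Parameter(parameter)
    group = Group(group)
    xs, ys, ids = [], [], []
    n_group = 0
    for patient in cohort:
        if patient.group != group:
            continue
        n_group += 1
        if parameter not in patient.maps:
            raise ManifestError(
                f"patient {patient.patient_id!r} has no {parameter.value} map"
            )
        mask = eligible_mask(patient, parameter, cbv_floor)
        vals = patient.maps[parameter].values[mask]
        xs.append(vals)
        ys.append(patient.lesion.values[mask])
        ids.append(np.repeat(patient.patient_id, vals.size))
    if n_group == 0:
        raise SampleSpaceError(f"no patients in group {group.value}")
    x = np.concatenate(xs) if xs else np.empty(0)
    if x.size == 0:
        raise SampleSpaceError(
            f"sample space for {parameter.value}/{group.value} is empty after "
            "eligibility filtering"
        )
    return VoxelSampleSet(parameter, group,
                          x, np.concatenate(ys).astype(np.int8),
                          np.concatenate(ids))


def observed_volume_ml(patient: CohortPatient) -> float:
    """Observed infarct volume: segmented lesion voxel count × voxel volume."""
    return float(patient.lesion.values.sum()) * voxel_volume_ml(patient.voxel_dims)


def observed_volumes(cohort: Sequence[CohortPatient],
                     group: Group | None = None) -> pd.Series:
    """Observed volumes for a cohort (optionally one group), indexed by patient."""
    rows = {
        p.patient_id: observed_volume_ml(p)
        for p in cohort
        if group is None or p.group == Group(group)
    }
    return pd.Series(rows, name="observed_ml")
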