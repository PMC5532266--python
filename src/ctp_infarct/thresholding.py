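"""Conventional threshold-based infarct prediction.

The classical approach binarizes a perfusion map at an "optimal" cutoff:
ROC-curve analysis of the pooled voxel sample yields, per parameter and
recanalization group, the cutoff maximizing the Youden index
J = sensitivity + specificity − 1.  Voxels beyond the cutoff (below it for
CBF/CBV, above it for MTT/TTD) are classified as infarct, and the predicted
infarct volume is the positive-voxel count times the voxel volume.

Conventions, fixed for reproducibility:

* candidate cutoffs are the sorted unique observed predictor values;
* classification uses strict inequality — a voxel exactly at the cutoff is
  negative;
* ties in J are broken toward the cutoff classifying the fewest voxels
  positive (the most conservative prediction), then the smallest cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import DegenerateROCError, ValidationError
from .images import FLOW_PARAMETERS, Group, Parameter, PerfusionMap
from .samples import VoxelSampleSet


class Direction(str, Enum):
    """Which tail of the predictor is called infarct."""

    LOWER_IS_POSITIVE = "LOWER_IS_POSITIVE"    # CBF, CBV: low flow/volume
    HIGHER_IS_POSITIVE = "HIGHER_IS_POSITIVE"  # MTT, TTD: long delays


def direction_for(parameter: Parameter) -> Direction:
    return (Direction.LOWER_IS_POSITIVE if Parameter(parameter) in FLOW_PARAMETERS
            else Direction.HIGHER_IS_POSITIVE)


@dataclass
class RocCurve:
    """Empirical ROC over the unique observed cutoffs of one sample set."""

    parameter: Parameter
    group: Group
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: Direction
    n_positive: int
    n_negative: int

    @property
    def youden(self) -> np.ndarray:
        """J = sensitivity + specificity − 1 at every candidate cutoff."""
        return self.sensitivity + self.specificity - 1.0

    @property
    def n_predicted_positive(self) -> np.ndarray:
        """Training voxels classified positive at every candidate cutoff."""
        tp = self.sensitivity * self.n_positive
        fp = (1.0 - self.specificity) * self.n_negative
        return np.rint(tp + fp).astype(int)


@dataclass
class ThresholdModel:
    """A fitted optimal-cutoff classifier for one parameter × group."""

    parameter: Parameter
    group: Group
    cutoff: float
    direction: Direction
    youden_j: float

    def predict(self, values: np.ndarray) -> np.ndarray:
        """Binary classification of raw parameter values (strict inequality)."""
        values = np.asarray(values, dtype=float)
        if self.direction == Direction.LOWER_IS_POSITIVE:
            return values < self.cutoff
        return values > self.cutoff


def roc_curve(samples: VoxelSampleSet) -> RocCurve:
    """ROC analysis of a pooled voxel sample.

    Candidate cutoffs are the sorted unique observed values; sensitivity and
    specificity at each cutoff follow the strict-inequality rule.  The AUC is
    the trapezoidal area under the ROC polyline closed at (0,0) and (1,1),
    which equals the Mann–Whitney probability that a random infarct voxel has
    a more extreme value than a random non-infarct voxel, ties counted ½.
    """
    y = samples.y
    if y.min() == y.max():
        raise DegenerateROCError(
            f"{samples.parameter.value}/{samples.group.value}: sample contains "
            "a single outcome class; ROC is undefined"
        )
    direction = direction_for(samples.parameter)
    pos = np.sort(samples.x[y == 1])
    neg = np.sort(samples.x[y == 0])
    cutoffs = np.unique(samples.x)
    if direction == Direction.LOWER_IS_POSITIVE:
        tp = np.searchsorted(pos, cutoffs, side="left")   # pos < c
        fp = np.searchsorted(neg, cutoffs, side="left")
    else:
        tp = pos.size - np.searchsorted(pos, cutoffs, side="right")  # pos > c
        fp = neg.size - np.searchsorted(neg, cutoffs, side="right")
    sens = tp / pos.size
    fpr = fp / neg.size

    # close the polyline at both corners before integrating
    pts_fpr = np.concatenate(([0.0], fpr, [1.0]))
    pts_tpr = np.concatenate(([0.0], sens, [1.0]))
    order = np.lexsort((pts_tpr, pts_fpr))
    auc = float(np.trapezoid(pts_tpr[order], pts_fpr[order]))

    return RocCurve(samples.parameter, samples.group, cutoffs, sens, 1.0 - fpr,
                    auc, direction, int(pos.size), int(neg.size))


def youden_threshold(roc: RocCurve) -> ThresholdModel:
    """Optimal cutoff by exhaustive Youden-index maximization.

    Ties in J (within 1e−12) are resolved toward the fewest predicted
    positives, then the smallest cutoff — a deterministic, conservative rule.
    """
    j = roc.youden
    jmax = j.max()
    tied = np.flatnonzero(j >= jmax - 1e-12)
    n_pos_pred = roc.n_predicted_positive[tied]
    best = tied[np.lexsort((roc.cutoffs[tied], n_pos_pred))[0]]
    return ThresholdModel(roc.parameter, roc.group, float(roc.cutoffs[best]),
                          roc.direction, float(j[best]))


def predict_binary(model: ThresholdModel, pmap: PerfusionMap,
                   eligible_mask: np.ndarray) -> np.ndarray:
    """Binary infarct prediction over the eligible voxels of one map."""
    if Parameter(model.parameter) != pmap.parameter:
        raise ValidationError(
            f"model is for {Parameter(model.parameter).value}, "
            f"map is {pmap.parameter.value}"
        )
    eligible_mask = np.asarray(eligible_mask, dtype=bool)
    if eligible_mask.shape != pmap.shape:
        raise ValidationError(
            f"eligible mask shape {eligible_mask.shape} != map shape {pmap.shape}"
        )
    return model.predict(pmap.values) & eligible_mask


def threshold_volume_ml(binary: np.ndarray, voxel_volume: float) -> float:
    """Predicted volume: positive-voxel count × voxel volume (ml)."""
    return float(np.count_nonzero(binary)) * float(voxel_volume)


def fit_threshold(samples: VoxelSampleSet) -> ThresholdModel:
    """Convenience: ROC analysis followed by Youden-cutoff selection."""
    return youden_threshold(roc_curve(samples))
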