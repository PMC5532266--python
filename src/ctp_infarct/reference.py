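"""Bundled reference models from a published multicenter stroke cohort.

Fitting these models requires patient data; for reuse (probability maps from
new co-registered CTP maps, simulator defaults, regression tests) the package
ships the published univariate logistic coefficients and the Youden-optimal
cutoffs/AUCs for all four perfusion parameters in both recanalization groups.
"""
from __future__ import annotations

import json
from importlib import resources

from .images import Group, Parameter
from .probabilistic import LogisticModel
from .thresholding import Direction, ThresholdModel


def _load(name: str) -> dict:
    with resources.files("ctp_infarct.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_reference_logistic_models() -> dict[tuple[Parameter, Group], LogisticModel]:
    """The eight published (parameter × group) logistic models."""
    raw = _load("logistic_models.json")
    return {
        (Parameter(m["parameter"]), Group(m["group"])): LogisticModel(
            Parameter(m["parameter"]), Group(m["group"]),
            m["intercept"], m["coefficient"])
        for m in raw["models"]
    }


def load_reference_threshold_models() -> dict[tuple[Parameter, Group], ThresholdModel]:
    """The eight published Youden-optimal cutoffs (AUC attached as attribute)."""
    raw = _load("threshold_models.json")
    out = {}
    for m in raw["models"]:
        model = ThresholdModel(Parameter(m["parameter"]), Group(m["group"]),
                               m["cutoff"], Direction(m["direction"]),
                               youden_j=float("nan"))
        model.auc = m["auc"]  # type: ignore[attr-defined]
        out[(Parameter(m["parameter"]), Group(m["group"]))] = model
    return out


def reference_coefficients() -> dict[tuple[Parameter, Group], tuple[float, float]]:
    """(β₀, β₁) pairs of the reference logistic models."""
    return {
        key: (m.intercept, m.coefficient)
        for key, m in load_reference_logistic_models().items()
    }
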