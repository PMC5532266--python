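"""Shared fixtures: hand-built micro-patients and a seeded synthetic cohort."""
from __future__ import annotations

import numpy as np
import pytest

from ctp_infarct import (CohortPatient, Group, LesionMask, Parameter,
                         PerfusionMap, SimulationConfig, simulate_cohort)

BASE_VALUES = {
    Parameter.CBF: 60.0,
    Parameter.CBV: 4.0,
    Parameter.MTT: 4.0,
    Parameter.TTD: 5.0,
}


def build_patient(patient_id="p1", group=Group.RECANALIZED, shape=(4, 4, 4),
                  voxel_dims=(2.0, 2.0, 5.0), values=None, lesion=None,
                  hemisphere=None):
    """Construct a CohortPatient from plain arrays with sensible defaults.

    ``values`` maps Parameter → array (missing parameters get a constant
    baseline); ``lesion`` defaults to empty; ``hemisphere`` defaults to the
    full grid.
    """
    values = values or {}
    if values:
        shape = np.asarray(next(iter(values.values()))).shape
    maps = {}
    for p in Parameter:
        v = values.get(p)
        if v is None:
            v = np.full(shape, BASE_VALUES[p])
        maps[p] = PerfusionMap(p, np.asarray(v, dtype=float), voxel_dims)
    if lesion is None:
        lesion = np.zeros(shape, dtype=bool)
    if hemisphere is None:
        hemisphere = np.ones(shape, dtype=bool)
    return CohortPatient(patient_id, group, maps,
                         LesionMask(np.asarray(lesion), voxel_dims),
                         np.asarray(hemisphere, dtype=bool))


@pytest.fixture
def make_patient():
    return build_patient


@pytest.fixture(scope="session")
def default_cohort():
    """The default-condition synthetic cohort (93 + 68 patients, 32³ grids)."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 16³ cohort for tests that refit models repeatedly."""
    config = SimulationConfig(n_recanalized=10, n_persistent=6,
                              shape=(16, 16, 16), seed=42)
    return simulate_cohort(config)
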