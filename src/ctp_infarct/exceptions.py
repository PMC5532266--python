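"""Exception hierarchy shared across the package."""


class CTPError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(CTPError):
    """Grid shapes or voxel dimensions disagree between a patient's volumes."""


class ManifestError(CTPError):
    """Cohort manifest is malformed: unknown group label, missing file/column."""


class ValidationError(CTPError):
    """An input violates a documented invariant (non-positive voxel size,
    probability outside [0, 1], parameter mismatch between model and map...)."""


class SampleSpaceError(CTPError):
    """Voxel sample assembly produced an empty or unusable sample set."""


class DegenerateROCError(CTPError):
    """ROC analysis received a single outcome class."""


class SeparationError(CTPError):
    """Logistic likelihood is unbounded (complete or quasi-complete
    separation of the predictor by outcome)."""


class ConvergenceError(CTPError):
    """Iterative maximum-likelihood fit failed to converge."""


class PairingError(CTPError):
    """Paired comparison received records that do not pair by patient."""
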