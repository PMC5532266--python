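"""Volumetric image I/O and per-patient geometry validation.

CT-perfusion post-processing yields, per patient, four co-registered 3-D
parameter maps — cerebral blood flow (CBF, ml·100 g⁻¹·min⁻¹), cerebral blood
volume (CBV, ml·100 g⁻¹), mean transit time (MTT, s) and time to drain
(TTD, s) — plus a binary follow-up infarct lesion mask and a binary mask of
parenchymal voxels in the ischemic hemisphere.  All volumes are exchanged as
NIfTI-1 files; voxel dimensions are taken from the NIfTI header.  Inputs are
assumed already co-registered and slice-interpolated upstream: no resampling
is performed here.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import GeometryError, ManifestError, ValidationError


class Parameter(str, Enum):
    """The four perfusion parameters used as univariate predictors."""

    CBF = "CBF"
    CBV = "CBV"
    MTT = "MTT"
    TTD = "TTD"


#: Physical units of each parameter map.
PARAMETER_UNITS: dict[Parameter, str] = {
    Parameter.CBF: "ml·100g⁻¹·min⁻¹",
    Parameter.CBV: "ml·100g⁻¹",
    Parameter.MTT: "s",
    Parameter.TTD: "s",
}

#: Parameters whose values *drop* in ischemia (flow/volume); the timing
#: parameters rise instead.  This fixes the classification direction.
FLOW_PARAMETERS = frozenset({Parameter.CBF, Parameter.CBV})
TIMING_PARAMETERS = frozenset({Parameter.MTT, Parameter.TTD})


class Group(str, Enum):
    """Recanalization outcome after endovascular therapy."""

    RECANALIZED = "RECANALIZED"  # TICI 2b-3, successful recanalization
    PERSISTENT = "PERSISTENT"    # TICI 0-2a, persistent occlusion


#: Accepted manifest spellings of the two groups.
GROUP_LABELS: dict[str, Group] = {
    "TICI 2B-3": Group.RECANALIZED,
    "TICI2B-3": Group.RECANALIZED,
    "RECANALIZED": Group.RECANALIZED,
    "TICI 0-2A": Group.PERSISTENT,
    "TICI0-2A": Group.PERSISTENT,
    "PERSISTENT": Group.PERSISTENT,
}

#: Manifest columns holding image paths, in canonical order.
MANIFEST_IMAGE_COLUMNS = (
    "cbf_path", "cbv_path", "mtt_path", "ttd_path",
    "lesion_path", "hemisphere_path",
)


def parse_group(label: str | Group) -> Group:
    """Map a manifest group label (e.g. ``"TICI 2b-3"``) to a :class:`Group`."""
    if isinstance(label, Group):
        return label
    key = str(label).strip().upper()
    try:
        return GROUP_LABELS[key]
    except KeyError:
        raise ManifestError(
            f"unknown group label {label!r}; expected one of "
            f"{sorted(set(GROUP_LABELS))}"
        ) from None


def voxel_volume_ml(obj) -> float:
    """Volume of a single voxel in millilitres.

    Accepts a :class:`PerfusionMap`/:class:`LesionMask` or a ``(dx, dy, dz)``
    triple in millimetres; 1 ml = 1000 mm³.
    """
    dims = getattr(obj, "voxel_dims", obj)
    dx, dy, dz = (float(d) for d in dims)
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValidationError(f"voxel dimensions must be positive, got {dims}")
    return dx * dy * dz / 1000.0


@dataclass
class PerfusionMap:
    """One perfusion parameter's 3-D scalar field with voxel geometry.

    ``valid_mask`` marks voxels carrying a defined value: finite entries
    intersected with the parenchyma mask supplied by the caller (exclusion of
    non-parenchymal voxels happens upstream and is represented by the mask
    only).
    """

    parameter: Parameter
    values: np.ndarray
    voxel_dims: tuple[float, float, float]
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.parameter = Parameter(self.parameter)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError(
                f"{self.parameter.value} map must be 3-D, got shape {self.values.shape}"
            )
        if any(d <= 0 for d in self.voxel_dims):
            raise ValidationError(
                f"voxel dimensions must be positive, got {self.voxel_dims}"
            )
        self.voxel_dims = tuple(float(d) for d in self.voxel_dims)
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool) & np.isfinite(
                self.values
            )
        if self.valid_mask.shape != self.values.shape:
            raise GeometryError(
                f"valid_mask shape {self.valid_mask.shape} does not match "
                f"values shape {self.values.shape}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        return voxel_volume_ml(self.voxel_dims)


@dataclass
class LesionMask:
    """Binary follow-up infarct mask (1 = infarct) on the patient grid."""

    values: np.ndarray
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.dtype != bool:
            arr = np.asarray(arr, dtype=float) > 0.5
        if arr.ndim != 3:
            raise ValidationError(f"lesion mask must be 3-D, got shape {arr.shape}")
        self.values = arr
        if any(d <= 0 for d in self.voxel_dims):
            raise ValidationError(
                f"voxel dimensions must be positive, got {self.voxel_dims}"
            )
        self.voxel_dims = tuple(float(d) for d in self.voxel_dims)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        return voxel_volume_ml(self.voxel_dims)


@dataclass
class CohortPatient:
    """All per-patient inputs: four maps, lesion mask, hemisphere mask, group."""

    patient_id: str
    group: Group
    maps: dict[Parameter, PerfusionMap]
    lesion: LesionMask
    hemisphere_mask: np.ndarray

    def __post_init__(self) -> None:
        self.group = parse_group(self.group)
        self.maps = {Parameter(k): v for k, v in self.maps.items()}
        missing = [p.value for p in Parameter if p not in self.maps]
        if missing:
            raise ManifestError(
                f"patient {self.patient_id!r} is missing maps: {missing}"
            )
        self.hemisphere_mask = np.asarray(self.hemisphere_mask)
        if self.hemisphere_mask.dtype != bool:
            self.hemisphere_mask = np.asarray(self.hemisphere_mask, dtype=float) > 0.5
        ref = self.maps[Parameter.CBF]
        for p, m in self.maps.items():
            _check_geometry(self.patient_id, f"{p.value} map", m.shape, m.voxel_dims,
                            ref.shape, ref.voxel_dims)
        _check_geometry(self.patient_id, "lesion mask", self.lesion.shape,
                        self.lesion.voxel_dims, ref.shape, ref.voxel_dims)
        if self.hemisphere_mask.shape != ref.shape:
            raise GeometryError(
                f"patient {self.patient_id!r}: hemisphere mask shape "
                f"{self.hemisphere_mask.shape} != map shape {ref.shape}"
            )
        if not self.hemisphere_mask.any():
            raise ValidationError(
                f"patient {self.patient_id!r}: hemisphere mask is empty"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.maps[Parameter.CBF].shape

    @property
    def voxel_dims(self) -> tuple[float, float, float]:
        return self.maps[Parameter.CBF].voxel_dims

    @property
    def voxel_volume_ml(self) -> float:
        return voxel_volume_ml(self.voxel_dims)


def _check_geometry(pid, what, shape, dims, ref_shape, ref_dims, *, name=None):
    if shape != ref_shape:
        raise GeometryError(
            f"patient {pid!r}: {name or what} has grid shape {shape}, "
            f"expected {ref_shape}"
        )
    if not np.allclose(dims, ref_dims, rtol=1e-4, atol=1e-4):
        raise GeometryError(
            f"patient {pid!r}: {name or what} has voxel dims {dims}, "
            f"expected {ref_dims}"
        )


# ---------------------------------------------------------------------------
# NIfTI round trip
# ---------------------------------------------------------------------------

def _load_nifti(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def write_volume(path: str | os.PathLike, values: np.ndarray,
                 voxel_dims: tuple[float, float, float]) -> None:
    """Write a 3-D array as NIfTI-1 with a diagonal voxel-scaling affine."""
    arr = np.asarray(values)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    affine = np.diag([voxel_dims[0], voxel_dims[1], voxel_dims[2], 1.0])
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine)
    img.header.set_zooms(voxel_dims)
    nib.save(img, str(path))


def read_map(path: str | os.PathLike, parameter: Parameter,
             parenchyma_mask: np.ndarray | None = None) -> PerfusionMap:
    """Read one parameter map from NIfTI; voxel dims come from the header."""
    data, zooms = _load_nifti(path)
    return PerfusionMap(Parameter(parameter), data, zooms, parenchyma_mask)


def read_patient(paths: Mapping[str, str | os.PathLike],
                 manifest_row: Mapping[str, str]) -> CohortPatient:
    """Build a geometry-validated :class:`CohortPatient` from image files.

    ``paths`` maps the manifest image columns (``cbf_path`` ... ``hemisphere_path``)
    to file paths; ``manifest_row`` supplies ``patient_id`` and ``group``.
    Mask files are coerced to boolean with any value > 0.5 mapped to true.
    """
    pid = str(manifest_row["patient_id"])
    group = parse_group(manifest_row["group"])
    for col in MANIFEST_IMAGE_COLUMNS:
        if col not in paths:
            raise ManifestError(f"patient {pid!r}: missing manifest column {col!r}")
        if not Path(paths[col]).exists():
            raise ManifestError(
                f"patient {pid!r}: file not found for {col!r}: {paths[col]}"
            )

    hemi, hemi_zooms = _load_nifti(paths["hemisphere_path"])
    hemi = hemi > 0.5
    lesion_data, lesion_zooms = _load_nifti(paths["lesion_path"])
    maps: dict[Parameter, PerfusionMap] = {}
    ref_shape, ref_dims = None, None
    for parameter, col in zip(Parameter, MANIFEST_IMAGE_COLUMNS[:4]):
        data, zooms = _load_nifti(paths[col])
        if ref_shape is None:
            ref_shape, ref_dims = data.shape, zooms
        else:
            _check_geometry(pid, col, data.shape, zooms, ref_shape, ref_dims,
                            name=str(paths[col]))
        maps[parameter] = PerfusionMap(parameter, data, zooms, hemi)
    _check_geometry(pid, "lesion", lesion_data.shape, lesion_zooms, ref_shape,
                    ref_dims, name=str(paths["lesion_path"]))
    _check_geometry(pid, "hemisphere", hemi.shape, hemi_zooms, ref_shape, ref_dims,
                    name=str(paths["hemisphere_path"]))
    lesion = LesionMask(lesion_data, lesion_zooms)
    return CohortPatient(pid, group, maps, lesion, hemi)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read the cohort manifest CSV and validate its columns."""
    df = pd.read_csv(path, dtype=str)
    required = {"patient_id", "group", *MANIFEST_IMAGE_COLUMNS}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ManifestError(f"manifest {path} is missing columns: {missing}")
    return df


def read_cohort(manifest_path: str | os.PathLike) -> list[CohortPatient]:
    """Read every patient referenced by a manifest CSV.

    Relative image paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    cohort = []
    for _, row in df.iterrows():
        paths = {
            col: (base / row[col] if not os.path.isabs(row[col]) else Path(row[col]))
            for col in MANIFEST_IMAGE_COLUMNS
        }
        cohort.append(read_patient(paths, row))
    return cohort
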