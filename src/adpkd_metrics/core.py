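"""Core containers: voxel grids, label/intensity volumes, series, exams.

Everything downstream (volumetry, fat fraction, confinement...) operates on
these types. A :class:`LabelVolume` is an integer-coded multi-organ
segmentation on a physical grid; an :class:`IntensityVolume` is the signal
it was derived from; a :class:`SeriesRecord` bundles one acquired pulse
sequence with its metadata; an :class:`ExamStudy` is one patient visit.

Conventions
-----------
* voxel indices are 0-based; axis order is (x, y, z) with z the slice axis;
* world coordinate of voxel (i, j, k) = origin + (i, j, k) * spacing along
  the oriented axes; bounding boxes are half-open ``[lo, hi)``;
* orientation is a per-axis anatomical direction label, RAS by default:
  axis 0 -> right/left, axis 1 -> anterior/posterior, axis 2 ->
  superior/inferior (craniocaudal).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Mapping, Sequence

import numpy as np

from .errors import GeometryError, InputError, RegistryError

__all__ = [
    "VoxelGrid",
    "LabelVolume",
    "IntensityVolume",
    "SequenceClass",
    "SeriesRecord",
    "SubjectContext",
    "ExamStudy",
    "VOLUMETRY_ELIGIBLE",
    "MM3_PER_ML",
]

#: cubic millimetres per millilitre
MM3_PER_ML = 1000.0

# anatomical axis names keyed by direction-label pair
_AXIS_NAMES = {
    frozenset("RL"): "left-right",
    frozenset("AP"): "anteroposterior",
    frozenset("SI"): "craniocaudal",
}


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel lattice with physical spacing and placement.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis; each component >= 1.
    spacing : tuple of float
        Physical size of one voxel along each axis, in mm; all > 0.
    orientation : tuple of str
        One-letter anatomical direction label per axis (RAS default).
    origin : tuple of float
        World coordinate of voxel (0, 0, 0), in mm.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    orientation: tuple[str, str, str] = ("R", "A", "S")
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise GeometryError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 positive reals, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of a single voxel in mm^3 (product of the spacings)."""
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (diagonal spacing, translation origin)."""
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def axis_name(self, axis: int) -> str:
        """Anatomical name of a grid axis (e.g. 'craniocaudal' for S/I)."""
        label = self.orientation[axis].upper()
        for pair, name in _AXIS_NAMES.items():
            if label in pair:
                return name
        return f"axis-{axis}"

    def slice_positions(self, axis: int = 2) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def compatible_with(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


def _check_array(grid: VoxelGrid, arr: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(arr)
    if tuple(arr.shape) != grid.shape:
        raise GeometryError(f"{what} shape {arr.shape} does not match grid {grid.shape}")
    return arr


@dataclass
class LabelVolume:
    """Integer-coded segmentation: the substrate of all volumetry.

    ``registry`` maps every label code that may occur to a structure name
    (organs, cysts, fluids, fat/muscle compartments, the saline QC bag).
    Construction validates that every nonzero code present in ``codes`` is
    registered; an unknown code raises :class:`RegistryError` naming it.
    """

    grid: VoxelGrid
    codes: np.ndarray
    registry: Mapping[int, str]

    def __post_init__(self) -> None:
        self.codes = _check_array(self.grid, self.codes, "label").astype(np.int32, copy=False)
        if self.codes.min() < 0:
            raise RegistryError("label codes must be non-negative")
        self.registry = {int(k): str(v) for k, v in self.registry.items()}
        present = set(np.unique(self.codes).tolist()) - {0}
        unknown = sorted(present - set(self.registry))
        if unknown:
            raise RegistryError(f"label code(s) {unknown} absent from registry")

    def mask(self, code: int) -> np.ndarray:
        """Boolean mask of one structure; the code must be registered."""
        if int(code) not in self.registry:
            raise RegistryError(f"code {code} absent from registry")
        return self.codes == int(code)

    def code_for(self, name: str) -> int:
        """Reverse registry lookup by structure name."""
        for code, n in self.registry.items():
            if n == name:
                return code
        raise RegistryError(f"structure {name!r} absent from registry")


@dataclass
class IntensityVolume:
    """Real-valued MR signal on a voxel grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_array(self.grid, self.values, "intensity").astype(
            np.float64, copy=False
        )
        if not np.all(np.isfinite(self.values)):
            raise InputError("intensity values must be finite")


class SequenceClass(str, enum.Enum):
    """Pulse-sequence category; drives eligibility for volumetry."""

    T2 = "T2"
    SSFP = "SSFP"
    SSFSE = "SSFSE"
    T1_IN_PHASE = "T1_in_phase"
    T1_OUT_OF_PHASE = "T1_out_of_phase"
    T1_WATER = "T1_water"
    T1_FAT = "T1_fat"
    DWI = "DWI"
    ADC = "ADC"
    LOCALIZER = "localizer"
    CALIBRATION = "calibration"
    OTHER = "other"


#: sequence classes whose geometry is trusted for volume measurement;
#: localizer, calibration, DWI and ADC maps are always excluded because of
#: low resolution and geometric distortion.
VOLUMETRY_ELIGIBLE = frozenset(
    {
        SequenceClass.T2,
        SequenceClass.SSFP,
        SequenceClass.SSFSE,
        SequenceClass.T1_IN_PHASE,
        SequenceClass.T1_OUT_OF_PHASE,
        SequenceClass.T1_WATER,
        SequenceClass.T1_FAT,
    }
)


@dataclass
class SeriesRecord:
    """One acquired sequence: intensity volume plus acquisition metadata.

    ``acquisition_times`` are per-image timestamps in seconds since
    midnight; a series' representative time is their mean (per-image
    timestamps are instantaneous but dynamic metrics are per-series).
    """

    series_id: str
    sequence_class: SequenceClass
    volume: IntensityVolume
    acquisition_times: Sequence[float]
    echo_index: int | None = None
    b_value: float | None = None

    def __post_init__(self) -> None:
        self.sequence_class = SequenceClass(self.sequence_class)
        times = [float(t) for t in self.acquisition_times]
        if not times:
            raise InputError(f"series {self.series_id}: acquisition_times is empty")
        if any(not (0.0 <= t < 86400.0) for t in times):
            raise InputError(f"series {self.series_id}: timestamps outside [0, 86400)")
        self.acquisition_times = times
        if self.sequence_class is SequenceClass.DWI and self.b_value is None:
            raise InputError(f"series {self.series_id}: DWI series must carry a b_value")

    @property
    def mean_time(self) -> float:
        """Representative acquisition time (seconds since midnight)."""
        return float(np.mean(self.acquisition_times))

    def with_volume(self, volume: IntensityVolume, **kw) -> "SeriesRecord":
        return replace(self, volume=volume, **kw)


@dataclass(frozen=True)
class SubjectContext:
    """Subject metadata needed by height/weight-normalized biomarkers."""

    height_m: float
    weight_kg: float
    sex: str
    age_years: float

    def __post_init__(self) -> None:
        if self.height_m <= 0:
            raise InputError("height must be positive (metres)")
        if self.weight_kg <= 0:
            raise InputError("weight must be positive (kg)")
        if self.age_years <= 0:
            raise InputError("age must be positive (years)")


@dataclass
class ExamStudy:
    """One exam: subject context, acquired series, and their label maps."""

    subject: SubjectContext
    exam_date: date
    series: list[SeriesRecord] = field(default_factory=list)
    labels: dict[str, LabelVolume] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {s.series_id for s in self.series}
        for sid, lab in self.labels.items():
            if sid not in ids:
                raise InputError(f"label volume references unknown series {sid!r}")
            rec = self.get_series(sid)
            if not lab.grid.compatible_with(rec.volume.grid):
                raise GeometryError(f"label grid for series {sid!r} mismatches its series grid")

    def get_series(self, series_id: str) -> SeriesRecord:
        for s in self.series:
            if s.series_id == series_id:
                return s
        raise KeyError(series_id)
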