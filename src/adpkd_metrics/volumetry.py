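"""Label-map volumetry: volume, dimension, presence, aggregation, QC.

Three basic metrics are read off a segmentation: organ *volume* (voxel
count × voxel volume), organ *dimensions* (3D bounding box extents in
anatomical axes), and feature *presence* (with the series and slices where
a small finding lives, so a reader can verify it). On top sit the
multi-sequence aggregation — each organ is measured on every geometrically
trustworthy sequence of an exam, reported as mean ± SD with outlier
flagging — and the saline-bag volume check used as a scanner-side QC
reference.

Volumes are kept at full precision here; rounding to the nearest mL is
presentational and happens only in the report layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    MM3_PER_ML,
    LabelVolume,
    SequenceClass,
    VOLUMETRY_ELIGIBLE,
)
from .errors import EligibilityError, EmptyStructureError, InputError

__all__ = [
    "OrganMeasurement",
    "VolumeSummary",
    "PresenceFinding",
    "SalineQC",
    "organ_volume",
    "bounding_dimensions",
    "detect_presence",
    "summarize_across_sequences",
    "saline_qc",
    "measure_exam",
    "measurements_table",
    "DEFAULT_MIN_PRESENCE_ML",
    "DEFAULT_OUTLIER_FRACTION",
]

#: findings smaller than this are still reported but flagged absent/small
DEFAULT_MIN_PRESENCE_ML = 0.05
#: flag a per-sequence volume deviating from the median by more than this
DEFAULT_OUTLIER_FRACTION = 0.10


@dataclass
class OrganMeasurement:
    organ: str
    series_id: str
    volume_ml: float
    dims_mm: dict[str, float] | None  # anatomical axis name -> extent
    slice_extent: tuple[tuple[int, int], ...] | None  # inclusive (lo, hi) per axis
    sequence_class: SequenceClass | None = None


@dataclass
class VolumeSummary:
    organ: str
    per_series: list[tuple[str, float]]
    mean_ml: float
    sd_ml: float
    n: int
    outlier_flags: list[str] = field(default_factory=list)


@dataclass
class PresenceFinding:
    feature: str
    present: bool
    series_id: str
    slice_indices: list[int]
    volume_ml: float


@dataclass
class SalineQC:
    measured_ml: float
    nominal_ml: float
    relative_error: float
    passed: bool


# ---------------------------------------------------------------------------
# Per-volume metrics
# ---------------------------------------------------------------------------

def organ_volume(labels: LabelVolume, code: int) -> float:
    """Structure volume in mL: voxel count × voxel volume.

    The count is exact integer arithmetic; only the final unit conversion
    (mm³ → mL) is floating point.
    """
    count = int(np.count_nonzero(labels.mask(code)))
    return count * labels.grid.voxel_volume_mm3 / MM3_PER_ML


def bounding_dimensions(
    labels: LabelVolume, code: int
) -> tuple[dict[str, float], tuple[tuple[int, int], ...]]:
    """Axis-aligned 3D bounding-box extents of a structure, in mm.

    Extent on an axis is ``(max_index - min_index + 1) * spacing`` — the
    physical size of the box of whole voxels — keyed by the anatomical axis
    name (craniocaudal / left-right / anteroposterior). Also returns the
    inclusive voxel index range per axis. The box ignores concavity: an
    L-shaped organ reports its enclosing box.
    """
    mask = labels.mask(code)
    if not mask.any():
        raise EmptyStructureError(f"code {code} has no voxels; no bounding box")
    dims: dict[str, float] = {}
    extents: list[tuple[int, int]] = []
    for axis in range(3):
        proj = np.any(mask, axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        lo, hi = int(idx[0]), int(idx[-1])
        extents.append((lo, hi))
        dims[labels.grid.axis_name(axis)] = (hi - lo + 1) * labels.grid.spacing[axis]
    return dims, tuple(extents)


def detect_presence(
    labels: LabelVolume,
    code: int,
    min_volume_ml: float = DEFAULT_MIN_PRESENCE_ML,
    series_id: str = "",
) -> PresenceFinding:
    """Presence/absence of a feature, documenting where it was seen.

    A feature counts as present when its volume reaches ``min_volume_ml``;
    the volume and the axial slice indices containing the code are reported
    either way, so sub-threshold findings remain reviewable.
    """
    if min_volume_ml < 0:
        raise InputError("min_volume_ml must be >= 0")
    mask = labels.mask(code)
    vol = organ_volume(labels, code)
    slices = np.flatnonzero(np.any(mask, axis=(0, 1))).tolist()
    return PresenceFinding(
        feature=labels.registry[int(code)],
        present=vol >= min_volume_ml and vol > 0,
        series_id=series_id,
        slice_indices=slices,
        volume_ml=vol,
    )


# ---------------------------------------------------------------------------
# Multi-sequence aggregation and QC
# ---------------------------------------------------------------------------

def summarize_across_sequences(
    measurements: Sequence[OrganMeasurement],
    eligible_classes: Iterable[SequenceClass] = VOLUMETRY_ELIGIBLE,
    outlier_fraction: float = DEFAULT_OUTLIER_FRACTION,
) -> VolumeSummary:
    """Mean ± SD of one organ's volume across eligible sequences.

    Measurements from excluded sequence classes (localizer, calibration,
    DWI, ADC) never enter the statistics. The SD is the sample standard
    deviation; with a single eligible series it is reported as 0 with
    ``n=1``. A series is flagged as an outlier when its volume deviates
    from the median of the eligible volumes by more than
    ``outlier_fraction`` of that median (requires n >= 3) — the trigger for
    re-review of images and segmentations.
    """
    eligible_classes = frozenset(SequenceClass(c) for c in eligible_classes)
    usable = [
        m
        for m in measurements
        if m.sequence_class is None or m.sequence_class in eligible_classes
    ]
    if not usable:
        raise EligibilityError("no measurement from an eligible sequence class")
    organs = {m.organ for m in usable}
    if len(organs) != 1:
        raise InputError(f"summary expects one organ, got {sorted(organs)}")
    vols = np.array([m.volume_ml for m in usable], dtype=float)
    mean = float(vols.mean())
    sd = float(vols.std(ddof=1)) if vols.size > 1 else 0.0
    flags: list[str] = []
    if vols.size >= 3:
        med = float(np.median(vols))
        if med > 0:
            flags = [
                m.series_id
                for m, v in zip(usable, vols)
                if abs(v - med) > outlier_fraction * med
            ]
    return VolumeSummary(
        organ=usable[0].organ,
        per_series=[(m.series_id, m.volume_ml) for m in usable],
        mean_ml=mean,
        sd_ml=sd,
        n=int(vols.size),
        outlier_flags=flags,
    )


def saline_qc(
    measured_ml: float, nominal_ml: float = 500.0, tolerance_fraction: float = 0.05
) -> SalineQC:
    """Check the image-derived volume of the reference saline bag.

    A 500 mL bag placed in the field of view validates volumetry end to
    end; the check passes when the relative error is within
    ``tolerance_fraction``.
    """
    if nominal_ml <= 0:
        raise InputError("nominal volume must be positive")
    rel = abs(measured_ml - nominal_ml) / nominal_ml
    return SalineQC(
        measured_ml=float(measured_ml),
        nominal_ml=float(nominal_ml),
        relative_error=rel,
        passed=rel <= tolerance_fraction,
    )


# ---------------------------------------------------------------------------
# Exam-level convenience
# ---------------------------------------------------------------------------

def measure_exam(exam, codes: Iterable[int] | None = None) -> list[OrganMeasurement]:
    """Measure every (or selected) labeled structure on every labeled series."""
    out: list[OrganMeasurement] = []
    for sid, labels in exam.labels.items():
        seq_class = exam.get_series(sid).sequence_class
        wanted = sorted(set(codes) if codes is not None else set(labels.registry))
        for code in wanted:
            vol = organ_volume(labels, code)
            if vol > 0:
                dims, extent = bounding_dimensions(labels, code)
            else:
                dims, extent = None, None
            out.append(
                OrganMeasurement(
                    organ=labels.registry[int(code)],
                    series_id=sid,
                    volume_ml=vol,
                    dims_mm=dims,
                    slice_extent=extent,
                    sequence_class=seq_class,
                )
            )
    return out


def measurements_table(measurements: Sequence[OrganMeasurement]) -> pd.DataFrame:
    """Tidy CSV-ready table: organ, series, volume, bounding dimensions."""
    rows = []
    for m in measurements:
        row = {
            "organ": m.organ,
            "series_id": m.series_id,
            "sequence_class": m.sequence_class.value if m.sequence_class else "",
            "volume_ml": m.volume_ml,
        }
        if m.dims_mm:
            for name, val in m.dims_mm.items():
                row[f"dim_{name.replace('-', '_')}_mm"] = val
        rows.append(row)
    return pd.DataFrame(rows)
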