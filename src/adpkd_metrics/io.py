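"""Volume/metadata I/O and acquisition normalization.

Volumes travel as NIfTI-1 (via nibabel) with a JSON sidecar per series
carrying ``{series_id, sequence_class, acquisition_times, echo_index,
b_value}`` and the label registry as JSON ``{code: name}``. DICOM is read
only for metadata (time tags); voxel conversion is delegated to dedicated
converters such as dcm2niix.

Acquisition normalization covers the two pre-analysis transforms a
multi-breath-hold abdominal protocol needs:

* :func:`merge_stacked_series` joins an "upper" and "lower" breath-hold
  stack into one series, discarding duplicated overlap slices and reslicing
  to the finer in-plane grid when resolutions differ;
* :func:`split_composite_series` breaks multi-echo (e.g. two-point Dixon)
  and multi-b-value DWI containers into one single-tag series each, so each
  behaves like an ordinary 3D acquisition downstream.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .core import (
    IntensityVolume,
    LabelVolume,
    SequenceClass,
    SeriesRecord,
    VoxelGrid,
)
from .errors import (
    CoverageGapError,
    FormatError,
    GeometryError,
    InputError,
    TagError,
    TimeParseError,
)

__all__ = [
    "read_volume",
    "write_volume",
    "read_sidecar",
    "write_sidecar",
    "read_registry",
    "write_registry",
    "read_exam",
    "write_exam",
    "merge_stacked_series",
    "FrameRecord",
    "CompositeSeries",
    "split_composite_series",
    "parse_acquisition_time",
    "extract_dicom_times",
]


# ---------------------------------------------------------------------------
# NIfTI + sidecars
# ---------------------------------------------------------------------------

def _grid_from_image(img) -> VoxelGrid:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise FormatError(f"non-positive voxel spacing {zooms} in header")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VoxelGrid(shape=tuple(img.shape[:3]), spacing=zooms, origin=origin)


def read_volume(
    path: str | Path, registry: Mapping[int, str] | None = None
) -> IntensityVolume | LabelVolume:
    """Read a NIfTI-1 volume.

    With ``registry`` given the file is interpreted as an integer label map
    and validated against it (an unregistered nonzero code raises
    :class:`~adpkd_metrics.errors.RegistryError` naming the code);
    without, it is returned as an :class:`IntensityVolume`.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as NIfTI-1: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    grid = _grid_from_image(img)
    if registry is not None:
        return LabelVolume(grid=grid, codes=np.rint(data).astype(np.int32), registry=registry)
    return IntensityVolume(grid=grid, values=data.astype(np.float64))


def write_volume(path: str | Path, volume: IntensityVolume | LabelVolume) -> Path:
    """Write a volume as NIfTI-1; label maps round-trip bit-exactly."""
    path = Path(path)
    if isinstance(volume, LabelVolume):
        data = volume.codes.astype(np.int32)
    else:
        data = volume.values.astype(np.float64)
    img = nib.Nifti1Image(data, affine=volume.grid.affine)
    img.header.set_zooms(volume.grid.spacing)
    nib.save(img, str(path))
    return path


def write_sidecar(path: str | Path, record: SeriesRecord) -> Path:
    meta = {
        "series_id": record.series_id,
        "sequence_class": record.sequence_class.value,
        "acquisition_times": list(record.acquisition_times),
        "echo_index": record.echo_index,
        "b_value": record.b_value,
    }
    path = Path(path)
    path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return path


def read_sidecar(path: str | Path) -> dict:
    meta = json.loads(Path(path).read_text())
    for key in ("series_id", "sequence_class", "acquisition_times"):
        if key not in meta:
            raise FormatError(f"sidecar {path} missing required key {key!r}")
    return meta


def write_registry(path: str | Path, registry: Mapping[int, str]) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps({str(int(k)): str(v) for k, v in registry.items()}, indent=1, sort_keys=True)
        + "\n"
    )
    return path


def read_registry(path: str | Path) -> dict[int, str]:
    raw = json.loads(Path(path).read_text())
    return {int(k): str(v) for k, v in raw.items()}


# ---------------------------------------------------------------------------
# Exam-level directory layout
# ---------------------------------------------------------------------------
# <dir>/subject.json                       subject context + exam date
# <dir>/registry.json                      label registry {code: name}
# <dir>/<series_id>.nii.gz + .json         intensity volume + sidecar
# <dir>/<series_id>_labels.nii.gz          label map for that series

def write_exam(exam, out_dir: str | Path) -> Path:
    """Write an :class:`~adpkd_metrics.core.ExamStudy` to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subj = {
        "height_m": exam.subject.height_m,
        "weight_kg": exam.subject.weight_kg,
        "sex": exam.subject.sex,
        "age_years": exam.subject.age_years,
        "exam_date": exam.exam_date.isoformat(),
    }
    (out / "subject.json").write_text(json.dumps(subj, indent=1, sort_keys=True) + "\n")
    registry: dict[int, str] = {}
    for rec in exam.series:
        write_volume(out / f"{rec.series_id}.nii.gz", rec.volume)
        write_sidecar(out / f"{rec.series_id}.json", rec)
        lab = exam.labels.get(rec.series_id)
        if lab is not None:
            write_volume(out / f"{rec.series_id}_labels.nii.gz", lab)
            registry.update(lab.registry)
    write_registry(out / "registry.json", registry)
    return out


def read_exam(exam_dir: str | Path):
    """Read an exam directory written by :func:`write_exam`."""
    from datetime import date as _date

    from .core import ExamStudy, SubjectContext

    d = Path(exam_dir)
    subj_meta = json.loads((d / "subject.json").read_text())
    subject = SubjectContext(
        height_m=subj_meta["height_m"],
        weight_kg=subj_meta["weight_kg"],
        sex=subj_meta.get("sex", "unknown"),
        age_years=subj_meta["age_years"],
    )
    exam_date = _date.fromisoformat(subj_meta["exam_date"])
    registry = read_registry(d / "registry.json")
    series, labels = [], {}
    for sidecar in sorted(d.glob("*.json")):
        # a sidecar is any JSON with a matching intensity volume next to it
        if not (d / f"{sidecar.stem}.nii.gz").exists():
            continue
        meta = read_sidecar(sidecar)
        sid = meta["series_id"]
        vol = read_volume(d / f"{sid}.nii.gz")
        series.append(
            SeriesRecord(
                series_id=sid,
                sequence_class=SequenceClass(meta["sequence_class"]),
                volume=vol,
                acquisition_times=meta["acquisition_times"],
                echo_index=meta.get("echo_index"),
                b_value=meta.get("b_value"),
            )
        )
        lab_path = d / f"{sid}_labels.nii.gz"
        if lab_path.exists():
            labels[sid] = read_volume(lab_path, registry=registry)
    return ExamStudy(subject=subject, exam_date=exam_date, series=series, labels=labels)


# ---------------------------------------------------------------------------
# Multi-breath-hold merging
# ---------------------------------------------------------------------------

def _resample_inplane(values: np.ndarray, grid: VoxelGrid, target_xy: tuple[float, float],
                      order: int) -> tuple[np.ndarray, VoxelGrid]:
    """Reslice a stack in-plane to a target (x, y) spacing, preserving extent."""
    sx, sy = grid.spacing[0], grid.spacing[1]
    tx, ty = target_xy
    if np.isclose(sx, tx) and np.isclose(sy, ty):
        return values, grid
    new_nx = int(round(grid.shape[0] * sx / tx))
    new_ny = int(round(grid.shape[1] * sy / ty))
    zoom = (new_nx / grid.shape[0], new_ny / grid.shape[1], 1.0)
    out = ndimage.zoom(values, zoom, order=order, mode="nearest", grid_mode=True)
    new_grid = VoxelGrid(
        shape=(new_nx, new_ny, grid.shape[2]),
        spacing=(tx, ty, grid.spacing[2]),
        orientation=grid.orientation,
        origin=grid.origin,
    )
    return out, new_grid


def merge_stacked_series(upper: SeriesRecord, lower: SeriesRecord) -> SeriesRecord:
    """Combine upper/lower breath-hold stacks into one series.

    Overlapping slice positions are represented once, keeping the first
    (``upper``) series' slices — the extra overlapping slices of the second
    stack are discarded rather than averaged. If the two stacks differ in
    in-plane resolution, both are resliced (linear interpolation) to the
    finer spacing before stacking; the union of slice positions and hence
    the total physical extent is preserved.

    Raises
    ------
    InputError
        mismatched sequence_class or slice thickness.
    CoverageGapError
        the stacks are disjoint with a gap larger than one slice thickness.
    """
    if upper.sequence_class is not lower.sequence_class:
        raise InputError(
            f"cannot merge series of different classes "
            f"({upper.sequence_class.value} vs {lower.sequence_class.value})"
        )
    gu, gl = upper.volume.grid, lower.volume.grid
    if upper.volume.grid.orientation != lower.volume.grid.orientation:
        raise InputError("cannot merge series with different in-plane orientations")
    dz = gu.spacing[2]
    if not np.isclose(dz, gl.spacing[2], rtol=1e-6):
        raise InputError(
            f"slice thickness mismatch ({gu.spacing[2]} vs {gl.spacing[2]} mm); "
            "merge expects equal slice spacing"
        )
    # reslice both to the finer in-plane grid
    target_xy = (min(gu.spacing[0], gl.spacing[0]), min(gu.spacing[1], gl.spacing[1]))
    vu, gu = _resample_inplane(upper.volume.values, gu, target_xy, order=1)
    vl, gl = _resample_inplane(lower.volume.values, gl, target_xy, order=1)
    if vu.shape[:2] != vl.shape[:2]:
        raise GeometryError(
            f"in-plane extents differ after reslicing ({vu.shape[:2]} vs {vl.shape[:2]})"
        )

    # collect slices keyed by world z; upper first, lower only where new
    slices: list[tuple[float, np.ndarray]] = []
    for k, z in enumerate(gu.slice_positions()):
        slices.append((float(z), vu[:, :, k]))
    upper_z = np.array([z for z, _ in slices])
    for k, z in enumerate(gl.slice_positions()):
        if upper_z.size == 0 or np.min(np.abs(upper_z - z)) > 0.5 * dz:
            slices.append((float(z), vl[:, :, k]))
    slices.sort(key=lambda t: t[0])
    zs = np.array([z for z, _ in slices])
    gaps = np.diff(zs)
    if gaps.size and gaps.max() > 2.0 * dz + 1e-6:
        raise CoverageGapError(
            f"stacks leave a coverage gap of {gaps.max() - dz:.1f} mm "
            f"(> one slice thickness of {dz:g} mm)"
        )

    # place slices on the union grid; fill a missing position (gap of at
    # most one slice) by averaging its neighbours
    z0 = zs[0]
    n_z = int(round((zs[-1] - z0) / dz)) + 1
    out = np.full(vu.shape[:2] + (n_z,), np.nan)
    for z, sl in slices:
        out[:, :, int(round((z - z0) / dz))] = sl
    for k in range(n_z):
        if np.isnan(out[0, 0, k]):
            out[:, :, k] = 0.5 * (out[:, :, k - 1] + out[:, :, k + 1])

    grid = VoxelGrid(
        shape=out.shape,
        spacing=(target_xy[0], target_xy[1], dz),
        orientation=gu.orientation,
        origin=(gu.origin[0], gu.origin[1], float(z0)),
    )
    return SeriesRecord(
        series_id=f"{upper.series_id}+{lower.series_id}",
        sequence_class=upper.sequence_class,
        volume=IntensityVolume(grid=grid, values=out),
        acquisition_times=list(upper.acquisition_times) + list(lower.acquisition_times),
        echo_index=upper.echo_index,
        b_value=upper.b_value,
    )


# ---------------------------------------------------------------------------
# Composite-series splitting
# ---------------------------------------------------------------------------

@dataclass
class FrameRecord:
    """One 2D image of a composite acquisition with its tags."""

    data: np.ndarray
    slice_index: int
    acquisition_time: float
    echo_index: int | None = None
    b_value: float | None = None


@dataclass
class CompositeSeries:
    """Multi-echo or multi-b-value container awaiting splitting.

    ``grid`` describes a single-tag output volume (its z extent equals the
    number of slices per tag group).
    """

    series_id: str
    sequence_class: SequenceClass
    grid: VoxelGrid
    frames: list[FrameRecord] = field(default_factory=list)


#: echo ordering of a two-point Dixon acquisition: the out-of-phase echo is
#: acquired at the shorter echo time, in-phase at the longer.
_DIXON_CLASSES = (SequenceClass.T1_OUT_OF_PHASE, SequenceClass.T1_IN_PHASE)


def split_composite_series(
    composite: CompositeSeries, dixon: bool = False
) -> list[SeriesRecord]:
    """Split a composite container into one series per echo or b-value.

    Frames are grouped by echo index when any frame carries one, else by
    b-value; every frame must carry the discriminating tag. Image counts are
    conserved (the outputs partition the input). With ``dixon=True`` and
    exactly two echoes, outputs are classed out-of-phase (first echo) and
    in-phase (second echo).
    """
    frames = composite.frames
    if not frames:
        raise InputError(f"composite {composite.series_id} has no frames")
    by_echo = any(f.echo_index is not None for f in frames)
    key = (lambda f: f.echo_index) if by_echo else (lambda f: f.b_value)
    missing = [i for i, f in enumerate(frames) if key(f) is None]
    if missing:
        tag = "echo_index" if by_echo else "b_value"
        raise TagError(f"frames {missing} of {composite.series_id} missing {tag}")

    groups: dict = {}
    for f in frames:
        groups.setdefault(key(f), []).append(f)
    tags = sorted(groups)

    out: list[SeriesRecord] = []
    for pos, tag in enumerate(tags):
        grp = sorted(groups[tag], key=lambda f: f.slice_index)
        indices = [f.slice_index for f in grp]
        if indices != list(range(len(grp))):
            raise InputError(
                f"{composite.series_id} tag {tag}: slice indices {indices} do not "
                f"form 0..{len(grp) - 1}"
            )
        if len(grp) != composite.grid.shape[2]:
            raise GeometryError(
                f"{composite.series_id} tag {tag}: {len(grp)} slices vs grid "
                f"depth {composite.grid.shape[2]}"
            )
        values = np.stack([np.asarray(f.data, dtype=np.float64) for f in grp], axis=-1)
        seq_class = composite.sequence_class
        echo = tag if by_echo else None
        bval = None if by_echo else float(tag)
        if dixon and by_echo and len(tags) == 2:
            seq_class = _DIXON_CLASSES[pos]
        suffix = f"e{tag}" if by_echo else f"b{tag:g}"
        out.append(
            SeriesRecord(
                series_id=f"{composite.series_id}_{suffix}",
                sequence_class=seq_class,
                volume=IntensityVolume(grid=composite.grid, values=values),
                acquisition_times=[f.acquisition_time for f in grp],
                echo_index=echo,
                b_value=bval,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Time parsing
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(r"^(\d{2})(\d{2})(\d{2})(\.\d{1,6})?$")


def parse_acquisition_time(raw: str) -> float:
    """Parse a DICOM TM string (HHMMSS[.frac]) to seconds since midnight."""
    m = _TIME_RE.match(raw.strip())
    if m is None:
        raise TimeParseError(f"{raw!r} does not match HHMMSS[.frac]")
    hh, mm, ss = int(m.group(1)), int(m.group(2)), int(m.group(3))
    if hh > 23 or mm > 59 or ss > 59:
        raise TimeParseError(f"{raw!r} has out-of-range time components")
    frac = float(m.group(4)) if m.group(4) else 0.0
    return hh * 3600.0 + mm * 60.0 + ss + frac


def extract_dicom_times(source) -> list[float]:
    """Read AcquisitionTime tags from DICOM file path(s) or dataset(s).

    Only metadata is consumed; voxel data stay with the NIfTI path.
    """
    import pydicom

    if not isinstance(source, (list, tuple)):
        source = [source]
    times = []
    for item in source:
        ds = item if isinstance(item, pydicom.Dataset) else pydicom.dcmread(str(item))
        raw = getattr(ds, "AcquisitionTime", None)
        if raw is None:
            raise TagError("DICOM dataset missing AcquisitionTime")
        times.append(parse_acquisition_time(str(raw)))
    return times
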