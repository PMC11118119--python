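"""Synthetic abdominal-exam phantoms with known ground truth.

Real ADPKD exams cannot ship with the package, so every downstream metric
is exercised against phantoms: label maps rasterized from geometric
primitives (boxes, ellipsoids) on a physical voxel grid, with intensity
series synthesized on top (uniform organ levels plus optional Gaussian
noise). The generator records ground truth *at generation time* — organ
volumes from the very voxel sets it rasterized, the fat fraction and urine
rate it encoded — so tests compare measured against known values without
circularity.

What is emulated: organ geometries with known volumes; two-point Dixon
in-/out-of-phase pairs encoding a set fat fraction; time-stamped series with
a linearly filling bladder; a 500 mL reference saline bag; longitudinal
exponential TKV growth. What is not: MRI physics (coil shading, dielectric
artifact, partial volume at organ boundaries) and the segmentation step
itself — label maps are inputs to this tool, so noise is applied to
intensities only, never to labels.

Rasterization rule: a voxel belongs to a primitive iff its *center* lies
inside; this makes counts deterministic and oracle-checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    MM3_PER_ML,
    ExamStudy,
    IntensityVolume,
    LabelVolume,
    SequenceClass,
    SeriesRecord,
    SubjectContext,
    VoxelGrid,
)
from .errors import GeometryError, PhantomSpecError

__all__ = [
    "OrganPrimitive",
    "DixonSpec",
    "BladderSpec",
    "PhantomSpec",
    "GroundTruth",
    "rasterize",
    "load_spec",
    "spec_from_dict",
    "make_exam",
    "make_dixon_pair",
    "make_bladder_series",
    "make_growth_history",
    "SALINE_BAG_CODE",
]

#: label code reserved for the external 500 mL QC saline bag
SALINE_BAG_CODE = 99


@dataclass(frozen=True)
class OrganPrimitive:
    """One labeled structure: an axis-aligned box or ellipsoid.

    ``semi_axes_mm`` are half-extents: a box spans center ± semi_axes, an
    ellipsoid has those semi-axis lengths. ``intensity`` is the uniform
    signal level painted into synthesized series.
    """

    code: int
    name: str
    kind: str  # "box" | "ellipsoid"
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    intensity: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in ("box", "ellipsoid"):
            raise PhantomSpecError(f"unknown primitive kind {self.kind!r}")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise PhantomSpecError("semi-axes must be positive")


@dataclass(frozen=True)
class DixonSpec:
    """Fat content encoded into an in-/out-of-phase pair.

    Restricted to ``fat_fraction < 0.5``: the two-point method cannot
    distinguish fat-dominant voxels (signal magnitude is symmetric about
    FF = 0.5), so the phantom refuses to encode what the estimator could
    not recover.
    """

    fat_fraction: float
    in_phase_level: float = 100.0
    target_code: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.fat_fraction < 0.5):
            raise PhantomSpecError(
                f"fat_fraction must be in [0, 0.5) for two-point encoding, "
                f"got {self.fat_fraction}"
            )
        if self.in_phase_level <= 0:
            raise PhantomSpecError("in_phase_level must be positive")


@dataclass(frozen=True)
class BladderSpec:
    """Linearly filling bladder observed at a set of exam times."""

    weight_kg: float
    start_volume_ml: float
    rate_ml_per_min: float
    times_min: tuple[float, ...]
    start_clock_s: float = 8 * 3600.0  # exam starts 08:00:00

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times_min) <= 0):
            raise PhantomSpecError("bladder series times must be strictly increasing")
        if not np.isfinite(self.rate_ml_per_min):
            raise PhantomSpecError("bladder filling rate must be finite")


@dataclass
class PhantomSpec:
    """Full recipe for one synthetic exam. Fixed seed ⇒ identical output."""

    grid: VoxelGrid = field(
        default_factory=lambda: VoxelGrid(shape=(64, 64, 64), spacing=(2.0, 2.0, 2.0))
    )
    organs: list[OrganPrimitive] = field(default_factory=list)
    dixon: DixonSpec | None = None
    bladder: BladderSpec | None = None
    saline_bag_volume_ml: float | None = None
    noise_sd: float = 0.0
    background_level: float = 10.0
    sequence_classes: tuple[SequenceClass, ...] = (SequenceClass.T2,)
    subject: SubjectContext = field(
        default_factory=lambda: SubjectContext(
            height_m=1.70, weight_kg=70.0, sex="F", age_years=40.0
        )
    )
    exam_date: date = date(2024, 1, 15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows to be true about its output."""

    organ_volumes_ml: dict[str, float] = field(default_factory=dict)
    fat_fraction: float | None = None
    urine_rate_ml_kg_h: float | None = None
    bladder_volumes_ml: list[float] | None = None
    tkv_by_age: list[tuple[float, float]] | None = None


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _axis_centers(grid: VoxelGrid):
    return [grid.origin[a] + np.arange(grid.shape[a]) * grid.spacing[a] for a in range(3)]


def _check_inside(grid: VoxelGrid, prim: OrganPrimitive) -> None:
    for a in range(3):
        lo = grid.origin[a] - 0.5 * grid.spacing[a]
        hi = grid.origin[a] + (grid.shape[a] - 0.5) * grid.spacing[a]
        if prim.center_mm[a] - prim.semi_axes_mm[a] < lo or (
            prim.center_mm[a] + prim.semi_axes_mm[a] > hi
        ):
            raise GeometryError(
                f"primitive {prim.name!r} exceeds grid extent on axis {a}"
            )


def rasterize(grid: VoxelGrid, prim: OrganPrimitive) -> np.ndarray:
    """Boolean mask of one primitive under the center-inside rule."""
    _check_inside(grid, prim)
    cx, cy, cz = _axis_centers(grid)
    dx = (cx - prim.center_mm[0])[:, None, None]
    dy = (cy - prim.center_mm[1])[None, :, None]
    dz = (cz - prim.center_mm[2])[None, None, :]
    ax, ay, az = prim.semi_axes_mm
    if prim.kind == "box":
        return (np.abs(dx) <= ax) & (np.abs(dy) <= ay) & (np.abs(dz) <= az)
    return (dx / ax) ** 2 + (dy / ay) ** 2 + (dz / az) ** 2 <= 1.0


def _saline_bag_mask(grid: VoxelGrid, volume_ml: float, occupied: np.ndarray) -> np.ndarray:
    """Exactly volume/voxel_volume voxels, filled in raster order over
    still-unlabeled voxels (the bag sits outside the body, never inside an
    organ)."""
    n_target = volume_ml * MM3_PER_ML / grid.voxel_volume_mm3
    n = int(round(n_target))
    if abs(n - n_target) > 1e-6:
        raise PhantomSpecError(
            f"saline bag of {volume_ml} mL is not a whole number of voxels "
            f"at voxel volume {grid.voxel_volume_mm3} mm^3"
        )
    free = np.flatnonzero(~occupied.reshape(-1))
    if n > free.size:
        raise GeometryError("saline bag volume exceeds free grid capacity")
    mask = np.zeros(grid.shape, dtype=bool)
    mask.reshape(-1)[free[:n]] = True
    return mask


def _paint_series(
    spec: PhantomSpec,
    labels: LabelVolume,
    rng: np.random.Generator,
    series_id: str,
    seq_class: SequenceClass,
    time_s: float,
) -> SeriesRecord:
    values = np.full(spec.grid.shape, spec.background_level, dtype=np.float64)
    for prim in spec.organs:
        values[labels.codes == prim.code] = prim.intensity
    if spec.saline_bag_volume_ml is not None:
        values[labels.codes == SALINE_BAG_CODE] = 80.0
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    n_slices = spec.grid.shape[2]
    times = (time_s + np.arange(n_slices) * 0.5).tolist()  # ~0.5 s per image
    return SeriesRecord(
        series_id=series_id,
        sequence_class=seq_class,
        volume=IntensityVolume(grid=spec.grid, values=values),
        acquisition_times=times,
    )


def build_labels(spec: PhantomSpec) -> LabelVolume:
    """Rasterize a spec's primitives (and saline bag) into one label map."""
    codes = np.zeros(spec.grid.shape, dtype=np.int32)
    registry: dict[int, str] = {}
    for prim in spec.organs:
        codes[rasterize(spec.grid, prim)] = prim.code
        registry[prim.code] = prim.name
    if spec.saline_bag_volume_ml is not None:
        bag = _saline_bag_mask(spec.grid, spec.saline_bag_volume_ml, occupied=codes != 0)
        codes[bag] = SALINE_BAG_CODE
        registry[SALINE_BAG_CODE] = "saline_bag"
    return LabelVolume(grid=spec.grid, codes=codes, registry=registry)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def load_spec(path) -> PhantomSpec:
    """Load a :class:`PhantomSpec` from a YAML/JSON file."""
    import yaml
    from pathlib import Path

    raw = yaml.safe_load(Path(path).read_text())
    return spec_from_dict(raw)


def spec_from_dict(raw: dict) -> PhantomSpec:
    """Build a :class:`PhantomSpec` from plain mapping data (YAML/JSON)."""
    kw: dict = {}
    if "grid" in raw:
        g = raw["grid"]
        kw["grid"] = VoxelGrid(
            shape=tuple(g["shape"]),
            spacing=tuple(g["spacing"]),
            origin=tuple(g.get("origin", (0.0, 0.0, 0.0))),
        )
    kw["organs"] = [
        OrganPrimitive(
            code=o["code"],
            name=o["name"],
            kind=o.get("kind", "ellipsoid"),
            center_mm=tuple(o["center_mm"]),
            semi_axes_mm=tuple(o["semi_axes_mm"]),
            intensity=o.get("intensity", 100.0),
        )
        for o in raw.get("organs", [])
    ]
    if raw.get("dixon"):
        kw["dixon"] = DixonSpec(**raw["dixon"])
    if raw.get("bladder"):
        b = dict(raw["bladder"])
        b["times_min"] = tuple(b["times_min"])
        kw["bladder"] = BladderSpec(**b)
    if raw.get("subject"):
        kw["subject"] = SubjectContext(**raw["subject"])
    if raw.get("exam_date"):
        kw["exam_date"] = date.fromisoformat(raw["exam_date"])
    if raw.get("sequence_classes"):
        kw["sequence_classes"] = tuple(SequenceClass(c) for c in raw["sequence_classes"])
    for key in ("saline_bag_volume_ml", "noise_sd", "background_level", "seed"):
        if key in raw:
            kw[key] = raw[key]
    return PhantomSpec(**kw)


def make_exam(spec: PhantomSpec) -> tuple[ExamStudy, GroundTruth]:
    """Build a full synthetic exam plus its ground-truth manifest.

    One series per entry of ``spec.sequence_classes``, all sharing the same
    label map (organ geometry does not move between sequences). Ground-truth
    volumes are computed from the rasterized voxel sets themselves, so
    measured and true volumes agree exactly by construction.
    """
    rng = np.random.default_rng(spec.seed)
    labels = build_labels(spec)
    truth = GroundTruth()
    vox_ml = spec.grid.voxel_volume_mm3 / MM3_PER_ML
    for code, name in labels.registry.items():
        truth.organ_volumes_ml[name] = float(np.count_nonzero(labels.codes == code)) * vox_ml
    if spec.dixon is not None:
        truth.fat_fraction = spec.dixon.fat_fraction

    series: list[SeriesRecord] = []
    labels_map: dict[str, LabelVolume] = {}
    for i, seq_class in enumerate(spec.sequence_classes):
        sid = f"ser{i:02d}_{seq_class.value}"
        rec = _paint_series(spec, labels, rng, sid, seq_class, time_s=8 * 3600.0 + 240.0 * i)
        series.append(rec)
        labels_map[sid] = labels
    exam = ExamStudy(
        subject=spec.subject, exam_date=spec.exam_date, series=series, labels=labels_map
    )
    return exam, truth


def make_dixon_pair(spec: PhantomSpec) -> tuple[SeriesRecord, SeriesRecord]:
    """Synthesize an in-/out-of-phase pair encoding ``spec.dixon.fat_fraction``.

    Inside the target organ the out-of-phase level is
    ``in_phase_level * (1 - 2 * fat_fraction)`` (plus noise), so the
    two-point estimator recovers the fat fraction exactly at zero noise;
    everywhere else the two volumes agree (no fat signal).
    """
    if spec.dixon is None:
        raise PhantomSpecError("spec.dixon is required for a Dixon pair")
    dx = spec.dixon
    rng = np.random.default_rng(spec.seed)
    labels = build_labels(spec)
    target = labels.codes == dx.target_code
    if not target.any():
        raise PhantomSpecError(f"Dixon target code {dx.target_code} rasterizes to nothing")

    ip = np.full(spec.grid.shape, spec.background_level, dtype=np.float64)
    for prim in spec.organs:
        ip[labels.codes == prim.code] = prim.intensity
    ip[target] = dx.in_phase_level
    op = ip.copy()
    op[target] = dx.in_phase_level * (1.0 - 2.0 * dx.fat_fraction)
    if spec.noise_sd > 0:
        ip = ip + rng.normal(0.0, spec.noise_sd, size=ip.shape)
        op = op + rng.normal(0.0, spec.noise_sd, size=op.shape)

    n_slices = spec.grid.shape[2]
    t0 = 8 * 3600.0
    mk = lambda sid, cls, vals, t: SeriesRecord(
        series_id=sid,
        sequence_class=cls,
        volume=IntensityVolume(grid=spec.grid, values=vals),
        acquisition_times=(t + np.arange(n_slices) * 0.5).tolist(),
        echo_index=0 if cls is SequenceClass.T1_OUT_OF_PHASE else 1,
    )
    return (
        mk("dixon_ip", SequenceClass.T1_IN_PHASE, ip, t0 + 20.0),
        mk("dixon_op", SequenceClass.T1_OUT_OF_PHASE, op, t0),
    )


def make_bladder_series(
    spec: PhantomSpec,
) -> tuple[list[SeriesRecord], dict[str, LabelVolume], GroundTruth]:
    """Time-stamped series with a bladder filling at a constant rate.

    The bladder is a box of fixed in-plane cross-section whose height grows
    so its analytic volume follows ``start + rate * t``; under the
    center-inside rule the rasterized volume is within one voxel layer of
    the analytic value. Ground truth records the analytic volumes and the
    weight-normalized filling rate ``rate * 60 / weight`` (mL/kg/h).
    """
    if spec.bladder is None:
        raise PhantomSpecError("spec.bladder is required for a bladder series")
    bl = spec.bladder
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    sp = grid.spacing
    # box base: central third of the in-plane extent
    nx, ny = max(grid.shape[0] // 3, 1), max(grid.shape[1] // 3, 1)
    base_area_mm2 = nx * sp[0] * ny * sp[1]
    x0, y0 = grid.shape[0] // 3, grid.shape[1] // 3

    seq_cycle = [SequenceClass.T2, SequenceClass.SSFP, SequenceClass.SSFSE]
    series: list[SeriesRecord] = []
    labels_map: dict[str, LabelVolume] = {}
    truth = GroundTruth(
        bladder_volumes_ml=[],
        urine_rate_ml_kg_h=bl.rate_ml_per_min * 60.0 / bl.weight_kg,
    )
    registry = {1: "urinary_bladder"}
    for i, t_min in enumerate(bl.times_min):
        vol_ml = bl.start_volume_ml + bl.rate_ml_per_min * t_min
        truth.bladder_volumes_ml.append(vol_ml)
        height_mm = vol_ml * MM3_PER_ML / base_area_mm2
        n_layers_max = int(np.ceil(height_mm / sp[2])) + 1
        if n_layers_max > grid.shape[2]:
            raise GeometryError("bladder exceeds grid depth; enlarge the grid")
        zc = grid.origin[2] + np.arange(grid.shape[2]) * sp[2]
        z_start = grid.origin[2] - 0.5 * sp[2]
        in_height = (zc >= z_start) & (zc < z_start + height_mm)
        codes = np.zeros(grid.shape, dtype=np.int32)
        codes[x0 : x0 + nx, y0 : y0 + ny, in_height] = 1
        labels = LabelVolume(grid=grid, codes=codes, registry=registry)

        values = np.full(grid.shape, spec.background_level, dtype=np.float64)
        values[codes == 1] = 1000.0  # T2-bright urine
        if spec.noise_sd > 0:
            values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
        t_s = bl.start_clock_s + t_min * 60.0
        sid = f"bladder{i:02d}"
        rec = SeriesRecord(
            series_id=sid,
            sequence_class=seq_cycle[i % len(seq_cycle)],
            volume=IntensityVolume(grid=grid, values=values),
            acquisition_times=[t_s] * grid.shape[2],
        )
        series.append(rec)
        labels_map[sid] = labels
    return series, labels_map, truth


def make_growth_history(
    start_volume_ml: float,
    annual_rate: float,
    ages: Sequence[float],
    n_sequences: int = 3,
    noise_sd_frac: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Longitudinal per-sequence TKV measurements under exponential growth.

    True TKV at age ``a`` is ``start * (1 + annual_rate) ** (a - ages[0])``;
    each sequence measurement multiplies it by lognormal noise of the given
    fractional sd. Returns a tidy frame (age_years, series_id, volume_ml)
    and the ground-truth (age, TKV) trajectory.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth = GroundTruth(tkv_by_age=[])
    for a in ages:
        true_tkv = start_volume_ml * (1.0 + annual_rate) ** (a - ages[0])
        truth.tkv_by_age.append((float(a), float(true_tkv)))
        for s in range(n_sequences):
            noise = np.exp(rng.normal(0.0, noise_sd_frac)) if noise_sd_frac > 0 else 1.0
            rows.append(
                {"age_years": float(a), "series_id": f"seq{s}", "volume_ml": true_tkv * noise}
            )
    return pd.DataFrame(rows), truth
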