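"""Structured radiological report assembly and trajectory plot data.

The report bundle is the single serializable record of everything the
pipeline computed for one exam: QC, renal metrics, hepatic metrics, body
composition, functional metrics, presence findings, plus provenance (tool
version, config hash, series inventory). Two renderings exist — JSON for
machines (full precision) and Markdown for humans (volumes rounded to the
nearest mL) — and both are pure projections of the bundle: regeneration
from the same inputs is byte-identical, and no number appears in prose
that is not in the JSON. Metrics that were not computed render as
"not evaluated", never silently vanish.

De-identification: the bundle stores an opaque subject id; names and exact
dates (beyond the exam year) are never serialized.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from . import __version__
from .core import ExamStudy
from .errors import InputError, SpanError
from .renal import GrowthFit, TKVObservation, fit_exponential_growth

__all__ = ["ReportBundle", "TrajectoryData", "build_report", "trajectory_data"]

#: fixed section order of the rendered report
_SECTIONS = (
    ("qc", "Quality Control"),
    ("kidneys", "Kidneys"),
    ("liver", "Liver"),
    ("body_composition", "Body Composition"),
    ("functional", "Functional Metrics"),
    ("presence", "Presence Findings"),
)


def _jsonable(obj: Any) -> Any:
    """Recursively convert dataclasses/enums/numpy into plain JSON types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class ReportBundle:
    """All computed biomarkers for one exam, plus provenance."""

    subject_id: str
    exam_year: int
    subject_summary: dict[str, Any]
    sections: dict[str, Any]
    provenance: dict[str, Any]

    def to_dict(self) -> dict:
        return _jsonable(dataclasses.asdict(self))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def to_markdown(self) -> str:
        lines = [
            f"# Radiological biomarker report — subject {self.subject_id}, exam {self.exam_year}",
            "",
            f"Age {self.subject_summary['age_years']:g} y, sex {self.subject_summary['sex']}, "
            f"height {self.subject_summary['height_m']:.2f} m, "
            f"weight {self.subject_summary['weight_kg']:.1f} kg.",
            "",
        ]
        for key, title in _SECTIONS:
            lines.append(f"## {title}")
            lines.append("")
            content = self.sections.get(key)
            if content is None:
                lines.append("not evaluated")
            else:
                lines.extend(_render_section(key, content))
            lines.append("")
        lines.append(
            f"---\nGenerated by adpkd-metrics {self.provenance['tool_version']} "
            f"(config {self.provenance['config_hash'][:12]})."
        )
        return "\n".join(lines) + "\n"


def _ml(x: float) -> str:
    """Volumes are rounded to the nearest mL only here, at render time."""
    return f"{round(float(x))} mL"


def _render_section(key: str, c: dict) -> list[str]:
    out: list[str] = []
    if key == "qc":
        s = c.get("saline")
        if s is not None:
            out.append(
                f"- Saline reference bag: measured {_ml(s['measured_ml'])} vs nominal "
                f"{_ml(s['nominal_ml'])} ({s['relative_error'] * 100:.1f}% error) — "
                + ("PASS" if s["passed"] else "FAIL, review acquisition")
            )
        for flag in c.get("outlier_flags", []):
            out.append(f"- Outlier volume flagged for review: series {flag}")
        if not out:
            out.append("no QC findings")
    elif key == "kidneys":
        if "tkv_ml" in c:
            out.append(f"- TKV: {_ml(c['tkv_ml'])}" + (f" ± {_ml(c['tkv_sd_ml'])}" if c.get("tkv_sd_ml") else ""))
        if "httkv_ml_per_m" in c:
            out.append(f"- htTKV: {round(c['httkv_ml_per_m'])} mL/m")
        if c.get("mayo") is not None:
            m = c["mayo"]
            out.append(
                f"- Mayo Imaging Classification: {m['mayo_class']} "
                f"(implied growth {m['estimated_rate'] * 100:.2f}%/yr)"
            )
        if c.get("growth") is not None:
            g = c["growth"]
            out.append(
                f"- Annual TKV growth: {g['annual_rate'] * 100:.2f}%/yr over "
                f"{g['n_points']} exams"
                + (" — RAPID progression (>5%/yr)" if g["rapid"] else "")
            )
    elif key == "liver":
        if "liver_volume_ml" in c:
            out.append(f"- Liver volume: {_ml(c['liver_volume_ml'])}")
        if c.get("cyst_fraction") is not None:
            out.append(f"- Liver cyst fraction: {c['cyst_fraction'] * 100:.1f}%")
        if c.get("fat_fraction") is not None:
            ff = c["fat_fraction"]
            out.append(
                f"- Liver fat fraction (two-point Dixon, histogram peak): "
                f"{ff['ff_mode'] * 100:.0f}% (mean {ff['ff_mean'] * 100:.1f}%, "
                f"{ff['n_voxels']} voxels)"
                + (" — possible fat-water swap, review" if ff["swap_flag"] else "")
            )
    elif key == "body_composition":
        if c.get("body") is not None:
            b = c["body"]
            out.append(
                f"- Cyst burden: {_ml(b['cyst_volume_total_ml'])} "
                f"(~{b['cyst_mass_kg']:.1f} kg at 1 g/mL)"
            )
            out.append(
                f"- BMI: {b['bmi_uncorrected']:.1f} kg/m² uncorrected, "
                f"{b['bmi_corrected']:.1f} kg/m² cyst-corrected"
            )
            for name, vol in sorted(b.get("compartment_volumes_ml", {}).items()):
                out.append(f"- {name}: {_ml(vol)}")
    elif key == "functional":
        if c.get("urine") is not None:
            u = c["urine"]
            out.append(
                f"- Urine output: {u['rate_ml_kg_h']:.1f} mL/kg/h "
                f"({u['n_points']} bladder time points)"
            )
        if c.get("jets") is not None:
            j = c["jets"]
            out.append(
                "- Ureteral jet screen: "
                + (
                    f"flagged (sd/median {j['sd_over_median']:.2f}, "
                    f"{j['candidate_void_voxels']} candidate void voxels)"
                    if j["flagged"]
                    else "not flagged"
                )
            )
        if c.get("confinement") is not None:
            g = c["confinement"]
            organs = ", ".join(
                f"{k} {v * 100:.0f}%" for k, v in sorted(g["per_organ_overlap"].items())
            )
            out.append(
                f"- Gastric confinement ({g['dilation_mm']:g} mm expansion): "
                f"free {g['free_fraction'] * 100:.0f}%" + (f"; {organs}" if organs else "")
            )
    elif key == "presence":
        for p in c.get("findings", []):
            state = "present" if p["present"] else "absent"
            where = (
                f" (series {p['series_id']}, slices {p['slice_indices']})"
                if p["present"]
                else ""
            )
            out.append(f"- {p['feature']}: {state}, {p['volume_ml']:.2f} mL{where}")
        if not out:
            out.append("no features assessed")
    return out or ["not evaluated"]


def build_report(
    study: ExamStudy,
    subject_id: str = "anon",
    *,
    qc: Any = None,
    outlier_flags: Sequence[str] = (),
    tkv_summary: Any = None,
    httkv: float | None = None,
    mayo: Any = None,
    growth: Any = None,
    liver_volume_ml: float | None = None,
    cyst_fraction: float | None = None,
    fat_fraction: Any = None,
    body: Any = None,
    urine: Any = None,
    jets: Any = None,
    confinement: Any = None,
    presence: Sequence[Any] = (),
    config: dict | None = None,
) -> ReportBundle:
    """Assemble module outputs into one deterministic report bundle.

    Every argument beyond the study is optional; omitted metrics render as
    "not evaluated". At minimum a volumes table (``tkv_summary``) or any
    one metric should exist for the report to be informative.
    """
    sections: dict[str, Any] = {}

    qc_section: dict[str, Any] = {}
    if qc is not None:
        qc_section["saline"] = _jsonable(qc)
    if outlier_flags:
        qc_section["outlier_flags"] = list(outlier_flags)
    sections["qc"] = qc_section or None

    kidneys: dict[str, Any] = {}
    if tkv_summary is not None:
        kidneys["tkv_ml"] = _jsonable(tkv_summary.mean_ml)
        kidneys["tkv_sd_ml"] = _jsonable(tkv_summary.sd_ml)
        kidneys["per_series"] = _jsonable(tkv_summary.per_series)
    if httkv is not None:
        kidneys["httkv_ml_per_m"] = float(httkv)
    if mayo is not None:
        kidneys["mayo"] = _jsonable(mayo)
    if growth is not None:
        kidneys["growth"] = _jsonable(growth)
    sections["kidneys"] = kidneys or None

    liver: dict[str, Any] = {}
    if liver_volume_ml is not None:
        liver["liver_volume_ml"] = float(liver_volume_ml)
    if cyst_fraction is not None:
        liver["cyst_fraction"] = float(cyst_fraction)
    if fat_fraction is not None:
        ff = _jsonable(fat_fraction)
        ff.pop("histogram", None)  # bulky; exported separately as CSV
        liver["fat_fraction"] = ff
    sections["liver"] = liver or None

    sections["body_composition"] = {"body": _jsonable(body)} if body is not None else None

    functional: dict[str, Any] = {}
    if urine is not None:
        u = _jsonable(urine)
        u.pop("used_points", None)
        functional["urine"] = u
    if jets is not None:
        functional["jets"] = _jsonable(jets)
    if confinement is not None:
        functional["confinement"] = _jsonable(confinement)
    sections["functional"] = functional or None

    sections["presence"] = {"findings": _jsonable(list(presence))} if presence else None

    config_hash = hashlib.sha256(
        json.dumps(_jsonable(config or {}), sort_keys=True).encode()
    ).hexdigest()
    provenance = {
        "tool_version": __version__,
        "config_hash": config_hash,
        "series_inventory": [
            {"series_id": s.series_id, "sequence_class": s.sequence_class.value}
            for s in study.series
        ],
    }
    return ReportBundle(
        subject_id=subject_id,
        exam_year=study.exam_date.year,
        subject_summary={
            "age_years": study.subject.age_years,
            "sex": study.subject.sex,
            "height_m": study.subject.height_m,
            "weight_kg": study.subject.weight_kg,
        },
        sections=sections,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Longitudinal trajectory
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryData:
    """Plot-ready TKV-vs-age data: per-exam points, mean ± SD, fitted curves."""

    points: list[dict]  # per exam: age, per-sequence volumes, mean, sd
    fit: GrowthFit | None = None
    fit_pre: GrowthFit | None = None
    fit_post: GrowthFit | None = None
    partition_age: float | None = None
    warnings: list[str] = field(default_factory=list)


def trajectory_data(
    observations: Sequence[TKVObservation],
    partition_age: float | None = None,
    min_span_years: float = 1.0,
) -> TrajectoryData:
    """Per-exam mean ± SD TKV points with exponential growth fit(s).

    Without a partition a single fit covers all exams (when >= 2 exams span
    >= ``min_span_years``). With a treatment partition age, independent
    fits are attempted before and after it — e.g. pre- vs post-tolvaptan
    slopes; a side with too few exams or too short a span is reported as a
    warning, with the points still emitted.
    """
    if not observations:
        raise InputError("trajectory needs at least one observation")
    obs = sorted(observations, key=lambda o: o.age_years)
    points = [
        {
            "age_years": o.age_years,
            "per_sequence_ml": list(o.per_sequence_ml),
            "mean_ml": o.tkv_ml,
            "sd_ml": o.sd_ml,
        }
        for o in obs
    ]
    traj = TrajectoryData(points=points, partition_age=partition_age)

    def try_fit(subset: list[TKVObservation], label: str) -> GrowthFit | None:
        if len(subset) < 2:
            traj.warnings.append(f"{label}: fewer than 2 exams, fit omitted")
            return None
        try:
            return fit_exponential_growth(subset, min_span_years=min_span_years)
        except SpanError as exc:
            traj.warnings.append(f"{label}: {exc}")
            return None

    if partition_age is None:
        traj.fit = try_fit(list(obs), "overall")
    else:
        traj.fit_pre = try_fit([o for o in obs if o.age_years < partition_age], "pre-partition")
        traj.fit_post = try_fit([o for o in obs if o.age_years >= partition_age], "post-partition")
    return traj
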