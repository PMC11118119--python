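"""Renal disease-progression metrics: TKV, htTKV, growth rate, Mayo class.

Total kidney volume (TKV) and its height-adjusted form htTKV = TKV/height
are the primary imaging biomarkers of ADPKD progression. Serial exams are
modelled as exponential kidney enlargement,

    TKV(age) = TKV0 * (1 + r) ** age,

fitted by ordinary least squares of ln(TKV) on age; the annualized growth
rate is r = exp(slope) - 1. A rate above 5 %/year flags rapid progression.

The Mayo Imaging Classification assigns risk classes 1A-1E by the growth
rate implied by a single (htTKV, age) pair under the same exponential
model anchored at a theoretical baseline of 150 mL/m at age 0:

    r_est = (htTKV / 150) ** (1 / age) - 1,

with class boundaries at 1.5, 3, 4.5 and 6 %/year. Only the typical
(class 1, diffuse bilateral) presentation is classified here; atypical
class 2 morphology is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, SpanError

__all__ = [
    "TKVObservation",
    "GrowthFit",
    "MayoResult",
    "MayoConfig",
    "total_kidney_volume",
    "height_adjust",
    "fit_exponential_growth",
    "classify_mayo",
    "flag_rapid_progression",
    "RAPID_GROWTH_THRESHOLD",
]

#: annual TKV growth above this fraction indicates rapid progression
RAPID_GROWTH_THRESHOLD = 0.05


@dataclass
class TKVObservation:
    """TKV at one exam: the cross-sequence mean plus its spread."""

    age_years: float
    tkv_ml: float
    per_sequence_ml: list[float] = field(default_factory=list)
    sd_ml: float = 0.0

    def __post_init__(self) -> None:
        if self.tkv_ml <= 0:
            raise InputError("TKV must be positive")
        if self.age_years <= 0:
            raise InputError("age must be positive")


@dataclass
class GrowthFit:
    """Exponential growth model fitted to serial TKV measurements."""

    annual_rate: float  # fraction/year
    intercept_log_tkv: float  # ln(mL) at age 0
    n_points: int
    r_squared: float
    rapid: bool

    def predict(self, age_years: float | np.ndarray) -> np.ndarray:
        """Model TKV (mL) at the given age(s)."""
        return np.exp(self.intercept_log_tkv + np.log1p(self.annual_rate) * np.asarray(age_years))


@dataclass(frozen=True)
class MayoConfig:
    """Classification constants (baseline htTKV and class boundaries).

    The 150 mL/m baseline at theoretical age 0 and the 1.5/3/4.5/6 %/yr
    boundaries follow the published Mayo Imaging Classification.
    """

    baseline_httkv: float = 150.0
    boundaries: tuple[float, ...] = (0.015, 0.03, 0.045, 0.06)
    classes: tuple[str, ...] = ("1A", "1B", "1C", "1D", "1E")


@dataclass
class MayoResult:
    httkv: float
    age_years: float
    estimated_rate: float
    mayo_class: str
    below_baseline: bool = False


def total_kidney_volume(left_ml: float, right_ml: float) -> float:
    """TKV: sum of both kidney volumes (either may be 0, e.g. nephrectomy)."""
    if left_ml < 0 or right_ml < 0:
        raise InputError("kidney volumes must be non-negative")
    return float(left_ml) + float(right_ml)


def height_adjust(volume_ml: float, height_m: float) -> float:
    """Height-adjusted volume in mL/m."""
    if height_m <= 0:
        raise InputError("height must be positive")
    return volume_ml / height_m


def fit_exponential_growth(
    observations: list[TKVObservation],
    min_span_years: float = 1.0,
    rapid_threshold: float = RAPID_GROWTH_THRESHOLD,
) -> GrowthFit:
    """OLS fit of ln(TKV) on age; annual rate = exp(slope) - 1.

    Requires at least two observations spanning at least ``min_span_years``
    (serial exams closer than a year carry too little growth signal
    relative to measurement noise). With exactly two points the fit is the
    closed form ln(V2/V1)/(a2-a1) and r² = 1 by construction.
    """
    if len(observations) < 2:
        raise InputError("growth fit needs at least two observations")
    ages = np.array([o.age_years for o in observations], dtype=float)
    tkvs = np.array([o.tkv_ml for o in observations], dtype=float)
    span = ages.max() - ages.min()
    if span < min_span_years:
        raise SpanError(
            f"observations span {span:.2f} y < required {min_span_years:g} y"
        )
    y = np.log(tkvs)
    slope, intercept = np.polyfit(ages, y, 1)
    resid = y - (slope * ages + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    rate = float(np.expm1(slope))
    return GrowthFit(
        annual_rate=rate,
        intercept_log_tkv=float(intercept),
        n_points=len(observations),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        rapid=flag_rapid_progression(rate, rapid_threshold),
    )


def classify_mayo(
    httkv: float, age_years: float, config: MayoConfig = MayoConfig()
) -> MayoResult:
    """Mayo Imaging Classification (typical class 1 subclasses).

    The implied growth rate is ``(htTKV/150)**(1/age) - 1``; class
    boundaries are half-open: 1A < 1.5 % <= 1B < 3 % <= 1C < 4.5 % <= 1D
    < 6 % <= 1E. An htTKV below the 150 mL/m baseline yields a
    non-positive rate and class 1A with a below-baseline note.
    """
    if age_years <= 0:
        raise InputError("age must be positive")
    if httkv <= 0:
        raise InputError("htTKV must be positive")
    rate = (httkv / config.baseline_httkv) ** (1.0 / age_years) - 1.0
    below = httkv < config.baseline_httkv
    idx = int(np.searchsorted(np.asarray(config.boundaries), rate, side="right"))
    return MayoResult(
        httkv=float(httkv),
        age_years=float(age_years),
        estimated_rate=float(rate),
        mayo_class=config.classes[idx],
        below_baseline=below,
    )


def flag_rapid_progression(
    rate: float, threshold: float = RAPID_GROWTH_THRESHOLD
) -> bool:
    """True when the annual growth rate strictly exceeds the threshold."""
    if not np.isfinite(rate):
        raise InputError("rate must be finite")
    return bool(rate > threshold)
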