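"""Domain types for esCCO estimation and method-comparison analysis.

Units follow monitoring convention: pulse wave transit time (PWTT) and beat
timestamps in milliseconds, sample timestamps in seconds, pressures in mmHg,
heart rate in beats/min, stroke volume in ml, cardiac output in L/min.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CONTEXT_TAGS",
    "ContextTag",
    "CalibrationMode",
    "QcFlag",
    "BeatEvents",
    "HemodynamicSample",
    "CalibrationState",
    "EsccoEstimate",
    "PatientInfo",
    "IcoMeasurement",
    "PairedComparison",
]


class ContextTag(str, enum.Enum):
    """Clinical-context annotations attached to a hemodynamic sample."""

    CPB = "CPB"
    AORTIC_CROSS_CLAMP = "AORTIC_CROSS_CLAMP"
    OPCAB_POSTERIOR_WALL = "OPCAB_POSTERIOR_WALL"
    PACING = "PACING"
    NONE = "NONE"


CONTEXT_TAGS = frozenset(t.value for t in ContextTag)


class CalibrationMode(str, enum.Enum):
    REFERENCE_CO = "REFERENCE_CO"
    PATIENT_INFO = "PATIENT_INFO"


class QcFlag(str, enum.Enum):
    """Identifiers of the automated exclusion rules."""

    CONTEXT_CPB = "CONTEXT_CPB"
    CONTEXT_CROSS_CLAMP = "CONTEXT_CROSS_CLAMP"
    CONTEXT_OPCAB_POSTERIOR = "CONTEXT_OPCAB_POSTERIOR"
    R_WAVE_ERROR = "R_WAVE_ERROR"
    SV_PWTT_INCONSISTENT = "SV_PWTT_INCONSISTENT"
    NONPHYSIOLOGIC_SV = "NONPHYSIOLOGIC_SV"


@dataclass(frozen=True)
class BeatEvents:
    """Paired ECG R-wave and peripheral pulse arrival timestamps (ms).

    PWTT for each beat is the interval from the R wave to the arrival of the
    pulse-oximetry wave at the periphery; it is the sum of the pre-ejection
    period and the arterial pulse travel time.
    """

    subject_id: str
    r_times: Tuple[float, ...]
    pulse_arrival_times: Tuple[float, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.r_times, dtype=float)
        a = np.asarray(self.pulse_arrival_times, dtype=float)
        if r.size != a.size:
            raise ValueError(
                f"r_times ({r.size}) and pulse_arrival_times ({a.size}) "
                "must be the same length"
            )
        if r.size > 1 and not np.all(np.diff(r) > 0):
            raise ValueError("r_times must be strictly increasing")
        if np.any(a < r):
            raise ValueError("each pulse arrival must not precede its R wave")
        object.__setattr__(self, "r_times", tuple(r))
        object.__setattr__(self, "pulse_arrival_times", tuple(a))

    def __len__(self) -> int:
        return len(self.r_times)


@dataclass(frozen=True)
class HemodynamicSample:
    """One period-averaged record of HR, PWTT, pressures and context.

    ``rr_intervals`` optionally carries the beat-to-beat RR intervals (ms)
    underlying the averaged values, used by the R-wave plausibility check.
    """

    subject_id: str
    t: float  # s
    hr: float  # beats/min
    pwtt: float  # ms
    sbp: float  # mmHg
    dbp: float  # mmHg
    context: frozenset = frozenset({ContextTag.NONE.value})
    rr_intervals: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if not (10.0 < self.hr < 300.0):
            raise ValueError(f"hr={self.hr} outside physiological (10, 300)")
        if self.pwtt <= 0:
            raise ValueError(f"pwtt={self.pwtt} must be positive")
        if not (self.sbp > self.dbp > 0):
            raise ValueError(
                f"require sbp > dbp > 0, got sbp={self.sbp}, dbp={self.dbp}"
            )
        object.__setattr__(self, "context", frozenset(self.context))
        if self.rr_intervals is not None:
            object.__setattr__(self, "rr_intervals", tuple(self.rr_intervals))

    @property
    def pulse_pressure(self) -> float:
        """sbp − dbp (mmHg); always positive by construction."""
        return self.sbp - self.dbp


@dataclass(frozen=True)
class CalibrationState:
    """Constants binding PWTT to stroke volume: SV = K·(alpha·PWTT + beta).

    ``alpha`` (ml/ms, negative by default: longer transit, lower SV) and
    ``beta`` (ml) are configured constants; ``K`` is the dimensionless scale
    set at calibration so the estimate reproduces the reference CO.
    """

    K: float
    alpha: float
    beta: float
    mode: CalibrationMode
    reference_co: Optional[float] = None  # L/min at the calibration point
    calibrated_at: Optional[float] = None  # s

    def __post_init__(self) -> None:
        if not (self.K > 0 and math.isfinite(self.K)):
            raise ValueError(f"K={self.K} must be positive and finite")

    def sv_term(self, pwtt: float) -> float:
        """The uncalibrated linear term alpha·pwtt + beta (ml)."""
        return self.alpha * pwtt + self.beta


@dataclass(frozen=True)
class EsccoEstimate:
    """Stroke volume / cardiac output estimate with QC flags."""

    sv: float  # ml; NaN when rejected
    co: float  # L/min; NaN when rejected
    qc_flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "qc_flags", frozenset(self.qc_flags))

    @property
    def rejected(self) -> bool:
        return QcFlag.NONPHYSIOLOGIC_SV.value in self.qc_flags


def du_bois_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m²), Du Bois & Du Bois formula."""
    return 0.007184 * height_cm**0.725 * weight_kg**0.425


@dataclass(frozen=True)
class PatientInfo:
    """Demographics consumed by the patient-information calibration."""

    subject_id: str
    age: float  # years
    sex: str  # 'M' or 'F'
    height: float  # cm
    weight: float  # kg

    def __post_init__(self) -> None:
        if not (0 < self.age <= 120):
            raise ValueError(f"age={self.age} outside (0, 120]")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not (100 <= self.height <= 220):
            raise ValueError(f"height={self.height} cm outside [100, 220]")
        if not (20 <= self.weight <= 250):
            raise ValueError(f"weight={self.weight} kg outside [20, 250]")

    @property
    def sex_indicator(self) -> int:
        """Indicator coding of sex: M → 1, F → 0."""
        return 1 if self.sex == "M" else 0

    @property
    def bsa(self) -> float:
        """Body surface area (m²) by the Du Bois formula."""
        return du_bois_bsa(self.height, self.weight)


@dataclass(frozen=True)
class IcoMeasurement:
    """Triplicate bolus thermodilution cardiac output with acceptance."""

    subject_id: str
    t: float  # s
    injectate_values: Tuple[float, float, float]  # L/min
    mean_co: float  # L/min
    accepted: bool

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "injectate_values", tuple(float(v) for v in self.injectate_values)
        )


@dataclass(frozen=True, order=True)
class PairedComparison:
    """One (test CO, reference CO) pair — the unit of all agreement statistics."""

    subject_id: str
    time_index: int
    test_co: float  # L/min
    ref_co: float  # L/min

    def __post_init__(self) -> None:
        if not (self.test_co > 0 and self.ref_co > 0):
            raise ValueError("CO values must be positive")
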