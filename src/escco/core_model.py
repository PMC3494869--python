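"""PWTT computation and the linear stroke-volume / cardiac-output model.

The estimator is the calibrated linear relation

    SV (ml)     = K · (alpha · PWTT + beta)
    CO (L/min)  = SV · HR / 1000

with alpha < 0 by default (a longer transit time implies a lower stroke
volume) and K fixed at calibration against a reference cardiac output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .types import (
    BeatEvents,
    CalibrationMode,
    CalibrationState,
    EsccoEstimate,
    HemodynamicSample,
    QcFlag,
)

__all__ = [
    "DEFAULT_ALPHA",
    "DEFAULT_BETA",
    "PwttSeries",
    "compute_pwtt",
    "smooth_pwtt",
    "estimate",
    "calibrate_reference",
]

#: Default slope (ml/ms) and intercept (ml) of the SV–PWTT relation. These are
#: configurable physiological scale constants chosen so SV spans roughly
#: 10–120 ml over PWTT 60–280 ms; every fit and test may override them.
DEFAULT_ALPHA = -0.5
DEFAULT_BETA = 150.0


@dataclass(frozen=True)
class PwttSeries:
    """Per-beat PWTT values (ms) with a degenerate (non-positive) mask."""

    values: np.ndarray
    degenerate: np.ndarray  # boolean, True where pwtt <= 0

    def __len__(self) -> int:
        return len(self.values)


def compute_pwtt(events: BeatEvents) -> PwttSeries:
    """Per-beat pulse wave transit time from paired beat events.

    PWTT for beat *i* is ``pulse_arrival_times[i] − r_times[i]`` (ms). Beats
    with non-positive PWTT (arrival coincident with the R wave) are flagged
    degenerate rather than dropped, preserving length.
    """
    r = np.asarray(events.r_times, dtype=float)
    a = np.asarray(events.pulse_arrival_times, dtype=float)
    pwtt = a - r
    return PwttSeries(values=pwtt, degenerate=pwtt <= 0)


def smooth_pwtt(values: np.ndarray, window: int = 8) -> np.ndarray:
    """Trailing moving average of beat-level PWTT over ``window`` beats.

    The monitor reports period-averaged PWTT; this reduces a beat stream to
    that convention. Shorter prefixes average over the beats available.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return v
    c = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(1, v.size + 1)
    lo = np.maximum(idx - window, 0)
    return (c[idx] - c[lo]) / (idx - lo)


def estimate(sample: HemodynamicSample, cal: CalibrationState) -> EsccoEstimate:
    """Estimate stroke volume and cardiac output for one sample.

    Returns an estimate flagged ``NONPHYSIOLOGIC_SV`` (SV/CO = NaN) when the
    linear term ``alpha·pwtt + beta`` is non-positive, i.e. the transit time
    lies beyond the physiologic range of the calibrated relation.
    """
    term = cal.sv_term(sample.pwtt)
    if term <= 0:
        return EsccoEstimate(
            sv=float("nan"),
            co=float("nan"),
            qc_flags=frozenset({QcFlag.NONPHYSIOLOGIC_SV.value}),
        )
    sv = cal.K * term
    co = sv * sample.hr / 1000.0
    return EsccoEstimate(sv=sv, co=co)


def calibrate_reference(
    reference_co: float,
    sample: HemodynamicSample,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    mode: CalibrationMode = CalibrationMode.REFERENCE_CO,
) -> CalibrationState:
    """Fix the scale factor K against a reference cardiac output.

    K is chosen so that ``estimate`` at the calibration sample reproduces
    ``reference_co`` exactly: K = reference_co·1000 / (hr·(alpha·pwtt+beta)).

    Raises
    ------
    ValueError
        If ``reference_co`` is not positive, or the SV term is non-positive
        at the calibration sample (calibration impossible there).
    """
    if not reference_co > 0:
        raise ValueError(f"reference_co={reference_co} must be positive")
    term = alpha * sample.pwtt + beta
    if term <= 0:
        raise ValueError(
            "alpha*pwtt + beta <= 0 at the calibration sample "
            f"(pwtt={sample.pwtt} ms): cannot calibrate"
        )
    K = reference_co * 1000.0 / (sample.hr * term)
    return CalibrationState(
        K=K,
        alpha=alpha,
        beta=beta,
        mode=mode,
        reference_co=reference_co,
        calibrated_at=sample.t,
    )
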