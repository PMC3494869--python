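"""Automated data-exclusion rules and the triplicate thermodilution check.

Rules implemented:

* context exclusions — samples annotated as cardiopulmonary bypass, aortic
  cross-clamping, or OPCAB posterior-wall grafting are theoretically
  inadequate for pulse-based CO estimation (non-pulsatile or distorted
  SpO2/ECG signals) and are excluded outright;
* R-wave plausibility — beat RR intervals deviating grossly from the local
  (running-median) rhythm indicate double-detected or missed R waves;
* SV–PWTT consistency — under the negative-slope SV–PWTT relation, large
  concordant changes of stroke volume and transit time (both falling or both
  rising) are unreachable under a single calibration and mark a pathological
  or artefactual state (the archetype is cardiac tamponade);
* triplicate acceptance — a bolus thermodilution measurement is accepted
  when every injection lies within ±10% of the triplicate mean (inclusive).

Threshold levels are free parameters of :class:`QcThresholds`; the rule
structure, not particular threshold values, is the contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .types import (
    CONTEXT_TAGS,
    ContextTag,
    EsccoEstimate,
    HemodynamicSample,
    IcoMeasurement,
    QcFlag,
)

__all__ = [
    "QcThresholds",
    "ExclusionReport",
    "check_triplicate_ico",
    "flag_r_wave_errors",
    "check_sv_pwtt_relation",
    "apply_context_exclusions",
    "run_exclusion",
]

_EPS = 1e-12

_CONTEXT_RULE = {
    ContextTag.CPB.value: QcFlag.CONTEXT_CPB.value,
    ContextTag.AORTIC_CROSS_CLAMP.value: QcFlag.CONTEXT_CROSS_CLAMP.value,
    ContextTag.OPCAB_POSTERIOR_WALL.value: QcFlag.CONTEXT_OPCAB_POSTERIOR.value,
}


@dataclass(frozen=True)
class QcThresholds:
    """Free parameters of the exclusion rules.

    triplicate_tolerance : max relative deviation of a bolus from the
        triplicate mean for acceptance (boundary inclusive).
    rr_deviation : max relative deviation of an RR interval from the
        running median before the beat is flagged as an R-wave error.
    rr_window : running-median window (beats, odd).
    sv_pwtt_change : minimum relative magnitude that both the SV and the
        PWTT change must exceed, concordantly in sign, to be inconsistent.
    hr_range, pp_range : soft plausibility gates; out-of-range values are
        reported as warnings, not exclusions.
    """

    triplicate_tolerance: float = 0.10
    rr_deviation: float = 0.40
    rr_window: int = 9
    sv_pwtt_change: float = 0.15
    hr_range: Tuple[float, float] = (30.0, 180.0)
    pp_range: Tuple[float, float] = (10.0, 120.0)


DEFAULT_THRESHOLDS = QcThresholds()


def check_triplicate_ico(
    values: Sequence[float],
    subject_id: str = "",
    t: float = 0.0,
    tolerance: float = DEFAULT_THRESHOLDS.triplicate_tolerance,
) -> IcoMeasurement:
    """Apply the ±10% triplicate acceptance rule to three bolus CO values.

    The mean is always computed; the measurement is accepted iff every
    injection deviates from the mean by at most ``tolerance`` (relative,
    boundary inclusive).
    """
    vals = [float(v) for v in values]
    if len(vals) != 3:
        raise ValueError(f"triplicate requires exactly 3 values, got {len(vals)}")
    if any(v <= 0 for v in vals):
        raise ValueError(f"bolus CO values must be positive, got {vals}")
    mean = sum(vals) / 3.0
    max_dev = max(abs(v - mean) for v in vals) / mean
    return IcoMeasurement(
        subject_id=subject_id,
        t=t,
        injectate_values=tuple(vals),
        mean_co=mean,
        accepted=bool(max_dev <= tolerance + _EPS),
    )


def flag_r_wave_errors(
    rr_intervals: Sequence[float],
    deviation: float = DEFAULT_THRESHOLDS.rr_deviation,
    window: int = DEFAULT_THRESHOLDS.rr_window,
) -> np.ndarray:
    """Flag beats whose RR interval departs grossly from the local rhythm.

    A beat is flagged when its RR interval deviates from the centred running
    median (window ``window`` beats) by more than ``deviation`` relative.
    Halved intervals correspond to double-detection, doubled intervals to a
    missed R wave. Empty input yields an empty flag array.
    """
    rr = np.asarray(rr_intervals, dtype=float)
    if rr.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(rr <= 0):
        raise ValueError("RR intervals must be positive")
    med = (
        pd.Series(rr)
        .rolling(window=window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    return np.abs(rr - med) / med > deviation


def check_sv_pwtt_relation(
    prev: Tuple[float, float],
    curr: Tuple[float, float],
    change_threshold: float = DEFAULT_THRESHOLDS.sv_pwtt_change,
) -> Optional[str]:
    """Flag concordant large changes of stroke volume and transit time.

    ``prev`` and ``curr`` are (sv, pwtt) pairs. Returns
    ``"SV_PWTT_INCONSISTENT"`` when the relative changes of SV and PWTT have
    the same sign and both exceed ``change_threshold`` in magnitude; under
    the negative-slope relation such a move cannot arise from one
    calibration. Returns None otherwise.
    """
    sv0, pwtt0 = prev
    sv1, pwtt1 = curr
    if min(sv0, pwtt0, sv1, pwtt1) <= 0:
        raise ValueError("sv and pwtt values must be positive")
    d_sv = (sv1 - sv0) / sv0
    d_pwtt = (pwtt1 - pwtt0) / pwtt0
    concordant = d_sv * d_pwtt > 0
    if concordant and abs(d_sv) > change_threshold and abs(d_pwtt) > change_threshold:
        return QcFlag.SV_PWTT_INCONSISTENT.value
    return None


def apply_context_exclusions(
    samples: Sequence[HemodynamicSample],
) -> List[Set[str]]:
    """Per-sample context exclusion flags.

    CPB, aortic cross-clamp and OPCAB posterior-wall tags map to their
    exclusion flags; pacing is annotated but is not an exclusion rule here.
    Unknown tags produce a warning and are ignored.
    """
    out: List[Set[str]] = []
    for s in samples:
        flags: Set[str] = set()
        for tag in s.context:
            if tag in _CONTEXT_RULE:
                flags.add(_CONTEXT_RULE[tag])
            elif tag not in CONTEXT_TAGS:
                warnings.warn(f"unknown context tag {tag!r} ignored", stacklevel=2)
        out.append(flags)
    return out


@dataclass
class ExclusionReport:
    """Outcome of the automated exclusion pass over an aligned cohort."""

    sample_flags: List[Set[str]]
    rule_counts: Dict[str, int]
    n_excluded: int
    n_retained: int
    soft_warnings: List[str] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return self.n_excluded + self.n_retained

    def excluded_mask(self) -> np.ndarray:
        return np.array([bool(f) for f in self.sample_flags])

    def to_payload(self) -> dict:
        """JSON-ready summary: per-sample rule lists plus counts."""
        return {
            "sample_flags": [sorted(f) for f in self.sample_flags],
            "rule_counts": dict(sorted(self.rule_counts.items())),
            "n_excluded": self.n_excluded,
            "n_retained": self.n_retained,
            "soft_warnings": list(self.soft_warnings),
        }


def run_exclusion(
    samples: Sequence[HemodynamicSample],
    estimates: Optional[Sequence[EsccoEstimate]] = None,
    thresholds: QcThresholds = DEFAULT_THRESHOLDS,
) -> ExclusionReport:
    """Evaluate every exclusion rule over aligned samples and estimates.

    The SV–PWTT consistency rule runs within subject, in time order, using
    pulse pressure as the stroke-volume surrogate (relative changes are what
    the rule compares, so the SV↔pulse-pressure proportionality constant
    cancels). Each sample is compared against the most recent sample of the
    same subject not itself flagged by this rule, so a transient artifact is
    flagged once at onset and the recovery transition back to the retained
    baseline is not penalized.

    Flags are a set union over rules — evaluation order cannot change the
    result, and adding a rule can only grow a sample's flag set.
    """
    n = len(samples)
    if estimates is not None and len(estimates) != n:
        raise ValueError(
            f"samples ({n}) and estimates ({len(estimates)}) must align"
        )

    flags: List[Set[str]] = [set() for _ in range(n)]
    soft: List[str] = []

    for f, ctx in zip(flags, apply_context_exclusions(samples)):
        f |= ctx

    if estimates is not None:
        for f, est in zip(flags, estimates):
            f |= set(est.qc_flags)

    for i, s in enumerate(samples):
        if s.rr_intervals is not None and np.any(
            flag_r_wave_errors(
                s.rr_intervals, deviation=thresholds.rr_deviation,
                window=thresholds.rr_window,
            )
        ):
            flags[i].add(QcFlag.R_WAVE_ERROR.value)

    # SV–PWTT consistency, per subject in time order against last clean point
    order = sorted(range(n), key=lambda i: (samples[i].subject_id, samples[i].t))
    last_clean: Dict[str, int] = {}
    for i in order:
        s = samples[i]
        ref = last_clean.get(s.subject_id)
        if ref is not None:
            r = samples[ref]
            hit = check_sv_pwtt_relation(
                (r.pulse_pressure, r.pwtt),
                (s.pulse_pressure, s.pwtt),
                change_threshold=thresholds.sv_pwtt_change,
            )
            if hit is not None:
                flags[i].add(hit)
        if QcFlag.SV_PWTT_INCONSISTENT.value not in flags[i]:
            last_clean[s.subject_id] = i

    for i, s in enumerate(samples):
        lo, hi = thresholds.hr_range
        if not (lo <= s.hr <= hi):
            soft.append(f"sample {i} ({s.subject_id}): hr={s.hr:g} outside [{lo:g}, {hi:g}]")
        lo, hi = thresholds.pp_range
        if not (lo <= s.pulse_pressure <= hi):
            soft.append(
                f"sample {i} ({s.subject_id}): pulse_pressure={s.pulse_pressure:g} "
                f"outside [{lo:g}, {hi:g}]"
            )

    counts: Dict[str, int] = {}
    for f in flags:
        for rule in f:
            counts[rule] = counts.get(rule, 0) + 1
    n_excluded = sum(1 for f in flags if f)
    return ExclusionReport(
        sample_flags=flags,
        rule_counts=counts,
        n_excluded=n_excluded,
        n_retained=n - n_excluded,
        soft_warnings=soft,
    )
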