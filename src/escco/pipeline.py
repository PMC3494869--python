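"""End-to-end study pipeline on generated or ingested cohorts.

Binds the modules together the way the monitoring study ran: calibrate each
subject once at their first acceptable reference measurement (thermodilution
mean, or the patient-information prediction), estimate CO at every sample,
run the automated exclusion pass, pair retained estimates with accepted
thermodilution means, and compute the full agreement/trending report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import core_model
from .exclusion_qc import ExclusionReport, QcThresholds, DEFAULT_THRESHOLDS, run_exclusion
from .method_comparison import AgreementReport, evaluate
from .patient_calibration import (
    PatientInfoModel,
    build_training_frame,
    fit_patient_info_model,
    predict_reference_co,
)
from .synthetic import Cohort, SyntheticCohortConfig, SyntheticTruth, generate_cohort
from .types import (
    CalibrationMode,
    CalibrationState,
    EsccoEstimate,
    HemodynamicSample,
    IcoMeasurement,
    PairedComparison,
    PatientInfo,
)

__all__ = [
    "StudyResult",
    "calibrate_cohort",
    "estimate_cohort",
    "build_pairs",
    "fit_calibration_from_cohort",
    "qc_performance",
    "run_study",
    "run_synthetic_study",
]


@dataclass
class StudyResult:
    """Everything one pipeline run produces."""

    cohort: Cohort
    calibrations: Dict[str, CalibrationState]
    estimates: List[EsccoEstimate]
    exclusion: ExclusionReport
    pairs: List[PairedComparison]
    agreement: AgreementReport
    patient_info_model: Optional[PatientInfoModel] = None


def _first_accepted_index(
    samples: Sequence[HemodynamicSample],
    ico: Sequence[IcoMeasurement],
    subject_id: str,
) -> Optional[int]:
    idxs = [i for i, s in enumerate(samples) if s.subject_id == subject_id]
    for i in sorted(idxs, key=lambda i: samples[i].t):
        if ico[i].accepted:
            return i
    return None


def fit_calibration_from_cohort(
    patients: Sequence[PatientInfo],
    samples: Sequence[HemodynamicSample],
    ico: Sequence[IcoMeasurement],
) -> PatientInfoModel:
    """Fit the patient-information regression from a cohort's own data.

    Mirrors the training design: each subject contributes the rows with
    their maximum and minimum accepted thermodilution CO.
    """
    info_by_id = {p.subject_id: p for p in patients}
    rows = []
    for sid, info in info_by_id.items():
        cand = [
            (i, ico[i].mean_co)
            for i, s in enumerate(samples)
            if s.subject_id == sid and ico[i].accepted
        ]
        if not cand:
            continue
        lo = min(cand, key=lambda x: x[1])[0]
        hi = max(cand, key=lambda x: x[1])[0]
        for i in {lo, hi}:
            s = samples[i]
            rows.append((info, s.pulse_pressure, s.hr, s.pwtt, ico[i].mean_co))
    return fit_patient_info_model(rows)


def calibrate_cohort(
    patients: Sequence[PatientInfo],
    samples: Sequence[HemodynamicSample],
    ico: Sequence[IcoMeasurement],
    mode: CalibrationMode = CalibrationMode.REFERENCE_CO,
    alpha: float = core_model.DEFAULT_ALPHA,
    beta: float = core_model.DEFAULT_BETA,
    model: Optional[PatientInfoModel] = None,
    reference_co: Optional[float] = None,
) -> Tuple[Dict[str, CalibrationState], Dict[str, int]]:
    """One calibration per subject at the first accepted reference point.

    In REFERENCE_CO mode the reference is the subject's first accepted
    thermodilution mean (or the ``reference_co`` override applied to every
    subject). In PATIENT_INFO mode it is the fitted regression's prediction
    at the calibration sample.
    """
    info_by_id = {p.subject_id: p for p in patients}
    cals: Dict[str, CalibrationState] = {}
    cal_index: Dict[str, int] = {}
    for sid in info_by_id:
        i = _first_accepted_index(samples, ico, sid)
        if i is None:
            continue
        s = samples[i]
        if mode == CalibrationMode.PATIENT_INFO:
            if model is None:
                raise ValueError("PATIENT_INFO mode requires a fitted model")
            ref = predict_reference_co(
                model, info_by_id[sid], s.pulse_pressure, s.hr, s.pwtt
            )
            if ref <= 0:
                continue  # prediction non-physiologic: no calibration
        else:
            ref = reference_co if reference_co is not None else ico[i].mean_co
        cals[sid] = core_model.calibrate_reference(ref, s, alpha=alpha, beta=beta, mode=mode)
        cal_index[sid] = i
    return cals, cal_index


def estimate_cohort(
    samples: Sequence[HemodynamicSample],
    calibrations: Dict[str, CalibrationState],
) -> List[EsccoEstimate]:
    """Apply each subject's calibration to every sample of that subject."""
    out: List[EsccoEstimate] = []
    for s in samples:
        cal = calibrations.get(s.subject_id)
        if cal is None:
            out.append(
                EsccoEstimate(sv=float("nan"), co=float("nan"), qc_flags=frozenset())
            )
        else:
            out.append(core_model.estimate(s, cal))
    return out


def build_pairs(
    samples: Sequence[HemodynamicSample],
    estimates: Sequence[EsccoEstimate],
    ico: Sequence[IcoMeasurement],
    exclusion: Optional[ExclusionReport] = None,
    skip_indices: Optional[Dict[str, int]] = None,
) -> List[PairedComparison]:
    """Pair retained estimates with accepted thermodilution means.

    Drops samples that are excluded, whose estimate is rejected or
    uncalibrated, or whose thermodilution triplicate failed the ±10% rule.
    ``skip_indices`` (subject → sample index) removes calibration points so
    agreement is judged at subsequent measurements only.
    """
    skip = set((skip_indices or {}).values())
    order: Dict[str, int] = {}
    pairs: List[PairedComparison] = []
    idx_sorted = sorted(
        range(len(samples)), key=lambda i: (samples[i].subject_id, samples[i].t)
    )
    for i in idx_sorted:
        s = samples[i]
        if i in skip:
            continue
        if exclusion is not None and exclusion.sample_flags[i]:
            continue
        if not ico[i].accepted:
            continue
        est = estimates[i]
        if not (np.isfinite(est.co) and est.co > 0):
            continue
        k = order.get(s.subject_id, 0)
        order[s.subject_id] = k + 1
        pairs.append(
            PairedComparison(
                subject_id=s.subject_id,
                time_index=k,
                test_co=est.co,
                ref_co=ico[i].mean_co,
            )
        )
    return pairs


def qc_performance(
    exclusion: ExclusionReport, truth: SyntheticTruth
) -> Tuple[float, float]:
    """(sensitivity, false-flag rate) of exclusion against injected truth."""
    flagged = exclusion.excluded_mask()
    artifact = truth.artifact_mask()
    n_art = int(artifact.sum())
    n_clean = int((~artifact).sum())
    sensitivity = float((flagged & artifact).sum() / n_art) if n_art else float("nan")
    false_rate = float((flagged & ~artifact).sum() / n_clean) if n_clean else float("nan")
    return sensitivity, false_rate


def run_study(
    patients: Sequence[PatientInfo],
    samples: Sequence[HemodynamicSample],
    ico: Sequence[IcoMeasurement],
    cohort: Optional[Cohort] = None,
    mode: CalibrationMode = CalibrationMode.REFERENCE_CO,
    alpha: float = core_model.DEFAULT_ALPHA,
    beta: float = core_model.DEFAULT_BETA,
    thresholds: QcThresholds = DEFAULT_THRESHOLDS,
    include_calibration_point: bool = False,
    central_zone: float = 0.5,
    concordance_limit: float = 30.0,
) -> StudyResult:
    """Calibrate, estimate, exclude, pair and evaluate one cohort."""
    model = None
    if mode == CalibrationMode.PATIENT_INFO:
        model = fit_calibration_from_cohort(patients, samples, ico)
    cals, cal_idx = calibrate_cohort(
        patients, samples, ico, mode=mode, alpha=alpha, beta=beta, model=model
    )
    estimates = estimate_cohort(samples, cals)
    exclusion = run_exclusion(samples, estimates, thresholds=thresholds)
    pairs = build_pairs(
        samples,
        estimates,
        ico,
        exclusion=exclusion,
        skip_indices=None if include_calibration_point else cal_idx,
    )
    if len(pairs) < 2:
        raise ValueError("fewer than 2 retained pairs: cannot evaluate agreement")
    agreement = evaluate(
        pairs, central_zone=central_zone, concordance_limit=concordance_limit
    )
    if cohort is None:
        cohort = Cohort(
            patients=list(patients),
            samples=list(samples),
            ico=list(ico),
            truth=SyntheticTruth([], [], [], {}, {}),
            config=SyntheticCohortConfig(),
        )
    return StudyResult(
        cohort=cohort,
        calibrations=cals,
        estimates=estimates,
        exclusion=exclusion,
        pairs=pairs,
        agreement=agreement,
        patient_info_model=model,
    )


def run_synthetic_study(
    config: Optional[SyntheticCohortConfig] = None,
    seed: Optional[int] = None,
    mode: CalibrationMode = CalibrationMode.REFERENCE_CO,
    **kwargs,
) -> StudyResult:
    """Generate a cohort from ``config``/``seed`` and run the full study."""
    cfg = config or SyntheticCohortConfig()
    cohort = generate_cohort(cfg, seed=seed)
    return run_study(
        cohort.patients,
        cohort.samples,
        cohort.ico,
        cohort=cohort,
        mode=mode,
        alpha=cfg.alpha,
        beta=cfg.beta,
        **kwargs,
    )
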