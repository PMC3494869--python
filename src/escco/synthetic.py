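"""Synthetic hemodynamic cohort generator with retained ground truth.

Emulates the statistical structure the analysis assumes: a perioperative
cohort (demographics matched to a cardiac-surgical population: age
65.3 ± 12.6 y, height 159.9 ± 10.3 cm, weight 59.1 ± 12.5 kg, two thirds
male), per-subject true cardiac output following a reflected Gaussian
random walk over the observed range 1.3–15.5 L/min, transit time generated
through the inverse of the linear SV–PWTT relation with a per-subject scale
K, proportional-noise thermodilution triplicates, and injectable artifacts
(transient tamponade-like SV/PWTT inconsistency, CPB context windows,
isolated R-wave detection errors) with exact labels.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from .types import (
    ContextTag,
    HemodynamicSample,
    IcoMeasurement,
    PatientInfo,
)

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticTruth",
    "Cohort",
    "generate_cohort",
    "inject_artifacts",
    "generate_regression_rows",
]

#: Default coefficients of the generating demographics→baseline-CO relation;
#: retained in the truth record so fits can be checked against them.
DEFAULT_BASELINE_CO_COEFFICIENTS = {
    "intercept": 3.0,
    "age": -0.02,
    "sex_indicator": 0.3,
    "height": 0.01,
    "weight": 0.03,
}


@dataclass
class SyntheticCohortConfig:
    """All knobs of the cohort generator, serializable to YAML.

    Demographic means/SDs follow the cardiac-surgical cohort the analysis
    targets; CO range and dynamics, noise levels and artifact rates are free
    parameters with physiologically plausible defaults.
    """

    n_subjects: int = 181
    pairs_per_subject: int = 3
    seed: int = 0

    # demographics
    age_mean: float = 65.3
    age_sd: float = 12.6
    height_mean: float = 159.9
    height_sd: float = 10.3
    weight_mean: float = 59.1
    weight_sd: float = 12.5
    male_fraction: float = 138.0 / 207.0

    # cardiac-output dynamics (L/min)
    co_range: Tuple[float, float] = (1.3, 15.5)
    co_walk_sd: float = 0.7
    baseline_co_sd: float = 0.8
    baseline_co_coefficients: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_CO_COEFFICIENTS)
    )

    # model constants and per-subject scale
    alpha: float = -0.5  # ml/ms
    beta: float = 150.0  # ml
    k_mean: float = 1.2
    k_sd: float = 0.1
    k_bounds: Tuple[float, float] = (1.0, 1.4)

    # physiology
    hr_median: float = 75.0  # beats/min, log-normal centre
    hr_log_sd: float = 0.15
    hr_bounds: Tuple[float, float] = (40.0, 140.0)
    sv_bounds: Tuple[float, float] = (25.0, 110.0)  # ml; HR adjusted to respect
    pp_per_ml: float = 0.5  # mmHg pulse pressure per ml stroke volume
    pp_noise_sd: float = 0.0  # mmHg
    dbp_mean: float = 60.0
    dbp_sd: float = 8.0
    beats_per_sample: int = 30
    rr_jitter_cv: float = 0.02

    # measurement noise
    pwtt_noise_sd: float = 4.0  # ms
    ico_noise_cv: float = 0.05  # proportional SD of each bolus value

    # artifact rates (per eligible sample)
    tamponade_prob: float = 0.01
    cpb_prob: float = 0.05
    r_wave_error_prob: float = 0.02
    tamponade_sv_factor: float = 0.35  # patterned on 39.7 → 13.6 ml
    tamponade_pwtt_factor: float = 0.8  # patterned on 199 → 157 ms

    def __post_init__(self) -> None:
        self.co_range = tuple(self.co_range)  # type: ignore[assignment]
        self.k_bounds = tuple(self.k_bounds)  # type: ignore[assignment]
        self.hr_bounds = tuple(self.hr_bounds)  # type: ignore[assignment]
        self.sv_bounds = tuple(self.sv_bounds)  # type: ignore[assignment]
        if not (0 < self.co_range[0] < self.co_range[1]):
            raise ValueError(f"co_range {self.co_range} must be positive and ordered")
        for name in ("co_walk_sd", "pwtt_noise_sd", "ico_noise_cv", "baseline_co_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tamponade_prob", "cpb_prob", "r_wave_error_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} must be in [0, 1]")
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero (inverse SV->PWTT undefined)")

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        for key in ("co_range", "k_bounds", "hr_bounds", "sv_bounds"):
            payload[key] = list(payload[key])
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


@dataclass
class SyntheticTruth:
    """Ground truth aligned one-to-one with the emitted samples."""

    true_co: List[float]
    true_sv: List[float]
    artifact_labels: List[Optional[str]]  # 'tamponade' | 'cpb' | 'r_wave' | None
    true_k: Dict[str, float]
    baseline_co_coefficients: Dict[str, float]

    def artifact_mask(self) -> np.ndarray:
        return np.array([lbl is not None for lbl in self.artifact_labels])

    def to_payload(self) -> dict:
        return {
            "true_co": list(map(float, self.true_co)),
            "true_sv": list(map(float, self.true_sv)),
            "artifact_labels": list(self.artifact_labels),
            "true_k": {k: float(v) for k, v in self.true_k.items()},
            "baseline_co_coefficients": dict(self.baseline_co_coefficients),
        }


@dataclass
class Cohort:
    """A generated cohort: demographics, samples, thermodilution, truth.

    ``ico`` is aligned one measurement per sample (triplicate bolus values
    at the same timestamp).
    """

    patients: List[PatientInfo]
    samples: List[HemodynamicSample]
    ico: List[IcoMeasurement]
    truth: SyntheticTruth
    config: SyntheticCohortConfig


def _reflect(x: float, lo: float, hi: float) -> float:
    # fold back into [lo, hi]; at most a few iterations for sane step sizes
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        else:
            x = 2 * hi - x
    return x


def _triplicate(co: float, cv: float, rng: np.random.Generator) -> Tuple[float, float, float]:
    vals = co * (1.0 + rng.normal(0.0, cv, size=3)) if cv > 0 else np.full(3, co)
    vals = np.maximum(vals, 0.1)  # thermodilution never reports <= 0
    return tuple(float(v) for v in vals)


def _sample_demographics(
    cfg: SyntheticCohortConfig, sid: str, rng: np.random.Generator
) -> PatientInfo:
    age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 18, 100))
    height = float(np.clip(rng.normal(cfg.height_mean, cfg.height_sd), 130, 200))
    weight = float(np.clip(rng.normal(cfg.weight_mean, cfg.weight_sd), 30, 150))
    sex = "M" if rng.random() < cfg.male_fraction else "F"
    return PatientInfo(subject_id=sid, age=age, sex=sex, height=height, weight=weight)


def generate_cohort(
    config: SyntheticCohortConfig,
    seed: Optional[int] = None,
    with_artifacts: bool = True,
) -> Cohort:
    """Generate a full cohort; byte-identical for identical config and seed.

    True CO follows a reflected random walk within ``co_range`` started at a
    demographics-dependent baseline; SV = CO·1000/HR (HR log-normal, adjusted
    to keep SV inside ``sv_bounds``); PWTT is the exact inverse of the
    SV–PWTT relation at the subject's true K plus Gaussian noise; pulse
    pressure is proportional to SV; each thermodilution bolus is the true CO
    times (1 + ε) with ε ~ Normal(0, ico_noise_cv).

    When ``with_artifacts`` is true (the default), artifacts are injected at
    the configured rates from the same random stream.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    coefs = dict(config.baseline_co_coefficients)
    lo, hi = config.co_range

    patients: List[PatientInfo] = []
    samples: List[HemodynamicSample] = []
    ico: List[IcoMeasurement] = []
    true_co: List[float] = []
    true_sv: List[float] = []
    labels: List[Optional[str]] = []
    true_k: Dict[str, float] = {}

    for i in range(config.n_subjects):
        sid = f"S{i + 1:04d}"
        info = _sample_demographics(config, sid, rng)
        patients.append(info)
        K = float(
            np.clip(rng.normal(config.k_mean, config.k_sd), *config.k_bounds)
        )
        true_k[sid] = K

        base = (
            coefs.get("intercept", 0.0)
            + coefs.get("age", 0.0) * info.age
            + coefs.get("sex_indicator", 0.0) * info.sex_indicator
            + coefs.get("height", 0.0) * info.height
            + coefs.get("weight", 0.0) * info.weight
        )
        if config.baseline_co_sd > 0:
            base += rng.normal(0.0, config.baseline_co_sd)
        co = _reflect(float(np.clip(base, lo + 0.5, hi - 3.0)), lo, hi)

        for j in range(config.pairs_per_subject):
            if j > 0 and config.co_walk_sd > 0:
                co = _reflect(co + float(rng.normal(0.0, config.co_walk_sd)), lo, hi)
            hr = float(
                np.clip(
                    config.hr_median * np.exp(rng.normal(0.0, config.hr_log_sd)),
                    *config.hr_bounds,
                )
            )
            sv = co * 1000.0 / hr
            sv_lo, sv_hi = config.sv_bounds
            if sv < sv_lo:
                sv = sv_lo
                hr = co * 1000.0 / sv
            elif sv > sv_hi:
                sv = sv_hi
                hr = co * 1000.0 / sv
            pwtt_true = (sv / K - config.beta) / config.alpha
            pwtt = pwtt_true
            if config.pwtt_noise_sd > 0:
                pwtt += float(rng.normal(0.0, config.pwtt_noise_sd))
            pp = config.pp_per_ml * sv
            if config.pp_noise_sd > 0:
                pp += float(rng.normal(0.0, config.pp_noise_sd))
            pp = max(pp, 5.0)
            dbp = float(np.clip(rng.normal(config.dbp_mean, config.dbp_sd), 40, 90))
            rr_mean = 60000.0 / hr
            rr = rr_mean * (
                1.0 + rng.normal(0.0, config.rr_jitter_cv, size=config.beats_per_sample)
            )
            t = 3600.0 * j  # hourly comparisons
            samples.append(
                HemodynamicSample(
                    subject_id=sid,
                    t=t,
                    hr=hr,
                    pwtt=pwtt,
                    sbp=dbp + pp,
                    dbp=dbp,
                    context=frozenset({ContextTag.NONE.value}),
                    rr_intervals=tuple(float(v) for v in rr),
                )
            )
            vals = _triplicate(co, config.ico_noise_cv, rng)
            mean = sum(vals) / 3.0
            max_dev = max(abs(v - mean) for v in vals) / mean
            ico.append(
                IcoMeasurement(
                    subject_id=sid,
                    t=t,
                    injectate_values=vals,
                    mean_co=mean,
                    accepted=bool(max_dev <= 0.10 + 1e-12),
                )
            )
            true_co.append(co)
            true_sv.append(sv)
            labels.append(None)

    truth = SyntheticTruth(
        true_co=true_co,
        true_sv=true_sv,
        artifact_labels=labels,
        true_k=true_k,
        baseline_co_coefficients=coefs,
    )
    cohort = Cohort(
        patients=patients, samples=samples, ico=ico, truth=truth, config=config
    )
    if with_artifacts and (
        config.tamponade_prob > 0 or config.cpb_prob > 0 or config.r_wave_error_prob > 0
    ):
        cohort = inject_artifacts(cohort, config, rng)
    return cohort


def inject_artifacts(
    cohort: Cohort,
    config: Optional[SyntheticCohortConfig] = None,
    rng: Union[np.random.Generator, int, None] = None,
) -> Cohort:
    """Inject labelled artifacts into a generated cohort (in place).

    * tamponade — a transient single-sample event: SV multiplied by
      ``tamponade_sv_factor`` and PWTT by ``tamponade_pwtt_factor`` relative
      to the previous sample (the concordant-decrease pattern of pericardial
      compression), with pulse pressure and thermodilution regenerated from
      the reduced true CO; requires a preceding unmodified sample;
    * cpb — the sample gains the CPB context tag;
    * r_wave — one interior RR interval is halved or doubled (double
      detection / missed beat).

    A sample receives at most one artifact; labels are recorded in the truth
    record exactly where injected. Zero rates leave the cohort unchanged.
    """
    cfg = config or cohort.config
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    by_index: Dict[str, List[int]] = {}
    for idx, s in enumerate(cohort.samples):
        by_index.setdefault(s.subject_id, []).append(idx)

    for sid, idxs in by_index.items():
        idxs = sorted(idxs, key=lambda i: cohort.samples[i].t)
        for pos, idx in enumerate(idxs):
            if cohort.truth.artifact_labels[idx] is not None:
                continue
            s = cohort.samples[idx]
            u = rng.random()
            if u < cfg.tamponade_prob:
                # needs an unmodified predecessor to define the transition
                if pos == 0 or cohort.truth.artifact_labels[idxs[pos - 1]] is not None:
                    continue
                prev = cohort.samples[idxs[pos - 1]]
                sv = cfg.tamponade_sv_factor * cohort.truth.true_sv[idxs[pos - 1]]
                pwtt = cfg.tamponade_pwtt_factor * prev.pwtt
                co = sv * s.hr / 1000.0
                pp = max(cfg.pp_per_ml * sv, 5.0)
                cohort.samples[idx] = dataclasses.replace(
                    s, pwtt=pwtt, sbp=s.dbp + pp
                )
                vals = _triplicate(co, cfg.ico_noise_cv, rng)
                mean = sum(vals) / 3.0
                max_dev = max(abs(v - mean) for v in vals) / mean
                cohort.ico[idx] = IcoMeasurement(
                    subject_id=sid,
                    t=s.t,
                    injectate_values=vals,
                    mean_co=mean,
                    accepted=bool(max_dev <= 0.10 + 1e-12),
                )
                cohort.truth.true_sv[idx] = sv
                cohort.truth.true_co[idx] = co
                cohort.truth.artifact_labels[idx] = "tamponade"
            elif u < cfg.tamponade_prob + cfg.cpb_prob:
                cohort.samples[idx] = dataclasses.replace(
                    s, context=frozenset({ContextTag.CPB.value})
                )
                cohort.truth.artifact_labels[idx] = "cpb"
            elif u < cfg.tamponade_prob + cfg.cpb_prob + cfg.r_wave_error_prob:
                if s.rr_intervals is None or len(s.rr_intervals) < 5:
                    continue
                rr = list(s.rr_intervals)
                beat = int(rng.integers(2, len(rr) - 2))
                rr[beat] = rr[beat] * (0.5 if rng.random() < 0.5 else 2.0)
                cohort.samples[idx] = dataclasses.replace(s, rr_intervals=tuple(rr))
                cohort.truth.artifact_labels[idx] = "r_wave"
    return cohort


def generate_regression_rows(
    coefficients: Dict[str, float],
    n: int,
    noise_sd: float,
    rng: Union[np.random.Generator, int, None] = None,
    config: Optional[SyntheticCohortConfig] = None,
) -> List[Tuple[PatientInfo, float, float, float, float]]:
    """Rows from a known affine generating model for calibration fitting.

    Draws demographics and physiological predictors from the cohort
    distributions, then sets reference_co = affine(coefficients) + Gaussian
    noise. Used to exercise coefficient recovery of the patient-information
    regression against known truth.
    """
    cfg = config or SyntheticCohortConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    for i in range(n):
        info = _sample_demographics(cfg, f"R{i + 1:04d}", rng)
        pp = float(rng.uniform(20.0, 60.0))
        hr = float(rng.uniform(*cfg.hr_bounds))
        pwtt = float(rng.uniform(100.0, 260.0))
        x = {
            "age": info.age,
            "sex_indicator": info.sex_indicator,
            "height": info.height,
            "weight": info.weight,
            "pulse_pressure": pp,
            "hr": hr,
            "pwtt": pwtt,
        }
        y = coefficients.get("intercept", 0.0) + sum(
            coefficients.get(k, 0.0) * v for k, v in x.items()
        )
        if noise_sd > 0:
            y += float(rng.normal(0.0, noise_sd))
        rows.append((info, pp, hr, pwtt, y))
    return rows
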