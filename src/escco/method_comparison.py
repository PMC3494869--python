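"""Agreement and trending statistics for paired cardiac-output methods.

Implements Bland–Altman limits of agreement (plain and with the
repeated-measures correction via one-way variance components of the
differences), the percentage error 2·SD/mean(reference), Pearson
correlation, and Critchley-style polar-plot trend analysis of successive CO
changes (half-circle transform, central-zone exclusion, angular bias,
radial limits and 30° concordance).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .types import PairedComparison

__all__ = [
    "LOA_MULTIPLIER",
    "ACCEPTABLE_PERCENTAGE_ERROR",
    "BlandAltmanResult",
    "CoDelta",
    "DeltaPair",
    "PolarResult",
    "AgreementReport",
    "bland_altman",
    "repeated_measures_sd",
    "percentage_error",
    "compute_deltas",
    "polar_analysis",
    "evaluate",
]

#: Two-sided 95% limits multiplier.
LOA_MULTIPLIER = 1.96
#: Conventional interchangeability bound on the percentage error (%).
ACCEPTABLE_PERCENTAGE_ERROR = 30.0

_EPS = 1e-12


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias, spread and limits of agreement of test−reference differences."""

    bias: float  # L/min
    sd: float  # L/min, sample SD (n−1)
    sd_corrected: float  # L/min, repeated-measures-corrected SD
    loa_lower: float  # L/min
    loa_upper: float  # L/min
    percentage_error: float  # %
    r: float  # Pearson correlation of test vs reference
    n: int

    @property
    def percentage_error_acceptable(self) -> bool:
        return self.percentage_error <= ACCEPTABLE_PERCENTAGE_ERROR


@dataclass(frozen=True)
class CoDelta:
    """One successive within-subject change of both methods (L/min)."""

    subject_id: str
    d_ref: float
    d_test: float


@dataclass(frozen=True)
class DeltaPair:
    """A CO-change pair after the half-circle transform, with polar geometry.

    ``angle_deg`` is measured from the 45° identity line; ``included`` marks
    survival of the central-zone filter (mean change ≥ the zone radius).
    """

    d_ref: float
    d_test: float
    mean_change: float  # (d_ref + d_test)/2 post-reflection, ≥ 0
    angle_deg: float
    included: bool


@dataclass(frozen=True)
class PolarResult:
    """Polar-plot trending statistics over included delta pairs."""

    angular_bias_deg: float
    radial_loa_deg: float  # half-width: ±multiplier·SD of angles (or percentile)
    radial_limits: Tuple[float, float]  # (lower, upper) angle limits, degrees
    concordance_rate_30: float  # % of included angles with |angle| ≤ limit
    n_included: int
    n_central_excluded: int
    concordance_limit_deg: float = 30.0
    undefined: bool = False  # True when no pair survives the central zone


def _diffs(pairs: Sequence[PairedComparison]) -> np.ndarray:
    return np.array([p.test_co - p.ref_co for p in pairs], dtype=float)


def percentage_error(sd: float, mean_ref: float) -> float:
    """Percentage error: 2·SD of the differences over the mean reference CO.

    Values at or below 30% are conventionally regarded as clinically
    interchangeable with the reference method.
    """
    if sd < 0:
        raise ValueError(f"sd={sd} must be non-negative")
    if mean_ref <= 0:
        raise ValueError(f"mean_ref={mean_ref} must be positive")
    return 2.0 * sd / mean_ref * 100.0


def repeated_measures_sd(pairs: Sequence[PairedComparison]) -> float:
    """SD of differences corrected for repeated measurements per subject.

    With several pairs per subject the plain SD of pooled differences
    underestimates the population spread. A one-way random-effects
    decomposition of the differences by subject (method of moments on the
    ANOVA mean squares, unbalanced-design weighting) gives

        var = between-subject component + within-subject component,

    with a negative between component truncated at zero. When every subject
    contributes a single pair the corrected SD equals the plain sample SD;
    with a single subject it falls back to the plain SD with a warning.
    """
    d = _diffs(pairs)
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    groups: Dict[str, List[float]] = {}
    for p, di in zip(pairs, d):
        groups.setdefault(p.subject_id, []).append(di)
    k = len(groups)
    N = d.size
    if k < 2:
        warnings.warn(
            "single subject: repeated-measures correction undefined, "
            "returning plain SD",
            stacklevel=2,
        )
        return float(np.std(d, ddof=1))
    if N == k:  # one pair per subject: no replication, plain SD
        return float(np.std(d, ddof=1))
    sizes = np.array([len(g) for g in groups.values()], dtype=float)
    means = np.array([np.mean(g) for g in groups.values()])
    grand = d.mean()
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups.values()))
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k) if N > k else 0.0
    n0 = (N - float(np.sum(sizes**2)) / N) / (k - 1)
    var_between = max(0.0, (ms_between - ms_within) / n0)
    return float(math.sqrt(var_between + ms_within))


def bland_altman(
    pairs: Sequence[PairedComparison],
    multiplier: float = LOA_MULTIPLIER,
) -> BlandAltmanResult:
    """Bland–Altman agreement analysis of test vs reference CO pairs.

    Limits of agreement are bias ± ``multiplier``·SD with the sample SD
    (n−1); the percentage error uses the plain SD and the mean reference CO.
    The repeated-measures-corrected SD is reported alongside.
    """
    if len(pairs) < 2:
        raise ValueError(f"need at least 2 pairs, got {len(pairs)}")
    d = _diffs(pairs)
    ref = np.array([p.ref_co for p in pairs])
    test = np.array([p.test_co for p in pairs])
    bias = float(d.mean())
    sd = float(np.std(d, ddof=1))
    sd_c = repeated_measures_sd(pairs)
    if np.std(ref) < _EPS or np.std(test) < _EPS:
        r = float("nan")  # correlation undefined for a constant method
    else:
        r = float(stats.pearsonr(test, ref).statistic)
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        sd_corrected=sd_c,
        loa_lower=bias - multiplier * sd,
        loa_upper=bias + multiplier * sd,
        percentage_error=percentage_error(sd, float(ref.mean())),
        r=r,
        n=len(pairs),
    )


def compute_deltas(pairs: Sequence[PairedComparison]) -> List[CoDelta]:
    """Successive within-subject CO changes (current minus previous).

    Pairs are grouped by subject and ordered by time index; one delta per
    consecutive pair, never across subjects. A subject with a single pair
    contributes no deltas.
    """
    by_subject: Dict[str, List[PairedComparison]] = {}
    for p in pairs:
        by_subject.setdefault(p.subject_id, []).append(p)
    deltas: List[CoDelta] = []
    for sid, ps in by_subject.items():
        ps = sorted(ps, key=lambda p: p.time_index)
        idx = [p.time_index for p in ps]
        if len(set(idx)) != len(idx):
            raise ValueError(f"duplicate time_index within subject {sid!r}")
        for prev, curr in zip(ps, ps[1:]):
            deltas.append(
                CoDelta(
                    subject_id=sid,
                    d_ref=curr.ref_co - prev.ref_co,
                    d_test=curr.test_co - prev.test_co,
                )
            )
    return deltas


def polar_analysis(
    deltas: Sequence[CoDelta],
    central_zone: float = 0.5,
    concordance_limit: float = 30.0,
    multiplier: float = LOA_MULTIPLIER,
    radial_method: str = "sd",
) -> Tuple[PolarResult, List[DeltaPair]]:
    """Polar-plot trend analysis of paired CO changes.

    Each change pair maps to polar coordinates: the radius is the mean change
    (d_ref + d_test)/2 and the angle is measured from the 45° identity line,
    ``atan2(d_test, d_ref) − 45°``. Negative-direction pairs (mean change
    < 0) are reflected through the origin (half-circle transform) so all
    points plot in the positive half; post-reflection angles lie in
    (−90°, 90°]. Pairs with mean change below ``central_zone`` L/min are
    excluded as uninformative (the 0.5 boundary itself is included).

    ``radial_method`` selects the radial limits of agreement: ``"sd"`` gives
    angular bias ± multiplier·SD of the included angles; ``"percentile"``
    gives the empirical 2.5th/97.5th percentiles.
    """
    if len(deltas) == 0:
        raise ValueError("need at least one delta pair")
    if radial_method not in ("sd", "percentile"):
        raise ValueError(f"radial_method must be 'sd' or 'percentile', got {radial_method!r}")
    out: List[DeltaPair] = []
    for dl in deltas:
        d_ref, d_test = dl.d_ref, dl.d_test
        if (d_ref + d_test) / 2.0 < 0:
            d_ref, d_test = -d_ref, -d_test
        mean_change = (d_ref + d_test) / 2.0
        angle = math.degrees(math.atan2(d_test, d_ref)) - 45.0
        out.append(
            DeltaPair(
                d_ref=d_ref,
                d_test=d_test,
                mean_change=mean_change,
                angle_deg=angle,
                included=mean_change >= central_zone - _EPS,
            )
        )
    angles = np.array([p.angle_deg for p in out if p.included])
    n_inc = int(angles.size)
    n_exc = len(out) - n_inc
    if n_inc == 0:
        result = PolarResult(
            angular_bias_deg=float("nan"),
            radial_loa_deg=float("nan"),
            radial_limits=(float("nan"), float("nan")),
            concordance_rate_30=float("nan"),
            n_included=0,
            n_central_excluded=n_exc,
            concordance_limit_deg=concordance_limit,
            undefined=True,
        )
        return result, out
    bias = float(angles.mean())
    if radial_method == "sd":
        spread = float(np.std(angles, ddof=1)) if n_inc > 1 else 0.0
        half = multiplier * spread
        limits = (bias - half, bias + half)
    else:
        lo, hi = np.percentile(angles, [2.5, 97.5])
        limits = (float(lo), float(hi))
        half = float(max(abs(lo - bias), abs(hi - bias)))
    conc = float(np.mean(np.abs(angles) <= concordance_limit + _EPS) * 100.0)
    result = PolarResult(
        angular_bias_deg=bias,
        radial_loa_deg=half,
        radial_limits=limits,
        concordance_rate_30=conc,
        n_included=n_inc,
        n_central_excluded=n_exc,
        concordance_limit_deg=concordance_limit,
    )
    return result, out


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement and trending report for one paired dataset."""

    bland_altman: BlandAltmanResult
    polar: Optional[PolarResult]
    delta_pairs: Tuple[DeltaPair, ...]

    def to_payload(self) -> dict:
        ba = self.bland_altman
        payload = {
            "bland_altman": {
                "bias": ba.bias,
                "sd": ba.sd,
                "sd_corrected": ba.sd_corrected,
                "loa_lower": ba.loa_lower,
                "loa_upper": ba.loa_upper,
                "percentage_error": ba.percentage_error,
                "percentage_error_acceptable": ba.percentage_error_acceptable,
                "r": ba.r,
                "n": ba.n,
            },
            "polar": None,
        }
        if self.polar is not None:
            po = self.polar
            payload["polar"] = {
                "angular_bias_deg": po.angular_bias_deg,
                "radial_loa_deg": po.radial_loa_deg,
                "radial_limits": list(po.radial_limits),
                "concordance_rate_30": po.concordance_rate_30,
                "concordance_limit_deg": po.concordance_limit_deg,
                "n_included": po.n_included,
                "n_central_excluded": po.n_central_excluded,
                "undefined": po.undefined,
            }
        return payload


def evaluate(
    pairs: Sequence[PairedComparison],
    central_zone: float = 0.5,
    concordance_limit: float = 30.0,
    radial_method: str = "sd",
) -> AgreementReport:
    """Run the full agreement suite: Bland–Altman plus polar trend analysis.

    Deterministic in its input; subject ordering does not matter. With no
    within-subject successive pairs the polar section is None.
    """
    if len(pairs) == 0:
        raise ValueError("empty input: no pairs to evaluate")
    ba = bland_altman(pairs)
    deltas = compute_deltas(pairs)
    if deltas:
        polar, dps = polar_analysis(
            deltas,
            central_zone=central_zone,
            concordance_limit=concordance_limit,
            radial_method=radial_method,
        )
    else:
        polar, dps = None, []
    return AgreementReport(
        bland_altman=ba, polar=polar, delta_pairs=tuple(dps)
    )
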