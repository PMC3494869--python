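"""Patient-information cardiac-output calibration.

A multiple linear regression predicts a reference CO from demographics
(age, sex, height, weight), pulse pressure, heart rate and PWTT. The
prediction replaces an invasive thermodilution reference when fixing the
scale factor K of the SV–PWTT relation, making the whole chain
non-invasive. Coefficients are always treated as data — fitted from a
training table or loaded from JSON — never as built-in constants.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import PatientInfo

__all__ = [
    "PREDICTORS",
    "PatientInfoModel",
    "build_training_frame",
    "fit_patient_info_model",
    "predict_reference_co",
]

#: Predictor order of the calibration regression (intercept is separate).
PREDICTORS = ("age", "sex_indicator", "height", "weight", "pulse_pressure", "hr", "pwtt")


class UnfittedModelError(RuntimeError):
    """Raised when prediction is attempted with no fitted coefficients."""


class CollinearityError(ValueError):
    """Raised when the design matrix is rank deficient, naming the columns."""


@dataclass
class PatientInfoModel:
    """Fitted calibration regression: intercept plus one weight per predictor.

    ``coefficients`` maps ``"intercept"`` and each predictor name to its
    weight (L/min per predictor unit). ``stderr`` holds OLS standard errors,
    used for confidence intervals. ``predictor_ranges`` records the training
    min/max of each predictor so out-of-range prediction can warn.
    """

    coefficients: Dict[str, float]
    stderr: Dict[str, float] = field(default_factory=dict)
    n: int = 0
    residual_sd: float = float("nan")
    r_squared: float = float("nan")
    predictor_ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    include_bsa: bool = False

    @property
    def fitted(self) -> bool:
        return bool(self.coefficients)

    def predictor_names(self) -> Tuple[str, ...]:
        names = PREDICTORS + (("bsa",) if self.include_bsa else ())
        return names

    def to_json(self, path) -> None:
        payload = {
            "coefficients": self.coefficients,
            "stderr": self.stderr,
            "n": self.n,
            "residual_sd": self.residual_sd,
            "r_squared": self.r_squared,
            "predictor_ranges": {k: list(v) for k, v in self.predictor_ranges.items()},
            "include_bsa": self.include_bsa,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PatientInfoModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            coefficients=dict(payload["coefficients"]),
            stderr=dict(payload.get("stderr", {})),
            n=int(payload.get("n", 0)),
            residual_sd=float(payload.get("residual_sd", float("nan"))),
            r_squared=float(payload.get("r_squared", float("nan"))),
            predictor_ranges={
                k: (float(v[0]), float(v[1]))
                for k, v in payload.get("predictor_ranges", {}).items()
            },
            include_bsa=bool(payload.get("include_bsa", False)),
        )


def build_training_frame(
    rows: Sequence[Tuple[PatientInfo, float, float, float, float]],
    include_bsa: bool = False,
) -> pd.DataFrame:
    """Assemble the regression table from (info, pulse_pressure, hr, pwtt, reference_co) rows.

    Body surface area enters only when ``include_bsa`` is set: the regression
    inputs are age, sex, height and weight by default, with BSA available as
    an optional derived covariate.
    """
    records = []
    for info, pp, hr, pwtt, ref_co in rows:
        rec = {
            "subject_id": info.subject_id,
            "age": info.age,
            "sex_indicator": info.sex_indicator,
            "height": info.height,
            "weight": info.weight,
            "pulse_pressure": pp,
            "hr": hr,
            "pwtt": pwtt,
            "reference_co": ref_co,
        }
        if include_bsa:
            rec["bsa"] = info.bsa
        records.append(rec)
    return pd.DataFrame.from_records(records)


def _collinear_columns(X: pd.DataFrame) -> list:
    """Columns (after the first) lying in the span of the preceding ones."""
    bad = []
    arr = X.to_numpy(dtype=float)
    for j in range(1, arr.shape[1]):
        prev = arr[:, :j]
        col = arr[:, j]
        coef, *_ = np.linalg.lstsq(prev, col, rcond=None)
        resid = col - prev @ coef
        scale = np.linalg.norm(col) or 1.0
        if np.linalg.norm(resid) / scale < 1e-10:
            bad.append(X.columns[j])
    return bad


def fit_patient_info_model(
    rows_or_frame,
    include_bsa: bool = False,
) -> PatientInfoModel:
    """Fit the calibration regression by ordinary least squares.

    Accepts either a sequence of ``(PatientInfo, pulse_pressure, hr, pwtt,
    reference_co)`` tuples or a prebuilt DataFrame with those columns. In the
    study design each patient contributes two rows (the maximum and minimum
    reference CO), which is supported naturally — rows are the unit of fit.

    Raises
    ------
    CollinearityError
        When the design matrix is rank deficient; the message names the
        collinear predictors.
    ValueError
        When there are too few rows to identify the coefficients.
    """
    if isinstance(rows_or_frame, pd.DataFrame):
        frame = rows_or_frame
        if include_bsa and "bsa" not in frame.columns:
            raise ValueError("include_bsa=True but frame has no 'bsa' column")
    else:
        frame = build_training_frame(rows_or_frame, include_bsa=include_bsa)

    names = list(PREDICTORS) + (["bsa"] if include_bsa else [])
    X = frame[names].astype(float)
    y = frame["reference_co"].astype(float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} rows to fit, got {n}")

    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        bad = _collinear_columns(design)
        raise CollinearityError(
            f"design matrix is rank deficient; collinear predictors: {bad}"
        )

    fit = sm.OLS(y, design).fit()
    coefs = {("intercept" if k == "const" else k): float(v) for k, v in fit.params.items()}
    stderr = {("intercept" if k == "const" else k): float(v) for k, v in fit.bse.items()}
    return PatientInfoModel(
        coefficients=coefs,
        stderr=stderr,
        n=int(n),
        residual_sd=float(np.sqrt(fit.mse_resid)),
        r_squared=float(fit.rsquared),
        predictor_ranges={c: (float(X[c].min()), float(X[c].max())) for c in names},
        include_bsa=include_bsa,
    )


def predict_reference_co(
    model: PatientInfoModel,
    info: PatientInfo,
    pulse_pressure: float,
    hr: float,
    pwtt: float,
) -> float:
    """Predicted reference cardiac output (L/min) for one patient state.

    The affine evaluation of the fitted model; the result serves as the
    reference CO for scale calibration in patient-information mode. Predictor
    values outside the fitted ranges trigger a warning, not an error.
    """
    if not model.fitted:
        raise UnfittedModelError("patient-information model has no coefficients")
    values = {
        "age": info.age,
        "sex_indicator": info.sex_indicator,
        "height": info.height,
        "weight": info.weight,
        "pulse_pressure": pulse_pressure,
        "hr": hr,
        "pwtt": pwtt,
    }
    if model.include_bsa:
        values["bsa"] = info.bsa
    for name, val in values.items():
        rng = model.predictor_ranges.get(name)
        if rng is not None and not (rng[0] <= val <= rng[1]):
            warnings.warn(
                f"predictor {name}={val:g} outside fitted range [{rng[0]:g}, {rng[1]:g}]",
                stacklevel=2,
            )
    pred = model.coefficients.get("intercept", 0.0)
    for name in model.predictor_names():
        pred += model.coefficients.get(name, 0.0) * values[name]
    return float(pred)
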