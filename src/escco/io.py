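"""CSV/JSON/YAML round-tripping for every schema the pipeline exchanges.

Schemas
-------
samples       subject_id,t,hr,pwtt,sbp,dbp,context   (context ';'-joined tags)
beats         subject_id,t,rr_ms                     (one row per beat)
beat events   subject_id,r_time_ms,pulse_arrival_ms
demographics  subject_id,age,sex,height_cm,weight_kg
ico           subject_id,t,ico1,ico2,ico3
estimates     subject_id,t,hr,pwtt,sv,co,qc_flags    (flags ';'-joined)
pairs         subject_id,time_index,test_co,ref_co

JSON reports round floating-point values to 6 significant digits; CSV
exports keep full precision. Report payloads never embed wall-clock
timestamps, so identical runs produce identical bytes.
"""

from __future__ import annotations

import json
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exclusion_qc import ExclusionReport, check_triplicate_ico
from .types import (
    BeatEvents,
    EsccoEstimate,
    HemodynamicSample,
    IcoMeasurement,
    PairedComparison,
    PatientInfo,
)

__all__ = [
    "read_samples_csv",
    "write_samples_csv",
    "read_beats_csv",
    "write_beats_csv",
    "read_beat_events_csv",
    "write_beat_events_csv",
    "read_demographics_csv",
    "write_demographics_csv",
    "read_ico_csv",
    "write_ico_csv",
    "read_estimates_csv",
    "write_estimates_csv",
    "read_pairs_csv",
    "write_pairs_csv",
    "write_report_json",
    "read_report_json",
    "write_exclusion_report",
]


def _round_sig(x, digits: int = 6):
    """Recursively round floats to ``digits`` significant digits."""
    if isinstance(x, dict):
        return {k: _round_sig(v, digits) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round_sig(v, digits) for v in x]
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, np.integer)):
        return int(x)
    if isinstance(x, (float, np.floating)):
        x = float(x)
        if not math.isfinite(x) or x == 0.0:
            return x
        return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))
    return x


# -- samples ----------------------------------------------------------------

def write_samples_csv(samples: Sequence[HemodynamicSample], path) -> None:
    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in samples],
            "t": [s.t for s in samples],
            "hr": [s.hr for s in samples],
            "pwtt": [s.pwtt for s in samples],
            "sbp": [s.sbp for s in samples],
            "dbp": [s.dbp for s in samples],
            "context": [";".join(sorted(s.context)) for s in samples],
        }
    ).to_csv(path, index=False)


def read_samples_csv(path, beats_path=None) -> List[HemodynamicSample]:
    """Read samples; optionally attach beat RR intervals from a beats CSV."""
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    rr_map: Dict[Tuple[str, float], Tuple[float, ...]] = {}
    if beats_path is not None:
        beats = pd.read_csv(beats_path, dtype={"subject_id": str}, float_precision="round_trip")
        for (sid, t), grp in beats.groupby(["subject_id", "t"], sort=False):
            rr_map[(sid, float(t))] = tuple(grp["rr_ms"].astype(float))
    out = []
    for _, row in df.iterrows():
        ctx = frozenset(
            tag for tag in str(row["context"]).split(";") if tag and tag != "nan"
        )
        out.append(
            HemodynamicSample(
                subject_id=row["subject_id"],
                t=float(row["t"]),
                hr=float(row["hr"]),
                pwtt=float(row["pwtt"]),
                sbp=float(row["sbp"]),
                dbp=float(row["dbp"]),
                context=ctx or frozenset({"NONE"}),
                rr_intervals=rr_map.get((row["subject_id"], float(row["t"]))),
            )
        )
    return out


def write_beats_csv(samples: Sequence[HemodynamicSample], path) -> None:
    """One row per beat for samples that carry RR intervals."""
    rows = [
        {"subject_id": s.subject_id, "t": s.t, "rr_ms": rr}
        for s in samples
        if s.rr_intervals is not None
        for rr in s.rr_intervals
    ]
    pd.DataFrame(rows, columns=["subject_id", "t", "rr_ms"]).to_csv(path, index=False)


def read_beats_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")


# -- beat events ------------------------------------------------------------

def write_beat_events_csv(events: Sequence[BeatEvents], path) -> None:
    rows = [
        {"subject_id": ev.subject_id, "r_time_ms": r, "pulse_arrival_ms": a}
        for ev in events
        for r, a in zip(ev.r_times, ev.pulse_arrival_times)
    ]
    pd.DataFrame(
        rows, columns=["subject_id", "r_time_ms", "pulse_arrival_ms"]
    ).to_csv(path, index=False)


def read_beat_events_csv(path) -> List[BeatEvents]:
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        out.append(
            BeatEvents(
                subject_id=sid,
                r_times=tuple(grp["r_time_ms"].astype(float)),
                pulse_arrival_times=tuple(grp["pulse_arrival_ms"].astype(float)),
            )
        )
    return out


# -- demographics -----------------------------------------------------------

def write_demographics_csv(patients: Sequence[PatientInfo], path) -> None:
    pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in patients],
            "age": [p.age for p in patients],
            "sex": [p.sex for p in patients],
            "height_cm": [p.height for p in patients],
            "weight_kg": [p.weight for p in patients],
        }
    ).to_csv(path, index=False)


def read_demographics_csv(path) -> List[PatientInfo]:
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    return [
        PatientInfo(
            subject_id=row["subject_id"],
            age=float(row["age"]),
            sex=str(row["sex"]),
            height=float(row["height_cm"]),
            weight=float(row["weight_kg"]),
        )
        for _, row in df.iterrows()
    ]


# -- thermodilution ---------------------------------------------------------

def write_ico_csv(measurements: Sequence[IcoMeasurement], path) -> None:
    pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in measurements],
            "t": [m.t for m in measurements],
            "ico1": [m.injectate_values[0] for m in measurements],
            "ico2": [m.injectate_values[1] for m in measurements],
            "ico3": [m.injectate_values[2] for m in measurements],
        }
    ).to_csv(path, index=False)


def read_ico_csv(path, tolerance: float = 0.10) -> List[IcoMeasurement]:
    """Read triplicates; mean and acceptance are recomputed on read."""
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    return [
        check_triplicate_ico(
            (float(row["ico1"]), float(row["ico2"]), float(row["ico3"])),
            subject_id=row["subject_id"],
            t=float(row["t"]),
            tolerance=tolerance,
        )
        for _, row in df.iterrows()
    ]


# -- estimates --------------------------------------------------------------

def write_estimates_csv(
    samples: Sequence[HemodynamicSample],
    estimates: Sequence[EsccoEstimate],
    path,
) -> None:
    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in samples],
            "t": [s.t for s in samples],
            "hr": [s.hr for s in samples],
            "pwtt": [s.pwtt for s in samples],
            "sv": [e.sv for e in estimates],
            "co": [e.co for e in estimates],
            "qc_flags": [";".join(sorted(e.qc_flags)) for e in estimates],
        }
    ).to_csv(path, index=False)


def read_estimates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    df["qc_flags"] = df["qc_flags"].fillna("")
    return df


def estimates_from_frame(df: pd.DataFrame) -> List[EsccoEstimate]:
    return [
        EsccoEstimate(
            sv=float(row["sv"]),
            co=float(row["co"]),
            qc_flags=frozenset(f for f in str(row["qc_flags"]).split(";") if f),
        )
        for _, row in df.iterrows()
    ]


# -- pairs ------------------------------------------------------------------

def write_pairs_csv(pairs: Sequence[PairedComparison], path) -> None:
    pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in pairs],
            "time_index": [p.time_index for p in pairs],
            "test_co": [p.test_co for p in pairs],
            "ref_co": [p.ref_co for p in pairs],
        }
    ).to_csv(path, index=False)


def read_pairs_csv(path) -> List[PairedComparison]:
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    return [
        PairedComparison(
            subject_id=row["subject_id"],
            time_index=int(row["time_index"]),
            test_co=float(row["test_co"]),
            ref_co=float(row["ref_co"]),
        )
        for _, row in df.iterrows()
    ]


# -- reports ----------------------------------------------------------------

def write_report_json(payload: dict, path, digits: int = 6) -> None:
    """Serialize a report with floats at ``digits`` significant digits."""
    with open(path, "w") as fh:
        json.dump(_round_sig(payload, digits), fh, indent=2, allow_nan=True)
        fh.write("\n")


def read_report_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_exclusion_report(
    report: ExclusionReport,
    samples: Sequence[HemodynamicSample],
    json_path=None,
    csv_path=None,
) -> None:
    """Exclusion report as JSON plus a CSV of excluded samples."""
    if json_path is not None:
        write_report_json(report.to_payload(), json_path)
    if csv_path is not None:
        rows = [
            {
                "subject_id": s.subject_id,
                "t": s.t,
                "rules": ";".join(sorted(flags)),
            }
            for s, flags in zip(samples, report.sample_flags)
            if flags
        ]
        pd.DataFrame(rows, columns=["subject_id", "t", "rules"]).to_csv(
            csv_path, index=False
        )
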