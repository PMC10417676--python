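"""CSV and report I/O.

Two input tables are exchanged as comma-separated UTF-8 files with a
mandatory header row and '.' decimal point:

* ``plates.csv`` — ``patient_id,timepoint,plate_id,n_urine,n_control,
  n_elsewhere,dilution``.  ``dilution`` may be omitted (defaults to 100).
  ``n_elsewhere`` may be omitted only when an ``n_total`` column is
  present, in which case n_elsewhere = n_total - n_urine - n_control.
* ``cohort.csv`` — ``patient_id,age,sex,cT,cN,cM,stage,response`` plus an
  optional ``excluded_reason`` column for CONSORT-style flow accounting.

Reports serialize to JSON (lossless round trip) or TSV (one row per
score × endpoint of the ROC table).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    CohortFlow,
    GroupComparison,
    PatientRecord,
    PlateAssay,
    Response,
    RocPoint,
    RocResult,
    SampleCI,
    SchemaError,
    Stage,
    StudyReport,
    Timepoint,
    ValidationError,
)

logger = logging.getLogger(__name__)

PLATE_COLUMNS = ("patient_id", "timepoint", "plate_id", "n_urine", "n_control")
COHORT_COLUMNS = ("patient_id", "age", "sex", "cT", "cN", "cM", "stage", "response")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )


def _int_count(value, column: str, row: int) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}: {column} must be an integer, got {value!r}"
        ) from None
    if not f.is_integer():
        raise ValidationError(f"row {row}: {column} must be an integer, got {value!r}")
    if f < 0:
        raise ValidationError(f"row {row}: {column} must be >= 0, got {value!r}")
    return int(f)


def read_plate_table(path) -> list[PlateAssay]:
    """Read a plate-count table; one PlateAssay per data row, order preserved.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, PLATE_COLUMNS, path)
    has_elsewhere = "n_elsewhere" in df.columns
    if not has_elsewhere and "n_total" not in df.columns:
        raise SchemaError(
            f"{path}: missing required column(s) n_elsewhere "
            "(or n_total to derive it)"
        )
    plates: list[PlateAssay] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        row = i
        n_urine = _int_count(rec["n_urine"], "n_urine", row)
        n_control = _int_count(rec["n_control"], "n_control", row)
        if has_elsewhere and not _is_missing(rec.get("n_elsewhere")):
            n_elsewhere = _int_count(rec["n_elsewhere"], "n_elsewhere", row)
        else:
            n_total = _int_count(rec["n_total"], "n_total", row)
            n_elsewhere = n_total - n_urine - n_control
            if n_elsewhere < 0:
                raise ValidationError(
                    f"row {row}: n_total {n_total} smaller than "
                    f"n_urine + n_control = {n_urine + n_control}"
                )
        dilution = 100.0
        if "dilution" in df.columns and not _is_missing(rec.get("dilution")):
            dilution = float(rec["dilution"])
        try:
            plates.append(
                PlateAssay(
                    patient_id=str(rec["patient_id"]),
                    timepoint=Timepoint.parse(rec["timepoint"]),
                    plate_id=str(rec["plate_id"]),
                    n_urine=n_urine,
                    n_control=n_control,
                    n_elsewhere=n_elsewhere,
                    dilution=dilution,
                )
            )
        except ValidationError as e:
            raise ValidationError(f"row {row}: {e}") from None
    if not plates:
        logger.warning("%s: no data rows", path)
    return plates


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or v == ""


def write_plate_table(plates: Sequence[PlateAssay], path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in plates],
            "timepoint": [p.timepoint.value for p in plates],
            "plate_id": [p.plate_id for p in plates],
            "n_urine": [p.n_urine for p in plates],
            "n_control": [p.n_control for p in plates],
            "n_elsewhere": [p.n_elsewhere for p in plates],
            "dilution": [p.dilution for p in plates],
        }
    )
    df.to_csv(path, index=False)


def read_cohort_table(path) -> list[PatientRecord]:
    """Read a cohort table; duplicate patient ids are rejected."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, COHORT_COLUMNS, path)
    records: list[PatientRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(df.to_dict("records"), start=1):
        pid = str(rec["patient_id"])
        if pid in seen:
            raise ValidationError(f"row {i}: duplicate patient_id {pid!r}")
        seen.add(pid)
        reason = rec.get("excluded_reason")
        try:
            records.append(
                PatientRecord(
                    patient_id=pid,
                    age=_int_count(rec["age"], "age", i),
                    sex=str(rec["sex"]).strip().upper(),
                    c_t=str(rec["cT"]),
                    c_n=str(rec["cN"]),
                    c_m=str(rec["cM"]),
                    stage=Stage.parse(rec["stage"]),
                    response=Response.parse(rec["response"]),
                    excluded_reason=None if _is_missing(reason) else str(reason),
                )
            )
        except ValidationError as e:
            raise ValidationError(f"row {i}: {e}") from None
    if not records:
        logger.warning("%s: no data rows", path)
    return records


def write_cohort_table(patients: Sequence[PatientRecord], path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "age": [p.age for p in patients],
            "sex": [p.sex for p in patients],
            "cT": [p.c_t for p in patients],
            "cN": [p.c_n for p in patients],
            "cM": [p.c_m for p in patients],
            "stage": [p.stage.value for p in patients],
            "response": [p.response.value for p in patients],
            "excluded_reason": [p.excluded_reason or "" for p in patients],
        }
    )
    df.to_csv(path, index=False)


def write_sample_table(samples: Sequence[SampleCI], path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in samples],
            "timepoint": [s.timepoint.value for s in samples],
            "ci": [s.ci for s in samples],
            "n_plates": [s.n_plates for s in samples],
        }
    )
    df.to_csv(path, index=False)


def read_sample_table(path) -> list[SampleCI]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("patient_id", "timepoint", "ci", "n_plates"), path)
    return [
        SampleCI(
            patient_id=str(r["patient_id"]),
            timepoint=Timepoint.parse(r["timepoint"]),
            ci=float(r["ci"]),
            n_plates=int(r["n_plates"]),
        )
        for r in df.to_dict("records")
    ]


# ---------------------------------------------------------------------------
# report serialization


def _report_to_jsonable(report: StudyReport) -> dict:
    def roc_to_dict(r: RocResult) -> dict:
        d = dataclasses.asdict(r)
        d["roc_points"] = [
            {"threshold": p.threshold, "sensitivity": p.sensitivity,
             "specificity": p.specificity}
            for p in r.roc_points
        ]
        return d

    return {
        "cohort_summary": report.cohort_summary,
        "group_comparison": [dataclasses.asdict(g) for g in report.group_comparison],
        "cr_group_summary": report.cr_group_summary,
        "roc_table": {k: roc_to_dict(v) for k, v in report.roc_table.items()},
        "metadata": report.metadata,
    }


def _report_from_jsonable(d: dict) -> StudyReport:
    def roc_from_dict(r: dict) -> RocResult:
        pts = tuple(
            RocPoint(
                threshold=p["threshold"],
                sensitivity=p["sensitivity"],
                specificity=p["specificity"],
            )
            for p in r["roc_points"]
        )
        return RocResult(**{**r, "roc_points": pts})

    return StudyReport(
        cohort_summary=d["cohort_summary"],
        group_comparison=tuple(
            GroupComparison(**{**g, "iqr_a": tuple(g["iqr_a"]),
                               "iqr_b": tuple(g["iqr_b"])})
            for g in d["group_comparison"]
        ),
        cr_group_summary=d["cr_group_summary"],
        roc_table={k: roc_from_dict(v) for k, v in d["roc_table"].items()},
        metadata=d.get("metadata", {}),
    )


def write_report(report: StudyReport, path, format: str = "json") -> None:
    """Serialize a report; json round-trips every numeric field bit-for-bit.

    The tsv form emits one row per (score, endpoint) pair of the ROC table
    (ROC point lists are summarized by their length).
    """
    path = Path(path)
    if format == "json":
        payload = _encode_inf(_report_to_jsonable(report))
        # Infinity is not valid JSON; the sentinel ROC threshold is encoded
        # as the string "Infinity" and decoded transparently on read.
        text = json.dumps(payload, indent=2, allow_nan=False)
        path.write_text(text, encoding="utf-8")
    elif format == "tsv":
        rows = []
        for key, r in report.roc_table.items():
            score, _, endpoint = key.partition("/")
            rows.append(
                {
                    "score": score,
                    "endpoint": endpoint,
                    "auc": r.auc,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "sensitivity": r.sensitivity_at_cutoff,
                    "specificity": r.specificity_at_cutoff,
                    "cutoff": r.cutoff,
                    "n_pos": r.n_pos,
                    "n_neg": r.n_neg,
                    "n_roc_points": len(r.roc_points),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValidationError(f"unknown report format {format!r}; use json or tsv")


def _encode_inf(obj):
    if isinstance(obj, dict):
        return {k: _encode_inf(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode_inf(v) for v in obj]
    if isinstance(obj, float) and math.isinf(obj):
        return "Infinity" if obj > 0 else "-Infinity"
    return obj


def read_report(path) -> StudyReport:
    """Read back a json report written by :func:`write_report`."""
    raw = Path(path).read_text(encoding="utf-8")
    d = json.loads(raw)
    d = _decode_inf(d)
    return _report_from_jsonable(d)


def _decode_inf(obj):
    if isinstance(obj, dict):
        return {k: _decode_inf(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode_inf(v) for v in obj]
    if obj == "Infinity":
        return math.inf
    if obj == "-Infinity":
        return -math.inf
    return obj
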