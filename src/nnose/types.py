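"""Shared domain types for the chemotaxis treatment-response analysis.

The analysis pipeline moves through four representations: raw plate counts
(:class:`PlateAssay`), an aggregated chemotaxis index per urine sample
(:class:`SampleCI`), per-patient index reduction scores (:class:`IRSRecord`),
and the final study-level report (:class:`StudyReport`).  Patient metadata
travels alongside as :class:`PatientRecord`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class ValidationError(ValueError):
    """Raised when an input value or file row violates a documented contract."""


class SchemaError(ValidationError):
    """Raised when a table is missing a required column."""


class Timepoint(str, Enum):
    """Urine-collection timepoint of the three-sample therapy schedule.

    T1 is collected within a week before chemotherapy starts, T2 just before
    surgery (after chemotherapy), and T3 three to five weeks after surgery.
    """

    T1_PRE_TREATMENT = "T1"
    T2_PRE_SURGERY = "T2"
    T3_POST_SURGERY = "T3"

    @property
    def order(self) -> int:
        return {"T1": 1, "T2": 2, "T3": 3}[self.value]

    @classmethod
    def parse(cls, label: str) -> "Timepoint":
        """Map a file label onto the closed timepoint vocabulary.

        Accepted labels (case-insensitive): ``T1``/``pre_treatment``,
        ``T2``/``pre_surgery``, ``T3``/``post_surgery``, and the long
        enum names.
        """
        aliases = {
            "t1": cls.T1_PRE_TREATMENT,
            "pre_treatment": cls.T1_PRE_TREATMENT,
            "t1_pre_treatment": cls.T1_PRE_TREATMENT,
            "t2": cls.T2_PRE_SURGERY,
            "pre_surgery": cls.T2_PRE_SURGERY,
            "t2_pre_surgery": cls.T2_PRE_SURGERY,
            "t3": cls.T3_POST_SURGERY,
            "post_surgery": cls.T3_POST_SURGERY,
            "t3_post_surgery": cls.T3_POST_SURGERY,
        }
        key = str(label).strip().lower()
        if key not in aliases:
            raise ValidationError(
                f"unknown timepoint label {label!r}; expected one of "
                "T1/T2/T3 or pre_treatment/pre_surgery/post_surgery"
            )
        return aliases[key]


class Response(str, Enum):
    """RECIST v1.1 response category (an input label, never computed here)."""

    CR = "CR"  # complete response
    PR = "PR"  # partial response
    SD = "SD"  # stable disease
    PD = "PD"  # progressive disease

    @classmethod
    def parse(cls, label: str) -> "Response":
        key = str(label).strip().upper()
        try:
            return cls(key)
        except ValueError:
            raise ValidationError(
                f"unknown response label {label!r}; expected CR, PR, SD or PD"
            ) from None


class Stage(str, Enum):
    """Clinical stage of the analyzed esophageal-cancer cohort."""

    II = "II"
    III = "III"
    IVA = "IVa"
    IVB = "IVb"

    @classmethod
    def parse(cls, label: str) -> "Stage":
        key = str(label).strip()
        for member in cls:
            if member.value.lower() == key.lower():
                return member
        raise ValidationError(
            f"unknown stage label {label!r}; expected II, III, IVa or IVb"
        )


@dataclass(frozen=True)
class PlateAssay:
    """Worm counts from one chemotaxis plate.

    ``n_urine`` counts worms in the scoring region around the urine spots,
    ``n_control`` the opposite (azide-only) region, ``n_elsewhere`` the rest
    of the plate.  ``dilution`` is the fold-dilution of the urine sample
    (the assay uses 100-fold).
    """

    patient_id: str
    timepoint: Timepoint
    plate_id: str
    n_urine: int
    n_control: int
    n_elsewhere: int
    dilution: float = 100.0

    def __post_init__(self) -> None:
        for name in ("n_urine", "n_control", "n_elsewhere"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                if isinstance(v, float) and v.is_integer():
                    object.__setattr__(self, name, int(v))
                    v = int(v)
                else:
                    raise ValidationError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if not (self.dilution > 0):
            raise ValidationError(f"dilution must be positive, got {self.dilution}")

    @property
    def n_total(self) -> int:
        return self.n_urine + self.n_control + self.n_elsewhere


@dataclass(frozen=True)
class SampleCI:
    """Aggregated chemotaxis index for one patient at one timepoint."""

    patient_id: str
    timepoint: Timepoint
    ci: float
    n_plates: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.ci <= 1.0:
            raise ValidationError(
                f"chemotaxis index must lie in [-1, 1], got {self.ci}"
            )
        if self.n_plates < 1:
            raise ValidationError(f"n_plates must be >= 1, got {self.n_plates}")


_IRS_ADDITIVITY_TOL = 1e-12


@dataclass(frozen=True)
class IRSRecord:
    """Index reduction scores for one patient.

    irs1 = CI(T1) − CI(T2); irs2 = CI(T2) − CI(T3); irs3 = CI(T1) − CI(T3).
    A positive score means the chemotaxis index fell over the interval
    (reduction of the cancer-associated attraction signal).
    """

    patient_id: str
    irs1: float
    irs2: float
    irs3: float

    def __post_init__(self) -> None:
        for name in ("irs1", "irs2", "irs3"):
            v = getattr(self, name)
            if not -2.0 <= v <= 2.0:
                raise ValidationError(f"{name} must lie in [-2, 2], got {v}")
        if abs((self.irs1 + self.irs2) - self.irs3) > _IRS_ADDITIVITY_TOL:
            raise ValidationError(
                "irs3 must equal irs1 + irs2 "
                f"(got {self.irs3} vs {self.irs1 + self.irs2})"
            )


@dataclass(frozen=True)
class PatientRecord:
    """One analyzed patient: demographics, clinical TNM stage and RECIST label."""

    patient_id: str
    age: int
    sex: str  # 'M' or 'F'
    c_t: str
    c_n: str
    c_m: str
    stage: Stage
    response: Response
    excluded_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not isinstance(self.response, Response):
            object.__setattr__(self, "response", Response.parse(self.response))
        if not isinstance(self.stage, Stage):
            object.__setattr__(self, "stage", Stage.parse(self.stage))

    @property
    def analyzed(self) -> bool:
        return self.excluded_reason is None


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC analysis of one score against one binary endpoint."""

    auc: float
    ci_low: float
    ci_high: float
    roc_points: tuple  # tuple[RocPoint, ...]
    cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.ci_high <= 1.0):
            raise ValidationError(
                f"CI bounds must satisfy 0 <= low <= high <= 1, got "
                f"[{self.ci_low}, {self.ci_high}]"
            )
        if not (self.ci_low <= self.auc <= self.ci_high):
            # AUC always lies inside its own Wald/percentile interval
            raise ValidationError(
                f"auc {self.auc} outside interval [{self.ci_low}, {self.ci_high}]"
            )


@dataclass(frozen=True)
class GroupComparison:
    """Median [IQR] of one score in two groups with a rank-sum p-value."""

    score_name: str
    label_a: str
    median_a: float
    iqr_a: tuple  # (q1, q3)
    n_a: int
    label_b: str
    median_b: float
    iqr_b: tuple
    n_b: int
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value must lie in [0, 1], got {self.p_value}")


@dataclass(frozen=True)
class CohortFlow:
    """CONSORT-style accounting: enrolled minus exclusions equals analyzed."""

    n_enrolled: int
    exclusions: tuple  # tuple[(reason, count), ...]
    n_analyzed: int

    def __post_init__(self) -> None:
        excluded = sum(c for _, c in self.exclusions)
        if self.n_analyzed != self.n_enrolled - excluded:
            raise ValidationError(
                f"n_analyzed ({self.n_analyzed}) != n_enrolled ({self.n_enrolled}) "
                f"- excluded ({excluded})"
            )


@dataclass(frozen=True)
class StudyReport:
    """Full analysis output: cohort summary, group comparisons, ROC table."""

    cohort_summary: dict  # class -> count, plus n_analyzed / n_responders / response_rate_pct
    group_comparison: tuple  # tuple[GroupComparison, ...] responders vs non-responders
    cr_group_summary: dict  # score -> {median, q1, q3, n} for the CR-only group
    roc_table: dict  # "SCORE/ENDPOINT" -> RocResult
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = [
            self.cohort_summary.get(r.value, 0) for r in Response
        ]
        if sum(counts) != self.cohort_summary.get("n_analyzed", sum(counts)):
            raise ValidationError(
                "cohort_summary class counts must sum to n_analyzed"
            )


def _check_finite(name: str, value: float) -> float:
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value}")
    return float(value)
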