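"""End-to-end treatment-response analysis.

Reproduces the shape of the reference study: CONSORT-style cohort flow,
a cohort summary with response rate, per-score median [IQR] comparisons of
responders (CR or PR) vs non-responders (SD or PD) with Wilcoxon rank-sum
p-values, and per-score × per-endpoint ROC tables with DeLong or bootstrap
confidence intervals and Youden cutoffs.  The two endpoints are complete
response only (CR_only) and objective response (CR_or_PR).
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np

from . import stats
from .chemotaxis import ci_table
from .irs import SCORE_NAMES, irs_table
from .types import (
    CohortFlow,
    GroupComparison,
    IRSRecord,
    PatientRecord,
    PlateAssay,
    Response,
    RocResult,
    SampleCI,
    StudyReport,
    ValidationError,
)

logger = logging.getLogger(__name__)

ENDPOINTS = ("CR_only", "CR_or_PR")


def classify_response(record: PatientRecord | Response, endpoint: str) -> bool:
    """Binary endpoint label: is this patient a treatment responder?

    ``CR_or_PR`` counts complete and partial responses as positive;
    ``CR_only`` counts only complete responses.
    """
    response = record.response if isinstance(record, PatientRecord) else record
    if endpoint == "CR_or_PR":
        return response in (Response.CR, Response.PR)
    if endpoint == "CR_only":
        return response is Response.CR
    raise ValidationError(f"unknown endpoint {endpoint!r}; use CR_only or CR_or_PR")


def cohort_flow(patients: Sequence[PatientRecord]) -> CohortFlow:
    """CONSORT-style accounting from per-patient exclusion reasons.

    Patients with a non-empty ``excluded_reason`` are counted per reason;
    the rest form the analyzed set.
    """
    reasons: dict[str, int] = {}
    n_analyzed = 0
    for p in patients:
        if p.excluded_reason:
            reasons[p.excluded_reason] = reasons.get(p.excluded_reason, 0) + 1
            logger.info("patient %s excluded: %s", p.patient_id, p.excluded_reason)
        else:
            n_analyzed += 1
    return CohortFlow(
        n_enrolled=len(patients),
        exclusions=tuple(sorted(reasons.items())),
        n_analyzed=n_analyzed,
    )


def analyzed_patients(patients: Sequence[PatientRecord]) -> list[PatientRecord]:
    return [p for p in patients if p.analyzed]


def _score_value(record: IRSRecord, score: str) -> float:
    return {"IRS1": record.irs1, "IRS2": record.irs2, "IRS3": record.irs3}[score]


def _roc_result(
    scores: np.ndarray,
    labels: np.ndarray,
    ci_method: str,
    seed: Optional[int],
) -> RocResult:
    pos = scores[labels]
    neg = scores[~labels]
    auc = stats.mann_whitney_auc(pos, neg)
    points = stats.roc_points(scores, labels)
    cutoff, sens, spec = stats.youden_cutoff(points)
    low, high = stats.auc_confidence_interval(
        pos, neg, method=ci_method, seed=seed
    )
    # Wald intervals can fall beside a boundary AUC; the reported interval
    # always contains the point estimate.
    low, high = min(low, auc), max(high, auc)
    return RocResult(
        auc=auc,
        ci_low=low,
        ci_high=high,
        roc_points=tuple(points),
        cutoff=cutoff,
        sensitivity_at_cutoff=sens,
        specificity_at_cutoff=spec,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def run_analysis(
    cohort: Sequence[PatientRecord],
    plates: Optional[Iterable[PlateAssay]] = None,
    samples: Optional[Iterable[SampleCI]] = None,
    endpoints: Sequence[str] = ENDPOINTS,
    ci_method: str = "delong",
    seed: Optional[int] = None,
) -> StudyReport:
    """Full analysis from plate counts (or pre-aggregated sample indices).

    Excluded patients are dropped via :func:`cohort_flow`; chemotaxis
    indices are aggregated per patient × timepoint, IRS scores derived for
    patients with all three timepoints, and each score is compared between
    responders and non-responders and evaluated against each requested
    endpoint by ROC analysis.  An endpoint with a single observed class is
    omitted from the ROC table with a logged warning.  Deterministic given
    inputs, ``ci_method`` and ``seed`` (the seed matters only for
    bootstrap intervals).
    """
    if (plates is None) == (samples is None):
        raise ValidationError("provide exactly one of plates or samples")
    flow = cohort_flow(cohort)
    analyzed = analyzed_patients(cohort)
    if not analyzed:
        raise ValidationError("no analyzed patients remain after exclusions")
    if samples is None:
        samples = ci_table(plates)
    irs_records = irs_table(samples, cohort=analyzed)
    if len(irs_records) < 4:
        raise ValidationError(
            f"only {len(irs_records)} patient(s) with complete timepoints; "
            "need at least 4 for a two-group comparison"
        )
    response_of = {p.patient_id: p.response for p in analyzed}

    class_counts = {r.value: 0 for r in Response}
    for p in analyzed:
        class_counts[p.response.value] += 1
    n_responders = sum(
        1 for p in analyzed if classify_response(p, "CR_or_PR")
    )
    cohort_summary = {
        **class_counts,
        "n_enrolled": flow.n_enrolled,
        "n_analyzed": len(analyzed),
        "n_responders": n_responders,
        "response_rate_pct": round(100.0 * n_responders / len(analyzed), 1),
    }

    comparisons = []
    cr_summary: dict[str, dict] = {}
    roc_table: dict[str, RocResult] = {}
    resp_mask = np.array(
        [classify_response(response_of[r.patient_id], "CR_or_PR")
         for r in irs_records]
    )
    cr_values_present = any(
        response_of[r.patient_id] is Response.CR for r in irs_records
    )
    for score in SCORE_NAMES:
        values = np.array([_score_value(r, score) for r in irs_records])
        grp_a, grp_b = values[resp_mask], values[~resp_mask]
        if grp_a.size >= 2 and grp_b.size >= 2:
            _, p_value = stats.wilcoxon_rank_sum(grp_a, grp_b, mode="auto")
            med_a, q1_a, q3_a = stats.median_iqr(grp_a)
            med_b, q1_b, q3_b = stats.median_iqr(grp_b)
            comparisons.append(
                GroupComparison(
                    score_name=score,
                    label_a="CR_or_PR", median_a=med_a, iqr_a=(q1_a, q3_a),
                    n_a=int(grp_a.size),
                    label_b="SD_or_PD", median_b=med_b, iqr_b=(q1_b, q3_b),
                    n_b=int(grp_b.size),
                    p_value=p_value,
                )
            )
        else:
            logger.warning(
                "%s: fewer than two patients in a response group; "
                "group comparison omitted", score,
            )
        if cr_values_present:
            cr_vals = values[
                [response_of[r.patient_id] is Response.CR for r in irs_records]
            ]
            med, q1, q3 = stats.median_iqr(cr_vals)
            cr_summary[score] = {
                "median": med, "q1": q1, "q3": q3, "n": int(cr_vals.size)
            }
        for endpoint in endpoints:
            labels = np.array(
                [classify_response(response_of[r.patient_id], endpoint)
                 for r in irs_records]
            )
            if labels.all() or not labels.any():
                logger.warning(
                    "endpoint %s has a single class among analyzed patients; "
                    "ROC for %s omitted", endpoint, score,
                )
                continue
            roc_table[f"{score}/{endpoint}"] = _roc_result(
                values, labels, ci_method, seed
            )

    return StudyReport(
        cohort_summary=cohort_summary,
        group_comparison=tuple(comparisons),
        cr_group_summary=cr_summary,
        roc_table=roc_table,
        metadata={
            "ci_method": ci_method,
            "seed": seed,
            "endpoints": list(endpoints),
            "n_irs_patients": len(irs_records),
            "exclusions": [list(e) for e in flow.exclusions],
        },
    )
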