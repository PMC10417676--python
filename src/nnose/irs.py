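"""Index reduction scores (IRS) from per-timepoint chemotaxis indices.

IRS1 = CI(pre-treatment) − CI(pre-surgery)
IRS2 = CI(pre-surgery)  − CI(post-surgery)
IRS3 = CI(pre-treatment) − CI(post-surgery)

Differences are taken earlier-minus-later, so a decline of the
cancer-associated attraction signal over therapy yields positive scores;
by construction IRS3 = IRS1 + IRS2 exactly.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

from .types import IRSRecord, PatientRecord, SampleCI, Timepoint, ValidationError

logger = logging.getLogger(__name__)

SCORE_NAMES = ("IRS1", "IRS2", "IRS3")


def compute_irs(
    ci_t1: float, ci_t2: float, ci_t3: float, patient_id: str = ""
) -> IRSRecord:
    """Derive the three index reduction scores from three timepoint indices."""
    for name, v in (("ci_t1", ci_t1), ("ci_t2", ci_t2), ("ci_t3", ci_t3)):
        if not -1.0 <= v <= 1.0:
            raise ValidationError(f"{name} must lie in [-1, 1], got {v}")
    return IRSRecord(
        patient_id=patient_id,
        irs1=ci_t1 - ci_t2,
        irs2=ci_t2 - ci_t3,
        irs3=ci_t1 - ci_t3,
    )


def irs_table(
    samples: Iterable[SampleCI],
    cohort: Optional[Sequence[PatientRecord]] = None,
) -> list[IRSRecord]:
    """One IRSRecord per patient with all three timepoints.

    Patients missing any timepoint are excluded with a logged warning naming
    the missing timepoint(s); missingness is never an error.  When a cohort
    is given, samples from patients outside it are ignored.
    """
    by_patient: dict[str, dict[Timepoint, float]] = {}
    for s in samples:
        by_patient.setdefault(s.patient_id, {})[s.timepoint] = s.ci

    if cohort is not None:
        ids = [p.patient_id for p in cohort]
        extra = set(by_patient) - set(ids)
        if extra:
            logger.warning(
                "ignoring samples from %d patient(s) not in the cohort table: %s",
                len(extra), sorted(extra),
            )
    else:
        ids = sorted(by_patient)

    out: list[IRSRecord] = []
    for pid in ids:
        cis = by_patient.get(pid, {})
        missing = [t.value for t in Timepoint if t not in cis]
        if missing:
            logger.warning(
                "patient %s excluded from IRS table: missing timepoint(s) %s",
                pid, ", ".join(missing),
            )
            continue
        out.append(
            compute_irs(
                cis[Timepoint.T1_PRE_TREATMENT],
                cis[Timepoint.T2_PRE_SURGERY],
                cis[Timepoint.T3_POST_SURGERY],
                patient_id=pid,
            )
        )
    return out
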