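"""Chemotaxis index computation and replicate aggregation.

The chemotaxis index (CI) of a plate is

    CI = (n_urine − n_control) / (n_urine + n_control + n_elsewhere)

so CI ∈ [−1, 1]; positive values indicate attraction toward the urine
spots, negative values repulsion.  Replicate plates for the same patient
and timepoint are combined by an unweighted mean of their per-plate
indices (plates are seeded with roughly equal worm numbers by design).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

from .types import PlateAssay, SampleCI, Timepoint, ValidationError


def chemotaxis_index(assay: PlateAssay) -> float:
    """Return the chemotaxis index of one plate.

    Raises :class:`ValidationError` for an empty plate (all counts zero).
    """
    total = assay.n_total
    if total < 1:
        raise ValidationError(
            f"empty plate {assay.plate_id!r}: all worm counts are zero"
        )
    return (assay.n_urine - assay.n_control) / total


def aggregate_ci(assays: Sequence[PlateAssay]) -> SampleCI:
    """Aggregate replicate plates of one patient × timepoint into a SampleCI.

    The sample index is the unweighted mean of per-plate indices.  All
    plates must share the same patient and timepoint.
    """
    assays = list(assays)
    if not assays:
        raise ValidationError("aggregate_ci requires at least one plate")
    pid = assays[0].patient_id
    tp = assays[0].timepoint
    for a in assays:
        if a.patient_id != pid or a.timepoint != tp:
            raise ValidationError(
                "aggregate_ci received plates from mixed patients/timepoints: "
                f"({pid!r}, {tp.value}) vs ({a.patient_id!r}, {a.timepoint.value})"
            )
    cis = [chemotaxis_index(a) for a in assays]
    return SampleCI(
        patient_id=pid,
        timepoint=tp,
        ci=sum(cis) / len(cis),
        n_plates=len(cis),
    )


def ci_table(plates: Iterable[PlateAssay]) -> list[SampleCI]:
    """Group a plate table by (patient, timepoint) and aggregate each group.

    Output is sorted by patient id then timepoint order, one SampleCI per
    patient × timepoint present in the input.
    """
    groups: dict[tuple[str, Timepoint], list[PlateAssay]] = defaultdict(list)
    for p in plates:
        groups[(p.patient_id, p.timepoint)].append(p)
    out = [aggregate_ci(v) for v in groups.values()]
    out.sort(key=lambda s: (s.patient_id, s.timepoint.order))
    return out
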