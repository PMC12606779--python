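"""Eligibility and run-quality gating.

Every rule the assay protocol states is implemented as a pure function
returning :class:`~fragscore.datatypes.QcVerdict`.  Timing windows are
inclusive at both endpoints; the transit bound fails only strictly above
120 h ("more than 120 h").  Thresholds without a protocol-stated value
(IPC shift, SVA concordance) default to conventional qPCR acceptance
values and are configurable.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .datatypes import CohortRecord, QcVerdict, QpcrWell, SampleDraw, Target

#: Rules whose failure excludes a patient from analysis.
HARD_RULES = (
    "transit_time",
    "draw_window",
    "scan_window",
    "ipc_shift",
    "sva_concordance",
    "clinical_exclusion",
    "unquantifiable",
)


def check_transit_time(draw: SampleDraw, max_hours: float = 120.0) -> QcVerdict:
    """Fail a draw whose lab receipt came more than ``max_hours`` after
    collection.  The boundary itself (exactly 120 h) passes.

    Delayed processing lets white blood cells lyse in the tube, inflating
    cfDNA of every size class; the gate removes draws where that risk is
    unbounded.
    """
    subject = f"{draw.patient_id}/draw{draw.draw_index}"
    if draw.collected_at is None or draw.received_at is None:
        return QcVerdict(
            subject, "transit_time", passed=False, detail="missing timestamp",
            indeterminate=True,
        )
    hours = draw.transit_hours
    ok = hours <= max_hours
    return QcVerdict(
        subject, "transit_time", passed=ok,
        detail=f"transit {hours:.1f} h (limit {max_hours:g} h)",
    )


def check_draw_window(
    record: CohortRecord, min_days: float = 12.0, max_days: float = 21.0
) -> QcVerdict:
    """Second draw must fall 12-21 days (inclusive) after first treatment."""
    d2 = record.draws[1]
    days = (d2.collected_at - record.treatment_date).total_seconds() / 86400.0
    if days < 0:
        return QcVerdict(
            record.patient_id, "draw_window", passed=False,
            detail="pre-treatment draw",
        )
    ok = min_days <= days <= max_days
    return QcVerdict(
        record.patient_id, "draw_window", passed=ok,
        detail=f"draw 2 at {days:.1f} d post-treatment (window {min_days:g}-{max_days:g} d)",
    )


def check_scan_window(
    record: CohortRecord, min_weeks: float = 9.0, max_weeks: float = 12.0
) -> QcVerdict:
    """Assessment scan must fall 9-12 weeks (inclusive) after the first draw."""
    if record.assessment_scan_date is None:
        return QcVerdict(
            record.patient_id, "scan_window", passed=False,
            detail="missing assessment scan", indeterminate=True,
        )
    d1 = record.draws[0]
    weeks = (
        record.assessment_scan_date - d1.collected_at
    ).total_seconds() / (7 * 86400.0)
    ok = min_weeks <= weeks <= max_weeks
    return QcVerdict(
        record.patient_id, "scan_window", passed=ok,
        detail=f"scan at {weeks:.1f} wk post-draw-1 (window {min_weeks:g}-{max_weeks:g} wk)",
    )


def check_ipc_shift(
    wells: Iterable[QpcrWell], run_id: str, max_shift_ct: float = 1.0
) -> List[QcVerdict]:
    """Flag PCR inhibition from internal-positive-control Ct shifts.

    The IPC is a spiked synthetic template at fixed copy number, so within
    a run every sample should report the same IPC Ct.  A sample whose mean
    IPC Ct sits more than ``max_shift_ct`` above or below the run median is
    flagged as inhibited; a sample with no IPC amplification at all is
    total inhibition and fails outright.
    """
    ipc_cts: Dict[str, List[Optional[float]]] = defaultdict(list)
    for w in wells:
        if w.target is Target.IPC172:
            ipc_cts[w.sample_id].append(w.ct)
    if not ipc_cts:
        raise ValueError(f"run {run_id}: no IPC wells present")

    sample_means: Dict[str, Optional[float]] = {}
    for sid, cts in ipc_cts.items():
        present = [c for c in cts if c is not None]
        sample_means[sid] = sum(present) / len(present) if present else None

    amplified = [m for m in sample_means.values() if m is not None]
    if len(amplified) < 2:
        raise ValueError(
            f"run {run_id}: need IPC Ct from >= 2 samples to assess shift"
        )
    run_median = _median(amplified)

    verdicts = []
    for sid in sorted(sample_means):
        mean_ct = sample_means[sid]
        if mean_ct is None:
            verdicts.append(
                QcVerdict(sid, "ipc_shift", passed=False, detail="total inhibition")
            )
            continue
        shift = mean_ct - run_median
        ok = abs(shift) <= max_shift_ct
        verdicts.append(
            QcVerdict(
                sid, "ipc_shift", passed=ok,
                detail=f"IPC shift {shift:+.2f} Ct vs run median {run_median:.2f}",
            )
        )
    return verdicts


def _median(values: Sequence[float]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else 0.5 * (s[mid - 1] + s[mid])


def check_sva_concordance(
    q_mpx1: float, q_mpx2: float, max_rel_diff: float = 0.30
) -> QcVerdict:
    """Cross-multiplex concordance of the shared 265 bp SVA quantity.

    Both multiplexes quantify the same SVA target from the same extract, so
    a large relative difference (|q1-q2| over their mean; symmetric in
    ordering) flags experimental error such as a pipetting fault.
    """
    if q_mpx1 is None or q_mpx2 is None or q_mpx1 <= 0 or q_mpx2 <= 0:
        return QcVerdict(
            "", "sva_concordance", passed=False,
            detail="missing or non-positive SVA quantity", indeterminate=True,
        )
    rel = abs(q_mpx1 - q_mpx2) / ((q_mpx1 + q_mpx2) / 2.0)
    ok = rel <= max_rel_diff
    return QcVerdict(
        "", "sva_concordance", passed=ok,
        detail=f"SVA relative difference {rel:.3f} (limit {max_rel_diff:g})",
    )


def check_clinical_exclusions(record: CohortRecord) -> QcVerdict:
    """Enrollment exclusions carried as manifest booleans.

    Secondary malignancy, active autoimmune treatment, or recent
    DVT/PE/sepsis disqualify a patient; the assay cannot diagnose these, so
    they arrive as flags.
    """
    reasons = []
    if record.secondary_malignancy:
        reasons.append("secondary malignancy")
    if record.autoimmune_treatment:
        reasons.append("autoimmune treatment")
    if record.recent_dvt_pe_sepsis:
        reasons.append("DVT/PE/sepsis within 12 days")
    return QcVerdict(
        record.patient_id, "clinical_exclusion",
        passed=not reasons, detail="; ".join(reasons),
    )


def gate_record(record: CohortRecord, max_transit_hours: float = 120.0) -> List[QcVerdict]:
    """All record-level verdicts for one patient (transit x2, windows, clinical)."""
    out = [check_transit_time(d, max_transit_hours) for d in record.draws]
    out.append(check_draw_window(record))
    out.append(check_scan_window(record))
    out.append(check_clinical_exclusions(record))
    return out


def apply_exclusions(
    cohort: Sequence[CohortRecord], verdicts: Iterable[QcVerdict]
) -> Tuple[List[CohortRecord], List[dict]]:
    """Partition the cohort into analyzable patients and an exclusion table.

    A patient is excluded iff any hard rule failed for them (verdict
    subjects may be ``patient_id`` or ``patient_id/draw``).  Every failure
    is listed; the partition is exact and disjoint.
    """
    failures: Dict[str, List[QcVerdict]] = defaultdict(list)
    for v in verdicts:
        if not v.passed and v.rule in HARD_RULES:
            pid = v.subject.split("/")[0]
            failures[pid].append(v)

    analyzable, table = [], []
    for rec in cohort:
        if rec.patient_id in failures:
            for v in failures[rec.patient_id]:
                table.append(
                    {"patient_id": rec.patient_id, "rule": v.rule, "detail": v.detail}
                )
        else:
            analyzable.append(rec)
    assert len(analyzable) + len({r["patient_id"] for r in table}) == len(cohort)
    return analyzable, table
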