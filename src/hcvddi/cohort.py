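"""New-user cohort selection: index events, inclusion, exclusion, attrition.

The index date is a patient's first DAA prescription inside the
identification period.  Inclusion requires adult age at index, an HCV
diagnosis (B18.2) recorded in the index month, and continuous enrollment
from the start of the third calendar month before the index month through
the index date.  Exclusion removes same-day multi-regimen initiators and
patients with a liver-transplant procedure at index or in the 90 days
before.  Rules are applied in that order and every removal is accounted in
an attrition report (the patient-selection flow).
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .claims import ClaimsBundle
from .config import (
    StudyConfig,
    age_at,
    month_first_day,
    month_of,
    months_before,
)

#: attrition step labels, in application order
ATTRITION_STEPS = ["age", "hcv_diagnosis", "lookback", "multiple_daa", "transplant"]

COHORT_COLUMNS = ["patient_id", "group", "index_date", "age_at_index", "sex", "facility_id"]


@dataclass(frozen=True)
class IndexEvent:
    patient_id: str
    index_date: dt.date
    regimens_on_index: frozenset[str]


@dataclass
class CohortResult:
    cohort: pd.DataFrame          # COHORT_COLUMNS, one row per included patient
    attrition: pd.DataFrame       # step, n_remaining, n_removed
    removed: pd.DataFrame         # patient_id, reason (first failed rule)


def find_index_events(bundle: ClaimsBundle, config: StudyConfig) -> dict[str, IndexEvent]:
    """Earliest DAA prescription per patient inside the identification period.

    ``regimens_on_index`` collects every distinct DAA regimen prescribed on
    that earliest date.  Independent of input row order.
    """
    daa_codes = config.daa_atc_codes
    best: dict[str, tuple[dt.date, set[str]]] = {}
    for row in bundle.prescriptions.itertuples(index=False):
        if row.atc_code not in daa_codes:
            continue
        date = row.prescription_date
        if not (config.identification_start <= date <= config.identification_end):
            continue
        regimen = config.regimen_of_atc(row.atc_code)
        cur = best.get(row.patient_id)
        if cur is None or date < cur[0]:
            best[row.patient_id] = (date, {regimen})
        elif date == cur[0]:
            cur[1].add(regimen)
    return {
        pid: IndexEvent(pid, date, frozenset(regimens))
        for pid, (date, regimens) in best.items()
    }


def merge_enrollment(spans: list[tuple[dt.date, dt.date]]) -> list[tuple[dt.date, dt.date]]:
    """Merge sorted enrollment intervals, treating adjacent days as continuous."""
    merged: list[tuple[dt.date, dt.date]] = []
    for start, end in sorted(spans):
        if merged and start <= merged[-1][1] + dt.timedelta(days=1):
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _covering_span(
    merged: list[tuple[dt.date, dt.date]], day: dt.date
) -> Optional[tuple[dt.date, dt.date]]:
    for start, end in merged:
        if start <= day <= end:
            return (start, end)
    return None


def check_inclusion(
    birth_date: dt.date,
    event: IndexEvent,
    diagnosis_months: set[tuple[str, str]],
    enrollment_spans: list[tuple[dt.date, dt.date]],
    config: StudyConfig,
) -> tuple[bool, Optional[str]]:
    """Evaluate inclusion criteria; return (passes, first failed criterion).

    *diagnosis_months* holds the patient's (icd10_code, year_month) pairs.
    Look-back requires one continuous merged enrollment span covering every
    day from the first day of ``index month - lookback_months`` through the
    index date itself.
    """
    if age_at(birth_date, event.index_date) < config.min_age_years:
        return False, "age"
    index_month = month_of(event.index_date)
    if (config.hcv_icd10, index_month) not in diagnosis_months:
        return False, "hcv_diagnosis"
    window_start = month_first_day(months_before(index_month, config.lookback_months))
    merged = merge_enrollment(enrollment_spans)
    span = _covering_span(merged, event.index_date)
    if span is None or span[0] > window_start:
        return False, "lookback"
    return True, None


def check_exclusion(
    event: IndexEvent,
    procedure_dates: list[tuple[str, dt.date]],
    config: StudyConfig,
) -> tuple[bool, Optional[str]]:
    """Evaluate exclusion criteria; return (excluded, reason)."""
    if len(event.regimens_on_index) >= 2:
        return True, "multiple_daa"
    window_start = event.index_date - dt.timedelta(days=config.transplant_window_days)
    codes = set(config.transplant_procedure_codes)
    for code, date in procedure_dates:
        if code in codes and window_start <= date <= event.index_date:
            return True, "transplant"
    return False, None


def build_cohort(bundle: ClaimsBundle, config: StudyConfig) -> CohortResult:
    """Apply index-event finding, inclusion and exclusion in order.

    The facility attributed to a patient is that of the index-date DAA
    prescription (lexicographically smallest id if several share the date,
    for determinism).
    """
    events = find_index_events(bundle, config)

    patients = {
        row.patient_id: row for row in bundle.patients.itertuples(index=False)
    }
    dx_by_patient: dict[str, set[tuple[str, str]]] = {}
    for row in bundle.diagnoses.itertuples(index=False):
        dx_by_patient.setdefault(row.patient_id, set()).add(
            (row.icd10_code, row.year_month)
        )
    enr_by_patient: dict[str, list[tuple[dt.date, dt.date]]] = {}
    for row in bundle.enrollment.itertuples(index=False):
        enr_by_patient.setdefault(row.patient_id, []).append(
            (row.start_date, row.end_date)
        )
    proc_by_patient: dict[str, list[tuple[str, dt.date]]] = {}
    for row in bundle.procedures.itertuples(index=False):
        proc_by_patient.setdefault(row.patient_id, []).append(
            (row.procedure_code, row.date)
        )

    daa_codes = config.daa_atc_codes
    facility_by_patient: dict[str, str] = {}
    for row in bundle.prescriptions.itertuples(index=False):
        ev = events.get(row.patient_id)
        if ev is None or row.atc_code not in daa_codes:
            continue
        if row.prescription_date == ev.index_date:
            cur = facility_by_patient.get(row.patient_id)
            if cur is None or row.facility_id < cur:
                facility_by_patient[row.patient_id] = row.facility_id

    removed: dict[str, list[str]] = {step: [] for step in ATTRITION_STEPS}
    included: list[dict] = []
    for pid in sorted(events):
        event = events[pid]
        patient = patients[pid]
        ok, reason = check_inclusion(
            patient.birth_date,
            event,
            dx_by_patient.get(pid, set()),
            enr_by_patient.get(pid, []),
            config,
        )
        if not ok:
            removed[reason].append(pid)
            continue
        excluded, reason = check_exclusion(
            event, proc_by_patient.get(pid, []), config
        )
        if excluded:
            removed[reason].append(pid)
            continue
        (group,) = event.regimens_on_index
        included.append(
            {
                "patient_id": pid,
                "group": group,
                "index_date": event.index_date,
                "age_at_index": age_at(patient.birth_date, event.index_date),
                "sex": patient.sex,
                "facility_id": facility_by_patient[pid],
            }
        )

    attrition_rows = [{"step": "daa_initiators", "n_remaining": len(events), "n_removed": 0}]
    remaining = len(events)
    for step in ATTRITION_STEPS:
        n = len(removed[step])
        remaining -= n
        attrition_rows.append({"step": step, "n_remaining": remaining, "n_removed": n})

    cohort = pd.DataFrame(included, columns=COHORT_COLUMNS)
    removed_df = pd.DataFrame(
        [
            {"patient_id": pid, "reason": step}
            for step in ATTRITION_STEPS
            for pid in sorted(removed[step])
        ],
        columns=["patient_id", "reason"],
    )
    return CohortResult(cohort, pd.DataFrame(attrition_rows), removed_df)


def format_attrition(attrition: pd.DataFrame) -> str:
    """Render the attrition report as a small text flow diagram."""
    labels = {
        "daa_initiators": "DAA initiation in identification period",
        "age": "age >= 18 at index",
        "hcv_diagnosis": "HCV (B18.2) diagnosis in index month",
        "lookback": "enrollment covering look-back and index date",
        "multiple_daa": "single DAA regimen at index",
        "transplant": "no liver transplant at index or within prior window",
    }
    lines = []
    for row in attrition.itertuples(index=False):
        label = labels.get(row.step, row.step)
        if row.step == "daa_initiators":
            lines.append(f"{label}: n = {row.n_remaining}")
        else:
            lines.append(f"  removed ({label}): {row.n_removed} -> n = {row.n_remaining}")
    return "\n".join(lines)
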