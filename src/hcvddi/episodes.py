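"""Treatment-episode construction and follow-up censoring.

A prescription of *s* days' supply starting on day *d* covers
``d .. d + s - 1``.  DAA therapy is continuous while the gap between the
running episode end and the next same-regimen prescription date is below
the grace threshold (default 7 days); a gap at or above the threshold ends
the episode at the last covered day.  Treatment days are the plain sum of
days' supply of the prescriptions in the episode (overlapping refills are
not stockpiled beyond the max of their end dates).

Follow-up runs from the index date to the earliest of: treatment
discontinuation (episode end), a prescription of the other DAA regimen,
disenrollment, or the administrative study end.  Date ties are resolved
switch > disenrollment > discontinuation > study end.
"""
from __future__ import annotations

import datetime as dt
from typing import Iterable, Optional, Sequence

import pandas as pd

from .claims import ClaimsBundle
from .cohort import merge_enrollment, _covering_span
from .config import StudyConfig

END_REASONS = ("discontinuation", "switch", "disenrollment", "study_end")

EPISODE_COLUMNS = [
    "patient_id", "group", "index_date", "episode_end", "treatment_days",
    "followup_end", "end_reason",
]

#: tie-break priority among same-date follow-up candidates (lower wins)
_REASON_PRIORITY = {"switch": 0, "disenrollment": 1, "discontinuation": 2, "study_end": 3}


def prescription_end(prescription_date: dt.date, days_supply: int) -> dt.date:
    """Last day covered by a prescription: date + supply - 1."""
    if days_supply < 1:
        raise ValueError("days_supply must be >= 1")
    return prescription_date + dt.timedelta(days=days_supply - 1)


def build_episode(
    prescriptions: Sequence[tuple[dt.date, int]], gap_threshold_days: int
) -> tuple[dt.date, int]:
    """Walk same-regimen refills sorted by date; return (episode_end, treatment_days).

    The first prescription is the index prescription.  A refill whose date
    minus the running episode end is below the threshold extends the episode
    (episode end becomes the max of covered ends); any larger gap stops the
    walk and later prescriptions are ignored.
    """
    if not prescriptions:
        raise ValueError("at least one prescription is required")
    first_date, first_supply = prescriptions[0]
    episode_end = prescription_end(first_date, first_supply)
    treatment_days = first_supply
    for date, supply in prescriptions[1:]:
        gap = (date - episode_end).days
        if gap >= gap_threshold_days:
            break
        episode_end = max(episode_end, prescription_end(date, supply))
        treatment_days += supply
    return episode_end, treatment_days


def determine_followup_end(
    index_date: dt.date,
    episode_end: dt.date,
    other_regimen_dates: Iterable[dt.date],
    enrollment_end: Optional[dt.date],
    config: StudyConfig,
) -> tuple[dt.date, str]:
    """Earliest censoring event after the index date, with its reason."""
    candidates: list[tuple[dt.date, int, str]] = [
        (episode_end, _REASON_PRIORITY["discontinuation"], "discontinuation"),
        (config.study_end, _REASON_PRIORITY["study_end"], "study_end"),
    ]
    switch_dates = [d for d in other_regimen_dates if d > index_date]
    if switch_dates:
        candidates.append((min(switch_dates), _REASON_PRIORITY["switch"], "switch"))
    if enrollment_end is not None:
        candidates.append(
            (enrollment_end, _REASON_PRIORITY["disenrollment"], "disenrollment")
        )
    date, _, reason = min(candidates)
    return date, reason


def build_episodes(
    cohort: pd.DataFrame, bundle: ClaimsBundle, config: StudyConfig
) -> pd.DataFrame:
    """One treatment episode and follow-up window per cohort patient."""
    daa_codes = config.daa_atc_codes
    own_rx: dict[str, list[tuple[dt.date, int]]] = {}
    other_rx: dict[str, list[dt.date]] = {}
    groups = dict(zip(cohort["patient_id"], cohort["group"]))
    index_dates = dict(zip(cohort["patient_id"], cohort["index_date"]))
    for row in bundle.prescriptions.itertuples(index=False):
        group = groups.get(row.patient_id)
        if group is None or row.atc_code not in daa_codes:
            continue
        if row.atc_code == config.daa_regimens[group]:
            if row.prescription_date >= index_dates[row.patient_id]:
                own_rx.setdefault(row.patient_id, []).append(
                    (row.prescription_date, row.days_supply)
                )
        else:
            other_rx.setdefault(row.patient_id, []).append(row.prescription_date)

    enr_by_patient: dict[str, list[tuple[dt.date, dt.date]]] = {}
    for row in bundle.enrollment.itertuples(index=False):
        if row.patient_id in groups:
            enr_by_patient.setdefault(row.patient_id, []).append(
                (row.start_date, row.end_date)
            )

    records = []
    for row in cohort.itertuples(index=False):
        rxs = sorted(own_rx[row.patient_id])
        episode_end, treatment_days = build_episode(rxs, config.gap_threshold_days)
        merged = merge_enrollment(enr_by_patient.get(row.patient_id, []))
        span = _covering_span(merged, row.index_date)
        enrollment_end = span[1] if span is not None else None
        followup_end, reason = determine_followup_end(
            row.index_date,
            episode_end,
            other_rx.get(row.patient_id, []),
            enrollment_end,
            config,
        )
        records.append(
            {
                "patient_id": row.patient_id,
                "group": row.group,
                "index_date": row.index_date,
                "episode_end": episode_end,
                "treatment_days": treatment_days,
                "followup_end": followup_end,
                "end_reason": reason,
            }
        )
    return pd.DataFrame(records, columns=EPISODE_COLUMNS)
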