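"""Per-patient DDI outcomes over the follow-up comedication set.

A comedication is any distinct normalized ingredient with at least one
prescription dated inside the closed follow-up interval
``[index_date, followup_end]``, excluding prescriptions carrying the index
regimen's own ATC code (a prescription of the *other* DAA regimen counts as
a comedication).  Supplies that overlap into follow-up from prescriptions
dated before the index are not counted.

Each comedication is classified against the knowledge base; per patient we
aggregate the interacting-ingredient count, any-DDI and two-or-more-DDI
flags, the maximum severity, the potential-DDI flag, and the set of
contraindicated (red) ingredients.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .claims import ClaimsBundle
from .config import StudyConfig
from .knowledge import KnowledgeBase, Severity, severity_max

DDI_RESULT_COLUMNS = [
    "patient_id", "group", "comedications", "n_comedications",
    "ddi_ingredients", "n_ddi_meds", "has_ddi", "has_ddi_ge2",
    "severity", "has_potential", "red_ingredients",
]


@dataclass
class PatientDDIResult:
    patient_id: str
    regimen: str
    comedications: frozenset[str]
    ddi_ingredients: frozenset[str]
    n_ddi_meds: int
    has_ddi: bool
    has_ddi_ge2: bool
    severity: Severity
    has_potential: bool
    red_ingredients: frozenset[str] = field(default_factory=frozenset)


def collect_comedications(
    prescriptions: Iterable[tuple[str, str, dt.date]],
    index_date: dt.date,
    followup_end: dt.date,
    own_atc: str,
) -> frozenset[str]:
    """Distinct ingredients prescribed during follow-up, own regimen excluded.

    *prescriptions* yields (ingredient, atc_code, prescription_date).
    """
    return frozenset(
        ingredient
        for ingredient, atc, date in prescriptions
        if atc != own_atc and index_date <= date <= followup_end
    )


def assess_patient(
    kb: KnowledgeBase, patient_id: str, regimen: str, comedications: Iterable[str]
) -> PatientDDIResult:
    """Classify each comedication and aggregate to the per-patient outcome."""
    comeds = frozenset(comedications)
    classifications = [kb.classify(regimen, ing) for ing in sorted(comeds)]
    ddi = frozenset(c.ingredient for c in classifications if c.is_ddi)
    red = frozenset(
        c.ingredient for c in classifications if c.severity is Severity.RED
    )
    return PatientDDIResult(
        patient_id=patient_id,
        regimen=regimen,
        comedications=comeds,
        ddi_ingredients=ddi,
        n_ddi_meds=len(ddi),
        has_ddi=len(ddi) >= 1,
        has_ddi_ge2=len(ddi) >= 2,
        severity=severity_max(c.severity for c in classifications),
        has_potential=any(c.is_potential for c in classifications),
        red_ingredients=red,
    )


def _join(items: frozenset[str]) -> str:
    return ";".join(sorted(items))


def assess_cohort(
    cohort: pd.DataFrame,
    episodes: pd.DataFrame,
    bundle: ClaimsBundle,
    kb: KnowledgeBase,
    config: StudyConfig,
) -> pd.DataFrame:
    """Per-patient DDI outcomes for the whole cohort."""
    windows = {
        row.patient_id: (row.index_date, row.followup_end)
        for row in episodes.itertuples(index=False)
    }
    rx_by_patient: dict[str, list] = {}
    for row in bundle.prescriptions.itertuples(index=False):
        if row.patient_id in windows:
            rx_by_patient.setdefault(row.patient_id, []).append(
                (row.ingredient, row.atc_code, row.prescription_date)
            )

    records = []
    for row in cohort.itertuples(index=False):
        index_date, followup_end = windows[row.patient_id]
        comeds = collect_comedications(
            rx_by_patient.get(row.patient_id, []),
            index_date,
            followup_end,
            config.daa_regimens[row.group],
        )
        result = assess_patient(kb, row.patient_id, row.group, comeds)
        records.append(
            {
                "patient_id": result.patient_id,
                "group": result.regimen,
                "comedications": _join(result.comedications),
                "n_comedications": len(result.comedications),
                "ddi_ingredients": _join(result.ddi_ingredients),
                "n_ddi_meds": result.n_ddi_meds,
                "has_ddi": result.has_ddi,
                "has_ddi_ge2": result.has_ddi_ge2,
                "severity": result.severity.label,
                "has_potential": result.has_potential,
                "red_ingredients": _join(result.red_ingredients),
            }
        )
    return pd.DataFrame(records, columns=DDI_RESULT_COLUMNS)


def tally_red_drugs(
    ddi_results: pd.DataFrame, kb: KnowledgeBase, regimen: str
) -> pd.DataFrame:
    """Patient counts per contraindicated (red) ingredient, zeros retained.

    Every knowledge-base ingredient that classifies red for *regimen* gets a
    row, in knowledge-base order, counting patients of that group whose
    follow-up comedications include it.
    """
    group = ddi_results[ddi_results["group"] == regimen]
    comed_sets = [set(c.split(";")) if c else set() for c in group["comedications"]]
    rows = []
    for ingredient in kb.red_ingredients(regimen):
        n = sum(ingredient in comeds for comeds in comed_sets)
        rows.append({"regimen": regimen, "ingredient": ingredient, "n_patients": n})
    return pd.DataFrame(rows, columns=["regimen", "ingredient", "n_patients"])
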