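"""Synthetic administrative-claims generator with planted ground truth.

Every downstream stage of the pipeline is testable without proprietary data:
the generator draws a population of DAA initiators with group-dependent age,
comorbidity and HCV-severity distributions (the SOF/VEL group older, more
comorbid and enriched for decompensated cirrhosis, as that regimen is the
one indicated there), realizes their enrollment spans, month-granular
diagnoses, day-granular DAA refill chains (back-to-back except planted
refill gaps), regimen switches, disenrollment, and per-drug Bernoulli
comedication draws keyed to the interaction knowledge base — and emits a
truth table computed from the same draws: who is eligible and why not,
the index date, follow-up end and censoring reason, the comedication set
and the resulting DDI labels.

A configurable fraction of patients is planted ineligible by a *minimal
single-rule violation* (under-age, HCV diagnosis in the wrong month,
insufficient look-back enrollment, two regimens on the index date, or a
recent liver transplant) so the attrition flow is checkable rule by rule.
"""
from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from dateutil.relativedelta import relativedelta
from pydantic import BaseModel, Field, model_validator

from .claims import ClaimsBundle, _coerce_types, TABLE_COLUMNS
from .config import (
    REGIMEN_INGREDIENTS,
    StudyConfig,
    age_at,
    month_first_day,
    month_last_day,
    month_of,
    months_before,
    parse_month,
)
from .covariates import CHARLSON_WEIGHTS
from .knowledge import KnowledgeBase, Severity, classify_entry, load_knowledge_base

GROUPS = ("SOF/VEL", "GLE/PIB")

EXCLUSION_REASONS = ("age", "hcv_diagnosis", "lookback", "multiple_daa", "transplant")

HCV_SEVERITY_KEYS = (
    "decompensated_cirrhosis", "compensated_cirrhosis", "chronic_hepatitis_c", "others",
)

#: representative baseline diagnosis code planted per comorbidity category
COMORBIDITY_CODES = {
    "myocardial_infarction": "I21.9",
    "congestive_heart_failure": "I50.0",
    "peripheral_vascular_disease": "I70.9",
    "cerebrovascular_disease": "I63.9",
    "dementia": "F03",
    "chronic_pulmonary_disease": "J44.9",
    "rheumatic_disease": "M05.9",
    "peptic_ulcer_disease": "K25.9",
    "diabetes_without_complication": "E11.9",
    "diabetes_with_complication": "E11.2",
    "hemiplegia_paraplegia": "G81.9",
    "renal_disease": "N18.9",
    "any_malignancy": "C34.9",
    "metastatic_solid_tumor": "C78.0",
    "aids_hiv": "B20",
}

_SEVERITY_CODES = {
    "decompensated_cirrhosis": "K72.9",
    "compensated_cirrhosis": "K74.1",
}

_BED_CATEGORY_PROBS = {
    "unknown": 0.004, "<20": 0.105, "20-99": 0.027, "100-199": 0.099,
    "200-299": 0.080, "300-399": 0.150, "400-500": 0.107, ">=500": 0.428,
}

#: per-drug probability of >= 1 prescription during DAA treatment,
#: calibrated to the per-drug shares of each group's follow-up tables
DEFAULT_COMEDICATION_PREVALENCES: dict[str, dict[str, float]] = {
    "SOF/VEL": {
        "esomeprazole": 0.165, "vonoprazan": 0.113, "lansoprazole": 0.099,
        "rabeprazole": 0.086, "famotidine": 0.062, "omeprazole": 0.015,
        "lafutidine": 0.002, "cimetidine": 0.002, "ranitidine hydrochloride": 0.002,
        "risperidone": 0.009, "atorvastatin": 0.011, "rosuvastatin": 0.009,
        "fluvastatin": 0.002,
    },
    "GLE/PIB": {
        "atorvastatin": 0.0052, "carbamazepine": 0.0042, "dabigatran": 0.0019,
        "phenytoin": 0.0019, "simvastatin": 0.0010, "phenobarbital": 0.0015,
        "primidone": 0.0003, "eltrombopag": 0.0004, "amobarbital": 0.0001,
        "bosentan": 0.0003, "drospirenone/ethinyl estradiol": 0.0003,
        "norethisterone/ethinyl estradiol": 0.0004, "vincristine": 0.0003,
        "ledipasvir/sofosbuvir": 0.0003,
        "quetiapine": 0.0045, "aripiprazole": 0.0029, "paliperidone": 0.0015,
        "risperidone": 0.0083, "lurasidone": 0.0001,
        "domperidone": 0.0128, "sulfasalazine": 0.0054, "droperidol": 0.0003,
        "lansoprazole": 0.0738, "esomeprazole": 0.0671, "vonoprazan": 0.0522,
        "famotidine": 0.0488, "rabeprazole": 0.0368, "omeprazole": 0.0115,
        "lafutidine": 0.0057, "loperamide": 0.0054, "cimetidine": 0.0033,
        "nizatidine": 0.0031, "granisetron": 0.0010, "roxatidine": 0.0007,
        "rosuvastatin": 0.0237, "pravastatin": 0.0098, "ezetimibe": 0.0096,
        "pitavastatin": 0.0096, "fluvastatin": 0.0007,
    },
}

#: common drugs with no interaction against either regimen
DEFAULT_NONINTERACTING_PREVALENCES: dict[str, float] = {
    "amlodipine": 0.25, "acetaminophen": 0.20, "magnesium oxide": 0.15,
    "ursodeoxycholic acid": 0.15, "aspirin": 0.12, "metformin": 0.10,
    "levothyroxine": 0.05, "allopurinol": 0.05,
}

TRUTH_COLUMNS = [
    "patient_id", "true_group", "true_included", "exclusion_reason",
    "true_index_date", "true_followup_end", "true_end_reason",
    "true_comedications", "true_has_ddi", "true_n_ddi_meds",
    "true_severity", "true_has_potential", "true_cci",
]


class SimulationConfig(BaseModel):
    """Knobs of the synthetic population; defaults encode the study conditions.

    Group shares, age distributions, comorbidity prevalences and the HCV
    severity mix are calibrated to the published baseline table of the two
    regimen groups; per-drug comedication prevalences to the published
    per-drug follow-up shares.  The severity mix carries an ``others`` key
    for completeness but it must be 0: a cohort patient always has the
    qualifying chronic-hepatitis diagnosis inside the baseline window, so
    the classifier can never return ``others`` for an included patient.
    """

    n_patients: int = 500
    seed: int = 0
    p_sofvel: float = 467 / 7338
    p_male: float = 0.5
    age_mean: dict[str, float] = Field(
        default_factory=lambda: {"SOF/VEL": 73.8, "GLE/PIB": 69.7}
    )
    age_sd: dict[str, float] = Field(
        default_factory=lambda: {"SOF/VEL": 10.5, "GLE/PIB": 13.3}
    )
    comorbidity_prevalences: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "SOF/VEL": {
                "myocardial_infarction": 0.015, "congestive_heart_failure": 0.238,
                "peripheral_vascular_disease": 0.079, "cerebrovascular_disease": 0.133,
                "dementia": 0.056, "chronic_pulmonary_disease": 0.201,
                "rheumatic_disease": 0.039, "peptic_ulcer_disease": 0.310,
                "diabetes_without_complication": 0.099,
                "diabetes_with_complication": 0.077,
                "hemiplegia_paraplegia": 0.002, "renal_disease": 0.088,
                "any_malignancy": 0.407, "metastatic_solid_tumor": 0.015,
                "aids_hiv": 0.002,
            },
            "GLE/PIB": {
                "myocardial_infarction": 0.022, "congestive_heart_failure": 0.185,
                "peripheral_vascular_disease": 0.107, "cerebrovascular_disease": 0.148,
                "dementia": 0.038, "chronic_pulmonary_disease": 0.173,
                "rheumatic_disease": 0.040, "peptic_ulcer_disease": 0.196,
                "diabetes_without_complication": 0.068,
                "diabetes_with_complication": 0.096,
                "hemiplegia_paraplegia": 0.010, "renal_disease": 0.100,
                "any_malignancy": 0.207, "metastatic_solid_tumor": 0.016,
                "aids_hiv": 0.002,
            },
        }
    )
    hcv_severity_mix: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "SOF/VEL": {
                "decompensated_cirrhosis": 0.276, "compensated_cirrhosis": 0.021,
                "chronic_hepatitis_c": 0.703, "others": 0.0,
            },
            "GLE/PIB": {
                "decompensated_cirrhosis": 0.003, "compensated_cirrhosis": 0.033,
                "chronic_hepatitis_c": 0.964, "others": 0.0,
            },
        }
    )
    comedication_prevalences: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            g: dict(v) for g, v in DEFAULT_COMEDICATION_PREVALENCES.items()
        }
    )
    noninteracting_prevalences: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_NONINTERACTING_PREVALENCES)
    )
    baseline_med_count_mean: float = 9.0
    baseline_med_count_dispersion: float = 2.0
    treatment_duration_weeks: dict[str, dict[int, float]] = Field(
        default_factory=lambda: {
            "SOF/VEL": {12: 0.9, 24: 0.1},
            "GLE/PIB": {8: 0.6, 12: 0.4},
        }
    )
    p_gap_event: float = 0.10
    p_switch: float = 0.02
    p_disenroll_during_treatment: float = 0.03
    fraction_ineligible: dict[str, float] = Field(
        default_factory=lambda: {
            "age": 0.02, "hcv_diagnosis": 0.03, "lookback": 0.03,
            "multiple_daa": 0.01, "transplant": 0.01,
        }
    )
    n_facilities: int = 30
    baseline_med_pool_size: int = 300

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("p_sofvel", "p_male", "p_gap_event", "p_switch",
                     "p_disenroll_during_treatment"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for group in GROUPS:
            mix = self.hcv_severity_mix[group]
            if set(mix) != set(HCV_SEVERITY_KEYS):
                raise ValueError(f"hcv_severity_mix[{group}] must have keys {HCV_SEVERITY_KEYS}")
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"hcv_severity_mix[{group}] must sum to 1")
            if mix["others"] > 0:
                raise ValueError(
                    "hcv_severity_mix 'others' must be 0: a cohort patient always "
                    "carries the qualifying HCV diagnosis inside the baseline "
                    "window, so 'others' is unreachable"
                )
            opts = self.treatment_duration_weeks[group]
            if abs(sum(opts.values()) - 1.0) > 1e-6:
                raise ValueError(f"treatment_duration_weeks[{group}] must sum to 1")
            if any(w < 1 for w in opts):
                raise ValueError("treatment durations must be >= 1 week")
            for p in list(self.comorbidity_prevalences[group].values()) + list(
                self.comedication_prevalences.get(group, {}).values()
            ):
                if not 0.0 <= p <= 1.0:
                    raise ValueError("prevalences must be in [0, 1]")
        unknown = set(self.fraction_ineligible) - set(EXCLUSION_REASONS)
        if unknown:
            raise ValueError(f"unknown ineligibility reasons: {sorted(unknown)}")
        if any(not 0.0 <= p <= 1.0 for p in self.fraction_ineligible.values()):
            raise ValueError("fraction_ineligible values must be in [0, 1]")
        if sum(self.fraction_ineligible.values()) > 1.0 + 1e-9:
            raise ValueError("fraction_ineligible must sum to <= 1")
        return self

    def validate_against(self, study: StudyConfig) -> None:
        """Reject configurations that cannot fit the study period."""
        horizon = (study.study_end - study.identification_start).days
        longest = 7 * max(w for g in GROUPS for w in self.treatment_duration_weeks[g])
        if longest > horizon:
            raise ValueError(
                f"treatment duration {longest} d exceeds the "
                f"{horizon} d between identification start and study end"
            )


def implied_ddi_prevalence(
    sim: SimulationConfig, kb: KnowledgeBase, regimen: str
) -> float:
    """P(any interacting comedication) implied by the independent per-drug draws.

    Equals ``1 - prod(1 - p_d)`` over configured drugs whose knowledge-base
    classification for *regimen* is a DDI.  Regimen switches (which add the
    other DAA as a comedication) are a separate mechanism not counted here.
    """
    p_none = 1.0
    for ingredient, p in sim.comedication_prevalences.get(regimen, {}).items():
        if kb.classify(regimen, ingredient).is_ddi:
            p_none *= 1.0 - p
    return 1.0 - p_none


# ---------------------------------------------------------------------------
# drawing helpers


def _categorical(rng: np.random.Generator, options: dict[str, float]) -> Optional[str]:
    """Draw a key by its probability; None for the residual mass."""
    u = rng.random()
    cum = 0.0
    for key, p in options.items():
        cum += p
        if u < cum:
            return key
    return None


def _truncated_normal(rng, mean: float, sd: float, lo: float, hi: float) -> float:
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x


def _random_day(rng, start: dt.date, end: dt.date) -> dt.date:
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def _random_month(rng, first: str, last: str) -> str:
    y1, m1 = parse_month(first)
    y2, m2 = parse_month(last)
    a, b = y1 * 12 + m1 - 1, y2 * 12 + m2 - 1
    pick = int(rng.integers(a, b + 1))
    return f"{pick // 12:04d}-{pick % 12 + 1:02d}"


def _truth_ddi(kb: KnowledgeBase, regimen: str, comeds: set[str]):
    """Generator-side aggregation of the planted comedication set."""
    n_ddi = 0
    max_sev = 0
    potential = False
    lp_colors = {"yellow": 1, "amber": 2, "red": 3}
    pi_sev = {"none": 0, "caution": 2, "contraindicated": 3}
    for ing in comeds:
        entry = kb.get(regimen, ing)
        if entry is None:
            continue
        lp = lp_colors.get(entry.liverpool_status)
        sev = lp if lp is not None else pi_sev[entry.pi_status]
        if lp is not None or entry.pi_status != "none":
            n_ddi += 1
        if lp is not None and entry.pi_status == "none":
            potential = True
        max_sev = max(max_sev, sev)
    label = {0: "none", 1: "yellow", 2: "amber", 3: "red"}[max_sev]
    return n_ddi, label, potential


def _truth_cci(flags: set[str]) -> int:
    effective = set(flags)
    if "diabetes_with_complication" in effective:
        effective.discard("diabetes_without_complication")
    if "moderate_severe_liver_disease" in effective:
        effective.discard("mild_liver_disease")
    if "metastatic_solid_tumor" in effective:
        effective.discard("any_malignancy")
    return sum(CHARLSON_WEIGHTS[c] for c in effective)


# ---------------------------------------------------------------------------
# generation


def generate(
    sim: SimulationConfig,
    study: Optional[StudyConfig] = None,
    kb: Optional[KnowledgeBase] = None,
) -> tuple[ClaimsBundle, pd.DataFrame]:
    """Generate a claims bundle and its truth table; deterministic per seed."""
    study = study or StudyConfig()
    kb = kb or load_knowledge_base()
    sim.validate_against(study)
    rng = np.random.default_rng(sim.seed)

    facilities = []
    facility_ids = [f"F{i:04d}" for i in range(1, sim.n_facilities + 1)]
    for fid in facility_ids:
        bed = _categorical(rng, _BED_CATEGORY_PROBS) or ">=500"
        facilities.append(
            {"facility_id": fid, "bed_category": bed,
             "cancer_hub": bool(rng.random() < 0.453)}
        )

    med_pool = [f"med{i:03d}" for i in range(sim.baseline_med_pool_size)]
    other_group = {"SOF/VEL": "GLE/PIB", "GLE/PIB": "SOF/VEL"}

    patients, enrollment, diagnoses, prescriptions, procedures = [], [], [], [], []
    truth_rows = []

    for i in range(sim.n_patients):
        pid = f"P{i + 1:06d}"
        group = "SOF/VEL" if rng.random() < sim.p_sofvel else "GLE/PIB"
        reason = _categorical(rng, sim.fraction_ineligible)
        eligible = reason is None
        home_facility = facility_ids[int(rng.integers(0, len(facility_ids)))]

        weeks = int(_categorical(
            rng, {str(w): p for w, p in sim.treatment_duration_weeks[group].items()}
        ) or max(sim.treatment_duration_weeks[group]))
        total_days = 7 * weeks

        index_date = _random_day(rng, study.identification_start, study.identification_end)
        index_month = month_of(index_date)

        # age / birth date (completed years at index)
        if reason == "age":
            age = int(rng.integers(12, study.min_age_years))
        else:
            age = int(_truncated_normal(
                rng, sim.age_mean[group], sim.age_sd[group], study.min_age_years, 100
            ))
        birth = index_date - relativedelta(years=age) - dt.timedelta(
            days=int(rng.integers(0, 364))
        )
        while age_at(birth, index_date) != age:
            birth += dt.timedelta(days=1)
        sex = "male" if rng.random() < sim.p_male else "female"
        patients.append({"patient_id": pid, "birth_date": birth, "sex": sex})

        # enrollment span
        lookback_first = month_first_day(
            months_before(index_month, study.lookback_months)
        )
        if reason == "lookback":
            enr_start = index_date - dt.timedelta(days=45)
        else:
            enr_start = _random_day(rng, study.study_start, lookback_first)
        disenroll = eligible and rng.random() < sim.p_disenroll_during_treatment
        if disenroll:
            enr_end = index_date + dt.timedelta(days=int(rng.integers(14, total_days + 1)))
        else:
            # enrollment continues past the observation window
            enr_end = study.study_end + dt.timedelta(days=int(rng.integers(30, 400)))
        insurer = "LSEHS" if age >= 75 else ("SHI" if rng.random() < 0.5 else "NHI")
        enrollment.append(
            {"patient_id": pid, "start_date": enr_start, "end_date": enr_end,
             "insurer_type": insurer}
        )

        # diagnoses: qualifying HCV code, severity code, comorbidity codes
        hcv_month = (
            months_before(index_month, 1) if reason == "hcv_diagnosis" else index_month
        )
        diagnoses.append(
            {"patient_id": pid, "icd10_code": study.hcv_icd10, "year_month": hcv_month}
        )
        baseline_first_month = month_of(max(enr_start, study.study_start))
        severity = _categorical(rng, sim.hcv_severity_mix[group]) or "others"
        if severity in _SEVERITY_CODES:
            diagnoses.append(
                {"patient_id": pid, "icd10_code": _SEVERITY_CODES[severity],
                 "year_month": _random_month(rng, baseline_first_month, index_month)}
            )
        flags = {"mild_liver_disease"}
        if severity == "decompensated_cirrhosis":
            flags.add("moderate_severe_liver_disease")
        for category, p in sim.comorbidity_prevalences[group].items():
            if rng.random() < p:
                flags.add(category)
                diagnoses.append(
                    {"patient_id": pid, "icd10_code": COMORBIDITY_CODES[category],
                     "year_month": _random_month(rng, baseline_first_month, index_month)}
                )

        # baseline comedications in the look-back months
        r = sim.baseline_med_count_dispersion
        m = sim.baseline_med_count_mean
        k = int(rng.negative_binomial(r, r / (r + m)))
        k = min(k, len(med_pool))
        picks = rng.choice(len(med_pool), size=k, replace=False)
        baseline_window_end = month_last_day(months_before(index_month, 1))
        for j in picks:
            prescriptions.append(
                {"patient_id": pid, "ingredient": med_pool[int(j)], "atc_code": "",
                 "prescription_date": _random_day(rng, lookback_first, baseline_window_end),
                 "days_supply": int(rng.integers(7, 31)),
                 "facility_id": facility_ids[int(rng.integers(0, len(facility_ids)))]}
            )

        # DAA refill chain, back-to-back except a planted gap
        supplies = [28] * (total_days // 28)
        if total_days % 28:
            supplies.append(total_days % 28)
        gap_at = None
        gap_len = 0
        if len(supplies) >= 2 and rng.random() < sim.p_gap_event:
            gap_at = int(rng.integers(1, len(supplies)))
            gap_len = study.gap_threshold_days + int(rng.integers(0, 15))
        refills: list[tuple[dt.date, int]] = []
        prev_end = None
        for j, supply in enumerate(supplies):
            if j == 0:
                date = index_date
            elif j == gap_at:
                date = prev_end + dt.timedelta(days=gap_len)
            else:
                date = prev_end + dt.timedelta(days=1)
            prev_end = date + dt.timedelta(days=supply - 1)
            if date <= study.study_end:
                refills.append((date, supply))
                prescriptions.append(
                    {"patient_id": pid, "ingredient": REGIMEN_INGREDIENTS[group],
                     "atc_code": study.daa_regimens[group],
                     "prescription_date": date, "days_supply": supply,
                     "facility_id": home_facility}
                )

        # planted single-rule violations
        if reason == "multiple_daa":
            prescriptions.append(
                {"patient_id": pid,
                 "ingredient": REGIMEN_INGREDIENTS[other_group[group]],
                 "atc_code": study.daa_regimens[other_group[group]],
                 "prescription_date": index_date, "days_supply": 28,
                 "facility_id": home_facility}
            )
        if reason == "transplant":
            code = study.transplant_procedure_codes[
                int(rng.integers(0, len(study.transplant_procedure_codes)))
            ]
            procedures.append(
                {"patient_id": pid, "procedure_code": code,
                 "date": index_date - dt.timedelta(
                     days=int(rng.integers(0, study.transplant_window_days + 1))
                 )}
            )

        # the treatment episode as realized by the records above
        ep_end, _ = _episode_from(refills, study.gap_threshold_days)

        # regimen switch
        switch_date = None
        if eligible and rng.random() < sim.p_switch:
            cand = index_date + dt.timedelta(days=int(rng.integers(7, total_days + 1)))
            if cand <= study.study_end:
                switch_date = cand
                prescriptions.append(
                    {"patient_id": pid,
                     "ingredient": REGIMEN_INGREDIENTS[other_group[group]],
                     "atc_code": study.daa_regimens[other_group[group]],
                     "prescription_date": switch_date, "days_supply": 28,
                     "facility_id": home_facility}
                )

        # follow-up window (earliest candidate; ties switch > disenrollment >
        # discontinuation > study end)
        candidates = [
            (ep_end, 2, "discontinuation"), (study.study_end, 3, "study_end"),
            (enr_end, 1, "disenrollment"),
        ]
        if switch_date is not None:
            candidates.append((switch_date, 0, "switch"))
        fu_end, _, fu_reason = min(candidates)

        # on-treatment comedications inside the follow-up window
        comed_end = fu_end if eligible else min(ep_end, study.study_end)
        comeds: set[str] = set()
        for ingredient, p in sim.comedication_prevalences.get(group, {}).items():
            if rng.random() < p:
                comeds.add(ingredient)
                prescriptions.append(
                    {"patient_id": pid, "ingredient": ingredient, "atc_code": "",
                     "prescription_date": _random_day(rng, index_date, comed_end),
                     "days_supply": int(rng.integers(7, 31)),
                     "facility_id": facility_ids[int(rng.integers(0, len(facility_ids)))]}
                )
        for ingredient, p in sim.noninteracting_prevalences.items():
            if rng.random() < p:
                comeds.add(ingredient)
                prescriptions.append(
                    {"patient_id": pid, "ingredient": ingredient, "atc_code": "",
                     "prescription_date": _random_day(rng, index_date, comed_end),
                     "days_supply": int(rng.integers(7, 31)),
                     "facility_id": facility_ids[int(rng.integers(0, len(facility_ids)))]}
                )
        if switch_date is not None and switch_date <= fu_end:
            comeds.add(REGIMEN_INGREDIENTS[other_group[group]])

        if eligible:
            n_ddi, sev_label, potential = _truth_ddi(kb, group, comeds)
            truth_rows.append(
                {"patient_id": pid, "true_group": group, "true_included": True,
                 "exclusion_reason": "", "true_index_date": index_date,
                 "true_followup_end": fu_end, "true_end_reason": fu_reason,
                 "true_comedications": ";".join(sorted(comeds)),
                 "true_has_ddi": n_ddi >= 1, "true_n_ddi_meds": n_ddi,
                 "true_severity": sev_label, "true_has_potential": potential,
                 "true_cci": _truth_cci(flags)}
            )
        else:
            truth_rows.append(
                {"patient_id": pid, "true_group": group, "true_included": False,
                 "exclusion_reason": reason, "true_index_date": index_date,
                 "true_followup_end": None, "true_end_reason": "",
                 "true_comedications": "", "true_has_ddi": None,
                 "true_n_ddi_meds": None, "true_severity": "",
                 "true_has_potential": None, "true_cci": _truth_cci(flags)}
            )

    tables = {
        "patients": pd.DataFrame(patients, columns=TABLE_COLUMNS["patients"]),
        "enrollment": pd.DataFrame(enrollment, columns=TABLE_COLUMNS["enrollment"]),
        "diagnoses": pd.DataFrame(diagnoses, columns=TABLE_COLUMNS["diagnoses"]),
        "prescriptions": pd.DataFrame(
            prescriptions, columns=TABLE_COLUMNS["prescriptions"]
        ),
        "procedures": pd.DataFrame(procedures, columns=TABLE_COLUMNS["procedures"]),
        "facilities": pd.DataFrame(facilities, columns=TABLE_COLUMNS["facilities"]),
    }
    bundle = ClaimsBundle(**{k: _coerce_types(k, v) for k, v in tables.items()})
    # column-wise object construction keeps ints/None from float coercion
    truth = pd.DataFrame(
        {
            col: pd.Series([row[col] for row in truth_rows], dtype=object)
            for col in TRUTH_COLUMNS
        },
        columns=TRUTH_COLUMNS,
    )
    return bundle, truth


def _episode_from(refills, gap_threshold: int):
    """Episode end and treatment days from the realized refill list."""
    (d0, s0), rest = refills[0], refills[1:]
    end = d0 + dt.timedelta(days=s0 - 1)
    days = s0
    for d, s in rest:
        if (d - end).days >= gap_threshold:
            break
        end = max(end, d + dt.timedelta(days=s - 1))
        days += s
    return end, days


# ---------------------------------------------------------------------------
# truth I/O


def write_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = truth.copy()
    for col in TRUTH_COLUMNS:
        out[col] = [
            "" if v is None else
            v.isoformat() if isinstance(v, dt.date) else
            str(v)
            for v in out[col]
        ]
    out.to_csv(path, index=False)
    return path


def _parse_optional(value: str, kind: str):
    if value == "":
        return None
    if kind == "date":
        return dt.date.fromisoformat(value)
    if kind == "bool":
        return value == "True"
    if kind == "int":
        return int(value)
    return value


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != TRUTH_COLUMNS:
        raise ValueError(f"truth file: expected columns {TRUTH_COLUMNS}")
    kinds = {
        "true_included": "bool", "true_index_date": "date",
        "true_followup_end": "date", "true_has_ddi": "bool",
        "true_n_ddi_meds": "int", "true_has_potential": "bool", "true_cci": "int",
    }
    out = {}
    for col in TRUTH_COLUMNS:
        kind = kinds.get(col)
        if kind is None:
            out[col] = list(df[col])
        else:
            out[col] = [_parse_optional(v, kind) for v in df[col]]
    return pd.DataFrame(out, columns=TRUTH_COLUMNS).astype(object)
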