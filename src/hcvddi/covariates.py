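"""Baseline characteristics: comorbidities, Charlson index, comedication
count, HCV severity, facility attributes.

Comorbidity flags follow the 17-category ICD-10 mapping of Quan et al.'s
Charlson adaptation (shipped as package data, overridable); the Charlson
comorbidity index (CCI) uses the original 1/2/3/6 weights with the standard
hierarchy rules (complicated diabetes supersedes uncomplicated,
moderate/severe liver disease supersedes mild, metastatic tumour supersedes
any malignancy).

HCV severity is graded by a precedence mapping: hepatic decompensation
codes > cirrhosis codes > chronic hepatitis C (B18.2) > others.

The baseline window for diagnoses is every record dated in or before the
index month; the baseline comedication count covers the 3 calendar months
preceding the index month (distinct non-DAA ingredients).
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .claims import ClaimsBundle
from .config import StudyConfig, month_of, months_before, parse_month

COMORBIDITY_CATEGORIES = [
    "myocardial_infarction",
    "congestive_heart_failure",
    "peripheral_vascular_disease",
    "cerebrovascular_disease",
    "dementia",
    "chronic_pulmonary_disease",
    "rheumatic_disease",
    "peptic_ulcer_disease",
    "mild_liver_disease",
    "diabetes_without_complication",
    "diabetes_with_complication",
    "hemiplegia_paraplegia",
    "renal_disease",
    "any_malignancy",
    "moderate_severe_liver_disease",
    "metastatic_solid_tumor",
    "aids_hiv",
]

#: original Charlson weights over the 17 categories
CHARLSON_WEIGHTS: dict[str, int] = {
    "myocardial_infarction": 1,
    "congestive_heart_failure": 1,
    "peripheral_vascular_disease": 1,
    "cerebrovascular_disease": 1,
    "dementia": 1,
    "chronic_pulmonary_disease": 1,
    "rheumatic_disease": 1,
    "peptic_ulcer_disease": 1,
    "mild_liver_disease": 1,
    "diabetes_without_complication": 1,
    "diabetes_with_complication": 2,
    "hemiplegia_paraplegia": 2,
    "renal_disease": 2,
    "any_malignancy": 2,
    "moderate_severe_liver_disease": 3,
    "metastatic_solid_tumor": 6,
    "aids_hiv": 6,
}

HCV_SEVERITY_PRECEDENCE = [
    "decompensated_cirrhosis",
    "compensated_cirrhosis",
    "chronic_hepatitis_c",
]
HCV_SEVERITY_LEVELS = HCV_SEVERITY_PRECEDENCE + ["others"]

COVARIATE_COLUMNS = (
    ["patient_id"]
    + COMORBIDITY_CATEGORIES
    + ["cci", "n_baseline_comedications", "hcv_severity", "bed_category", "cancer_hub"]
)


def _normalize_code(code: str) -> str:
    return code.replace(".", "").upper()


def _load_prefix_map(path: Path) -> dict[str, tuple[str, ...]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    mapping: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        mapping.setdefault(row.category, []).append(_normalize_code(row.icd10_prefix))
    return {k: tuple(v) for k, v in mapping.items()}


def load_comorbidity_map(path: Optional[str | Path] = None) -> dict[str, tuple[str, ...]]:
    if path is None:
        path = Path(str(resources.files("hcvddi").joinpath("data/comorbidity_map.csv")))
    return _load_prefix_map(Path(path))


def load_hcv_severity_map(path: Optional[str | Path] = None) -> dict[str, tuple[str, ...]]:
    if path is None:
        path = Path(str(resources.files("hcvddi").joinpath("data/hcv_severity_map.csv")))
    return _load_prefix_map(Path(path))


def map_comorbidities(
    codes: Iterable[str], mapping: Mapping[str, tuple[str, ...]]
) -> dict[str, bool]:
    """Flag each comorbidity category with a matching baseline code.

    Matching is by ICD-10 prefix after stripping the dot; unmapped codes are
    ignored.
    """
    normalized = [_normalize_code(c) for c in codes]
    flags = {}
    for category in COMORBIDITY_CATEGORIES:
        prefixes = mapping.get(category, ())
        flags[category] = any(
            code.startswith(p) for code in normalized for p in prefixes
        )
    return flags


def cci_score(flags: Mapping[str, bool], weights: Optional[Mapping[str, int]] = None) -> int:
    """Weighted Charlson sum with the standard hierarchy rules applied."""
    weights = weights or CHARLSON_WEIGHTS
    effective = {c: bool(flags.get(c, False)) for c in COMORBIDITY_CATEGORIES}
    if effective["diabetes_with_complication"]:
        effective["diabetes_without_complication"] = False
    if effective["moderate_severe_liver_disease"]:
        effective["mild_liver_disease"] = False
    if effective["metastatic_solid_tumor"]:
        effective["any_malignancy"] = False
    return sum(weights[c] for c, on in effective.items() if on)


def count_baseline_comedications(
    prescriptions: Iterable[tuple[str, str, "dt.date"]],
    index_month: str,
    config: StudyConfig,
) -> int:
    """Distinct non-DAA ingredients prescribed in the look-back months.

    *prescriptions* yields (ingredient, atc_code, prescription_date) tuples;
    the window is the ``lookback_months`` calendar months strictly before
    the index month.
    """
    window = {
        months_before(index_month, k) for k in range(1, config.lookback_months + 1)
    }
    daa_codes = config.daa_atc_codes
    ingredients = {
        ingredient
        for ingredient, atc, date in prescriptions
        if atc not in daa_codes and month_of(date) in window
    }
    return len(ingredients)


def classify_hcv_severity(
    codes: Iterable[str], severity_map: Mapping[str, tuple[str, ...]]
) -> str:
    """Highest-precedence HCV severity category with a matching code."""
    normalized = [_normalize_code(c) for c in codes]
    for category in HCV_SEVERITY_PRECEDENCE:
        prefixes = severity_map.get(category, ())
        if any(code.startswith(p) for code in normalized for p in prefixes):
            return category
    return "others"


def build_covariates(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    config: StudyConfig,
    comorbidity_map: Optional[Mapping[str, tuple[str, ...]]] = None,
    severity_map: Optional[Mapping[str, tuple[str, ...]]] = None,
) -> pd.DataFrame:
    """Baseline profile per cohort patient."""
    comorbidity_map = comorbidity_map or load_comorbidity_map()
    severity_map = severity_map or load_hcv_severity_map()

    in_cohort = set(cohort["patient_id"])
    dx_by_patient: dict[str, list[tuple[str, str]]] = {}
    for row in bundle.diagnoses.itertuples(index=False):
        if row.patient_id in in_cohort:
            dx_by_patient.setdefault(row.patient_id, []).append(
                (row.icd10_code, row.year_month)
            )
    rx_by_patient: dict[str, list] = {}
    for row in bundle.prescriptions.itertuples(index=False):
        if row.patient_id in in_cohort:
            rx_by_patient.setdefault(row.patient_id, []).append(
                (row.ingredient, row.atc_code, row.prescription_date)
            )
    facilities = {
        row.facility_id: (row.bed_category, row.cancer_hub)
        for row in bundle.facilities.itertuples(index=False)
    }

    records = []
    for row in cohort.itertuples(index=False):
        index_month = month_of(row.index_date)
        cutoff = parse_month(index_month)
        baseline_codes = [
            code
            for code, ym in dx_by_patient.get(row.patient_id, [])
            if parse_month(ym) <= cutoff
        ]
        flags = map_comorbidities(baseline_codes, comorbidity_map)
        bed_category, cancer_hub = facilities[row.facility_id]
        rec = {"patient_id": row.patient_id, **flags}
        rec["cci"] = cci_score(flags)
        rec["n_baseline_comedications"] = count_baseline_comedications(
            rx_by_patient.get(row.patient_id, []), index_month, config
        )
        rec["hcv_severity"] = classify_hcv_severity(baseline_codes, severity_map)
        rec["bed_category"] = bed_category
        rec["cancer_hub"] = cancer_hub
        records.append(rec)
    return pd.DataFrame(records, columns=COVARIATE_COLUMNS)
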