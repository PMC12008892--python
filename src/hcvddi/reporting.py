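"""Descriptive tables, attrition flow, and the end-to-end pipeline driver.

Formatting conventions: percentages are rendered to one decimal with
half-up rounding against the group total as denominator; continuous
variables are summarized as mean (sample SD) and median (IQR, Q3 - Q1 with
linear interpolation).  No inferential statistics are produced — the
analysis is descriptive.

Tables emitted (named after their content):

* ``characteristics`` — baseline characteristics by group
* ``ddi`` — any-DDI and two-or-more-DDI counts by group
* ``potential_ddi`` — package-insert-silent but checker-flagged comedications
* ``ddi_severity`` — the mutually exclusive severity partition
* ``red_details`` — per-ingredient contraindicated tallies (zeros retained)
* ``ddi_stratified`` — DDI counts by common comorbidities and HCV severity
* ``drug_details`` — per-drug counts with severity and drug class
"""
from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .assessment import assess_cohort, tally_red_drugs
from .claims import ClaimsBundle, read_claims_bundle
from .cohort import CohortResult, build_cohort, format_attrition
from .config import StudyConfig, load_study_config
from .covariates import (
    COMORBIDITY_CATEGORIES,
    HCV_SEVERITY_LEVELS,
    build_covariates,
)
from .episodes import build_episodes
from .knowledge import KnowledgeBase, Severity, load_knowledge_base

GROUP_ORDER = ["SOF/VEL", "GLE/PIB"]

#: comorbidities used for the stratified DDI table
STRATIFICATION_COMORBIDITIES = [
    "congestive_heart_failure",
    "cerebrovascular_disease",
    "chronic_pulmonary_disease",
    "peptic_ulcer_disease",
    "any_malignancy",
]

AGE_CATEGORIES = [("18-39", 18, 39), ("40-64", 40, 64), ("65-74", 65, 74), ("75-", 75, 200)]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(numerator: int, denominator: int) -> str:
    """``100 * numerator / denominator`` rounded half-up to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return str(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_continuous(values) -> dict[str, Optional[float]]:
    """Mean/SD (sample SD, n-1) and median/IQR (linear-interpolation quantiles)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty collection")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else None
    return {
        "n": int(arr.size),
        "mean": float(np.mean(arr)),
        "sd": sd,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(q3 - q1),
    }


# ---------------------------------------------------------------------------
# table builders


def _strata(cohort: pd.DataFrame) -> list[tuple[str, pd.Series]]:
    """(name, boolean mask) for overall and each regimen group."""
    out = [("Overall", pd.Series(True, index=cohort.index))]
    for group in GROUP_ORDER:
        out.append((group, cohort["group"] == group))
    return out


def _count_row(table: str, stratum: str, label: str, n: int, den: int) -> dict:
    return {
        "table": table, "stratum": stratum, "label": label,
        "n": n, "denominator": den,
        "pct": format_percent(n, den) if den > 0 else "",
    }


def table_characteristics(
    cohort: pd.DataFrame, covariates: pd.DataFrame, episodes: pd.DataFrame
) -> pd.DataFrame:
    """Baseline-characteristics table by group (counts, means, medians)."""
    merged = cohort.merge(covariates, on="patient_id").merge(
        episodes[["patient_id", "followup_end"]], on="patient_id"
    )
    merged["observation_days"] = [
        (fu - ix).days + 1
        for fu, ix in zip(merged["followup_end"], merged["index_date"])
    ]
    rows = []
    for stratum, mask in _strata(merged):
        sub = merged[mask]
        den = len(sub)
        rows.append({"table": "characteristics", "stratum": stratum,
                     "label": "total", "n": den, "denominator": den, "pct": ""})
        if den == 0:
            continue
        age = summarize_continuous(sub["age_at_index"])
        rows.append({"table": "characteristics", "stratum": stratum,
                     "label": "age_mean_sd", "mean": age["mean"], "sd": age["sd"],
                     "denominator": den})
        for label, lo, hi in AGE_CATEGORIES:
            n = int(((sub["age_at_index"] >= lo) & (sub["age_at_index"] <= hi)).sum())
            rows.append(_count_row("characteristics", stratum, f"age_{label}", n, den))
        for sex in ("male", "female"):
            rows.append(_count_row(
                "characteristics", stratum, f"sex_{sex}",
                int((sub["sex"] == sex).sum()), den,
            ))
        obs = summarize_continuous(sub["observation_days"])
        rows.append({"table": "characteristics", "stratum": stratum,
                     "label": "observation_days_median_iqr",
                     "median": obs["median"], "iqr": obs["iqr"], "denominator": den})
        for cat in COMORBIDITY_CATEGORIES:
            rows.append(_count_row(
                "characteristics", stratum, cat, int(sub[cat].sum()), den
            ))
        cci = summarize_continuous(sub["cci"])
        rows.append({"table": "characteristics", "stratum": stratum,
                     "label": "cci_median_iqr", "median": cci["median"],
                     "iqr": cci["iqr"], "denominator": den})
        meds = summarize_continuous(sub["n_baseline_comedications"])
        rows.append({"table": "characteristics", "stratum": stratum,
                     "label": "baseline_comedications_median_iqr",
                     "median": meds["median"], "iqr": meds["iqr"], "denominator": den})
        for bed in sub["bed_category"].value_counts().sort_index().index:
            rows.append(_count_row(
                "characteristics", stratum, f"beds_{bed}",
                int((sub["bed_category"] == bed).sum()), den,
            ))
        rows.append(_count_row(
            "characteristics", stratum, "cancer_hub",
            int(sub["cancer_hub"].sum()), den,
        ))
        for level in HCV_SEVERITY_LEVELS:
            rows.append(_count_row(
                "characteristics", stratum, f"hcv_{level}",
                int((sub["hcv_severity"] == level).sum()), den,
            ))
    return pd.DataFrame(rows)


def table_ddi(ddi_results: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for stratum, mask in _strata(ddi_results):
        sub = ddi_results[mask]
        den = len(sub)
        rows.append({"table": "ddi", "stratum": stratum, "label": "total",
                     "n": den, "denominator": den, "pct": ""})
        if den == 0:
            continue
        rows.append(_count_row("ddi", stratum, "ddi", int(sub["has_ddi"].sum()), den))
        rows.append(_count_row(
            "ddi", stratum, "ddi_ge2_medications", int(sub["has_ddi_ge2"].sum()), den
        ))
    return pd.DataFrame(rows)


def table_potential_ddi(ddi_results: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for stratum, mask in _strata(ddi_results):
        sub = ddi_results[mask]
        den = len(sub)
        rows.append({"table": "potential_ddi", "stratum": stratum, "label": "total",
                     "n": den, "denominator": den, "pct": ""})
        if den == 0:
            continue
        rows.append(_count_row(
            "potential_ddi", stratum, "potential_ddi",
            int(sub["has_potential"].sum()), den,
        ))
    return pd.DataFrame(rows)


def table_severity(ddi_results: pd.DataFrame) -> pd.DataFrame:
    """Mutually exclusive severity partition; rows sum to the group total."""
    labels = [
        ("red", "contraindication_red"),
        ("amber", "potential_clinically_significant_amber"),
        ("yellow", "weak_interaction_yellow"),
        ("none", "no_ddi"),
    ]
    rows = []
    for stratum, mask in _strata(ddi_results):
        sub = ddi_results[mask]
        den = len(sub)
        rows.append({"table": "ddi_severity", "stratum": stratum, "label": "total",
                     "n": den, "denominator": den, "pct": ""})
        if den == 0:
            continue
        for value, label in labels:
            rows.append(_count_row(
                "ddi_severity", stratum, label,
                int((sub["severity"] == value).sum()), den,
            ))
    return pd.DataFrame(rows)


def table_red_details(ddi_results: pd.DataFrame, kb: KnowledgeBase) -> pd.DataFrame:
    """Per-ingredient contraindicated tallies per regimen, zero rows retained."""
    frames = []
    for regimen in GROUP_ORDER:
        tally = tally_red_drugs(ddi_results, kb, regimen)
        den = int((ddi_results["group"] == regimen).sum())
        tally["denominator"] = den
        tally["pct"] = [
            format_percent(n, den) if den > 0 else "" for n in tally["n_patients"]
        ]
        frames.append(tally)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "table", "red_details")
    return out


def table_stratified(
    ddi_results: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """DDI counts stratified by common comorbidities (with/without) and HCV type."""
    merged = ddi_results.merge(covariates, on="patient_id")
    rows = []

    def emit(variable: str, level: str, sub: pd.DataFrame) -> None:
        for stratum, mask in _strata(sub):
            part = sub[mask]
            den = len(part)
            base = {"table": "ddi_stratified", "variable": variable, "level": level,
                    "stratum": stratum}
            rows.append({**base, "label": "total", "n": den, "denominator": den,
                         "pct": ""})
            if den == 0:
                continue
            rows.append({**base, **_count_row(
                "ddi_stratified", stratum, "ddi", int(part["has_ddi"].sum()), den
            )})
            rows.append({**base, **_count_row(
                "ddi_stratified", stratum, "ddi_ge2_medications",
                int(part["has_ddi_ge2"].sum()), den,
            )})

    for comorbidity in STRATIFICATION_COMORBIDITIES:
        emit(comorbidity, "with", merged[merged[comorbidity]])
        emit(comorbidity, "without", merged[~merged[comorbidity]])
    for level in HCV_SEVERITY_LEVELS:
        emit("hcv_severity", level, merged[merged["hcv_severity"] == level])
    return pd.DataFrame(rows)


def table_drug_details(ddi_results: pd.DataFrame, kb: KnowledgeBase) -> pd.DataFrame:
    """Per-drug patient counts with severity grade and drug class, per regimen."""
    rows = []
    for regimen in GROUP_ORDER:
        group = ddi_results[ddi_results["group"] == regimen]
        den = len(group)
        comed_sets = [
            set(c.split(";")) if c else set() for c in group["comedications"]
        ]
        for entry in kb.entries_for(regimen):
            cls = kb.classify(regimen, entry.ingredient)
            n = sum(entry.ingredient in s for s in comed_sets)
            rows.append({
                "table": "drug_details", "regimen": regimen,
                "drug_class": entry.drug_class, "ingredient": entry.ingredient,
                "severity": cls.severity.label, "n_patients": n,
                "denominator": den,
                "pct": format_percent(n, den) if den > 0 else "",
            })
    return pd.DataFrame(rows)


def build_all_tables(
    cohort: pd.DataFrame,
    covariates: pd.DataFrame,
    episodes: pd.DataFrame,
    ddi_results: pd.DataFrame,
    kb: KnowledgeBase,
) -> dict[str, pd.DataFrame]:
    return {
        "characteristics": table_characteristics(cohort, covariates, episodes),
        "ddi": table_ddi(ddi_results),
        "potential_ddi": table_potential_ddi(ddi_results),
        "ddi_severity": table_severity(ddi_results),
        "red_details": table_red_details(ddi_results, kb),
        "ddi_stratified": table_stratified(ddi_results, covariates),
        "drug_details": table_drug_details(ddi_results, kb),
    }


def render_tables(tables: dict[str, pd.DataFrame]) -> str:
    """Human-readable text rendering of every table."""
    blocks = []
    for name, df in tables.items():
        blocks.append(f"== {name} ==")
        blocks.append(df.to_string(index=False))
        blocks.append("")
    return "\n".join(blocks)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    attrition: pd.DataFrame
    removed: pd.DataFrame
    episodes: pd.DataFrame
    covariates: pd.DataFrame
    ddi_results: pd.DataFrame
    tables: dict[str, pd.DataFrame]


def run_pipeline_frames(
    bundle: ClaimsBundle,
    kb: KnowledgeBase,
    config: StudyConfig,
) -> PipelineResult:
    """Execute cohort -> episodes -> covariates -> assessment -> tables in memory."""
    result: CohortResult = build_cohort(bundle, config)
    episodes = build_episodes(result.cohort, bundle, config)
    covariates = build_covariates(result.cohort, bundle, config)
    ddi_results = assess_cohort(result.cohort, episodes, bundle, kb, config)
    tables = build_all_tables(result.cohort, covariates, episodes, ddi_results, kb)
    return PipelineResult(
        result.cohort, result.attrition, result.removed,
        episodes, covariates, ddi_results, tables,
    )


def _write_dates(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].map(lambda v: isinstance(v, dt.date)).any():
            out[col] = [
                v.isoformat() if isinstance(v, dt.date) else v for v in out[col]
            ]
    return out


def run_pipeline(
    claims_dir: str | Path,
    kb_path: Optional[str | Path],
    study_config: Optional[str | Path | StudyConfig],
    out_dir: str | Path,
) -> PipelineResult:
    """Read inputs, run every stage, and write all artifacts to *out_dir*.

    Deterministic for fixed inputs: running twice produces byte-identical
    files.
    """
    if isinstance(study_config, StudyConfig):
        config = study_config
    else:
        config = load_study_config(study_config)
    bundle = read_claims_bundle(claims_dir, config)
    kb = load_knowledge_base(kb_path)
    result = run_pipeline_frames(bundle, kb, config)

    out_dir = Path(out_dir)
    tables_dir = out_dir / "tables"
    tables_dir.mkdir(parents=True, exist_ok=True)
    _write_dates(result.cohort).to_csv(out_dir / "cohort.csv", index=False)
    result.attrition.to_csv(out_dir / "attrition.csv", index=False)
    result.removed.to_csv(out_dir / "removed.csv", index=False)
    _write_dates(result.episodes).to_csv(out_dir / "episodes.csv", index=False)
    result.covariates.to_csv(out_dir / "covariates.csv", index=False)
    result.ddi_results.to_csv(out_dir / "ddi_results.csv", index=False)
    for name, df in result.tables.items():
        df.to_csv(tables_dir / f"{name}.csv", index=False)
    (out_dir / "report.txt").write_text(
        format_attrition(result.attrition) + "\n\n" + render_tables(result.tables),
        encoding="utf-8",
    )
    config_hash = hashlib.sha256(
        json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    ).hexdigest()[:16]
    log_lines = [
        f"config_hash: {config_hash}",
        f"claims_dir: {Path(claims_dir).name}",
        f"n_patients_input: {bundle.n_patients}",
        f"n_index_events: {int(result.attrition.iloc[0]['n_remaining'])}",
        f"n_cohort: {len(result.cohort)}",
        f"n_prescriptions: {len(bundle.prescriptions)}",
        f"n_diagnoses: {len(bundle.diagnoses)}",
    ]
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return result
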