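"""Generator determinism, planted structure, and parameter recovery."""
import filecmp

import numpy as np
import pytest
from scipy import stats

from hcvddi.claims import write_claims_bundle
from hcvddi.config import StudyConfig
from hcvddi.knowledge import load_knowledge_base
from hcvddi.reporting import run_pipeline_frames
from hcvddi.simulate import (
    SimulationConfig,
    generate,
    implied_ddi_prevalence,
    read_truth,
    write_truth,
)


def clopper_pearson(k: int, n: int, alpha: float = 0.05):
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return lo, hi


def test_seeded_determinism_is_byte_identical(tmp_path):
    for run in ("a", "b"):
        bundle, truth = generate(SimulationConfig(n_patients=100, seed=7))
        write_claims_bundle(bundle, tmp_path / run)
        write_truth(truth, tmp_path / run / "truth.csv")
    for path in (tmp_path / "a").glob("*.csv"):
        assert filecmp.cmp(path, tmp_path / "b" / path.name, shallow=False), path.name


def test_forced_ineligibility_by_age():
    sim = SimulationConfig(
        n_patients=50, seed=3, fraction_ineligible={"age": 1.0}
    )
    bundle, truth = generate(sim)
    assert not any(truth["true_included"])
    assert set(truth["exclusion_reason"]) == {"age"}
    study = StudyConfig()
    for row in bundle.patients.itertuples(index=False):
        index = truth.set_index("patient_id").loc[row.patient_id, "true_index_date"]
        from hcvddi.config import age_at

        assert age_at(row.birth_date, index) < study.min_age_years


def test_truth_round_trip(tmp_path):
    _, truth = generate(SimulationConfig(n_patients=60, seed=9))
    write_truth(truth, tmp_path / "truth.csv")
    assert read_truth(tmp_path / "truth.csv").equals(truth)


def test_empty_truth_round_trip(tmp_path):
    import pandas as pd

    from hcvddi.simulate import TRUTH_COLUMNS

    empty = pd.DataFrame({c: pd.Series(dtype=object) for c in TRUTH_COLUMNS})
    write_truth(empty, tmp_path / "truth.csv")
    out = read_truth(tmp_path / "truth.csv")
    assert out.empty and list(out.columns) == TRUTH_COLUMNS


def test_infeasible_duration_rejected():
    sim = SimulationConfig(
        treatment_duration_weeks={
            "SOF/VEL": {1000: 1.0}, "GLE/PIB": {8: 0.6, 12: 0.4},
        }
    )
    with pytest.raises(ValueError, match="exceeds"):
        generate(sim)


def test_unreachable_severity_category_rejected():
    with pytest.raises(ValueError, match="others"):
        SimulationConfig(
            hcv_severity_mix={
                "SOF/VEL": {"decompensated_cirrhosis": 0.2,
                            "compensated_cirrhosis": 0.1,
                            "chronic_hepatitis_c": 0.5, "others": 0.2},
                "GLE/PIB": {"decompensated_cirrhosis": 0.003,
                            "compensated_cirrhosis": 0.033,
                            "chronic_hepatitis_c": 0.964, "others": 0.0},
            }
        )


def test_group_share_matches_configured_probability():
    """At the published cohort size the SOF/VEL share sits in the exact
    binomial CI of the configured assignment probability."""
    sim = SimulationConfig(n_patients=7338, seed=21)
    _, truth = generate(sim)
    k = int((truth["true_group"] == "SOF/VEL").sum())
    lo, hi = clopper_pearson(k, len(truth))
    assert lo <= sim.p_sofvel <= hi


def test_pipeline_recovers_planted_truth_small():
    bundle, truth = generate(SimulationConfig(n_patients=500, seed=13))
    result = run_pipeline_frames(bundle, load_knowledge_base(), StudyConfig())
    truth_i = truth.set_index("patient_id")
    included_truth = set(truth_i[truth_i["true_included"] == True].index)  # noqa: E712
    assert set(result.cohort["patient_id"]) == included_truth
    removed = dict(zip(result.removed["patient_id"], result.removed["reason"]))
    for pid, reason in removed.items():
        assert truth_i.loc[pid, "exclusion_reason"] == reason
    episodes = result.episodes.set_index("patient_id")
    ddi = result.ddi_results.set_index("patient_id")
    for pid in included_truth:
        assert episodes.loc[pid, "index_date"] == truth_i.loc[pid, "true_index_date"]
        assert episodes.loc[pid, "followup_end"] == truth_i.loc[pid, "true_followup_end"]
        assert episodes.loc[pid, "end_reason"] == truth_i.loc[pid, "true_end_reason"]
        assert ddi.loc[pid, "has_ddi"] == truth_i.loc[pid, "true_has_ddi"]
        assert ddi.loc[pid, "n_ddi_meds"] == truth_i.loc[pid, "true_n_ddi_meds"]
        assert ddi.loc[pid, "severity"] == truth_i.loc[pid, "true_severity"]
        assert ddi.loc[pid, "has_potential"] == truth_i.loc[pid, "true_has_potential"]
        assert ddi.loc[pid, "comedications"] == truth_i.loc[pid, "true_comedications"]


def test_comorbidity_prevalence_recovery():
    """Cohort comorbidity rates sit inside the exact binomial CI of the
    configured per-category prevalence (GLE/PIB group, a few categories)."""
    sim = SimulationConfig(n_patients=2500, seed=29)
    bundle, _ = generate(sim)
    result = run_pipeline_frames(bundle, load_knowledge_base(), StudyConfig())
    merged = result.cohort.merge(result.covariates, on="patient_id")
    sub = merged[merged["group"] == "GLE/PIB"]
    n = len(sub)
    for category in ["congestive_heart_failure", "peptic_ulcer_disease",
                     "any_malignancy", "renal_disease"]:
        k = int(sub[category].sum())
        lo, hi = clopper_pearson(k, n)
        assert lo <= sim.comorbidity_prevalences["GLE/PIB"][category] <= hi, category


def test_implied_ddi_prevalence_formula(kb):
    sim = SimulationConfig()
    p = implied_ddi_prevalence(sim, kb, "SOF/VEL")
    manual = 1.0
    for ing, prob in sim.comedication_prevalences["SOF/VEL"].items():
        if kb.classify("SOF/VEL", ing).is_ddi:
            manual *= 1 - prob
    assert p == pytest.approx(1 - manual)
    assert 0 < p < 1
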