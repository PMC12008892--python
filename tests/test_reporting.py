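"""Formatting conventions, table invariants, and pipeline determinism."""
import filecmp

import numpy as np
import pandas as pd
import pytest

from hcvddi.claims import write_claims_bundle
from hcvddi.knowledge import load_knowledge_base
from hcvddi.reporting import (
    format_percent,
    round_half_up,
    run_pipeline,
    run_pipeline_frames,
    summarize_continuous,
)
from hcvddi.simulate import SimulationConfig, generate


@pytest.mark.parametrize(
    "num,den,expected",
    [(277, 467, "59.3"), (115, 6871, "1.7"), (0, 467, "0.0"),
     (66, 467, "14.1"), (1648, 6871, "24.0"), (68, 467, "14.6")],
)
def test_format_percent(num, den, expected):
    assert format_percent(num, den) == expected


def test_format_percent_zero_denominator():
    with pytest.raises(ValueError):
        format_percent(1, 0)


def test_half_up_rounding_of_exact_ties():
    assert format_percent(1, 8) == "12.5"
    assert format_percent(5, 8) == "62.5"
    assert format_percent(25, 1000) == "2.5"   # 2.5 exactly
    assert format_percent(35, 1000) == "3.5"
    assert round_half_up(0.25, 1) == 0.3       # half rounds up, not to even
    assert round_half_up(0.35, 1) == 0.4


def test_summarize_continuous():
    s = summarize_continuous([1, 2, 3, 4, 5])
    assert s["median"] == 3.0 and s["iqr"] == 2.0
    assert s["mean"] == 3.0
    assert s["sd"] == pytest.approx(np.std([1, 2, 3, 4, 5], ddof=1))
    single = summarize_continuous([7])
    assert single["mean"] == 7.0 and single["sd"] is None
    const = summarize_continuous([4, 4, 4])
    assert const["sd"] == 0.0 and const["iqr"] == 0.0
    with pytest.raises(ValueError):
        summarize_continuous([])


@pytest.fixture(scope="module")
def small_run():
    bundle, truth = generate(SimulationConfig(n_patients=400, seed=17))
    kb = load_knowledge_base()
    from hcvddi.config import StudyConfig

    return run_pipeline_frames(bundle, kb, StudyConfig()), truth


def test_severity_partition_sums_to_group_totals(small_run):
    result, _ = small_run
    table = result.tables["ddi_severity"]
    for stratum in table["stratum"].unique():
        sub = table[table["stratum"] == stratum]
        total = sub[sub["label"] == "total"]["n"].iloc[0]
        parts = sub[sub["label"] != "total"]["n"].sum()
        assert parts == total


def test_stratified_with_without_complement(small_run):
    result, _ = small_run
    table = result.tables["ddi_stratified"]
    group_totals = result.tables["ddi"]
    for variable in table["variable"].unique():
        if variable == "hcv_severity":
            continue
        sub = table[(table["variable"] == variable) & (table["label"] == "total")]
        for stratum in ("Overall", "SOF/VEL", "GLE/PIB"):
            parts = sub[sub["stratum"] == stratum]["n"].sum()
            total = group_totals[
                (group_totals["stratum"] == stratum)
                & (group_totals["label"] == "total")
            ]["n"].iloc[0]
            assert parts == total, (variable, stratum)


def test_every_printed_percentage_is_self_consistent(small_run):
    """Audit: each pct cell equals format_percent(n, denominator)."""
    result, _ = small_run
    for name, table in result.tables.items():
        if "pct" not in table.columns:
            continue
        for row in table.itertuples(index=False):
            pct = getattr(row, "pct", "")
            if not isinstance(pct, str) or pct == "":
                continue
            n = getattr(row, "n", None)
            if n is None or (isinstance(n, float) and np.isnan(n)):
                n = getattr(row, "n_patients")
            assert pct == format_percent(int(n), int(row.denominator)), (name, row)


def test_pipeline_writes_all_artifacts_and_is_deterministic(tmp_path):
    bundle, _ = generate(SimulationConfig(n_patients=120, seed=42))
    claims_dir = tmp_path / "claims"
    write_claims_bundle(bundle, claims_dir)
    out1, out2 = tmp_path / "run1", tmp_path / "run2"
    run_pipeline(claims_dir, None, None, out1)
    run_pipeline(claims_dir, None, None, out2)
    expected = [
        "cohort.csv", "attrition.csv", "removed.csv", "episodes.csv",
        "covariates.csv", "ddi_results.csv", "report.txt", "run.log",
    ]
    for name in expected:
        assert (out1 / name).exists(), name
        assert filecmp.cmp(out1 / name, out2 / name, shallow=False), name
    for name in ["characteristics", "ddi", "potential_ddi", "ddi_severity",
                 "red_details", "ddi_stratified", "drug_details"]:
        path1 = out1 / "tables" / f"{name}.csv"
        assert path1.exists(), name
        assert filecmp.cmp(path1, out2 / "tables" / f"{name}.csv", shallow=False)


def test_attrition_csv_consistent_with_cohort(tmp_path):
    bundle, _ = generate(SimulationConfig(n_patients=150, seed=5))
    claims_dir = tmp_path / "claims"
    write_claims_bundle(bundle, claims_dir)
    result = run_pipeline(claims_dir, None, None, tmp_path / "out")
    att = pd.read_csv(tmp_path / "out" / "attrition.csv")
    assert att["n_remaining"].iloc[-1] == len(result.cohort)
    assert att["n_remaining"].iloc[0] - att["n_removed"].sum() == len(result.cohort)
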