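import datetime as dt

import pandas as pd
import pytest

from hcvddi.claims import ClaimsBundle, TABLE_COLUMNS, _coerce_types
from hcvddi.config import StudyConfig
from hcvddi.knowledge import load_knowledge_base


def make_bundle(
    patients=(), enrollment=(), diagnoses=(), prescriptions=(), procedures=(),
    facilities=(),
) -> ClaimsBundle:
    """Build a bundle from row dicts, filling schema columns."""
    defaults = {
        "facilities": [{"facility_id": "F1", "bed_category": ">=500", "cancer_hub": True}],
    }
    raw = {
        "patients": list(patients),
        "enrollment": list(enrollment),
        "diagnoses": list(diagnoses),
        "prescriptions": list(prescriptions),
        "procedures": list(procedures),
        "facilities": list(facilities) or defaults["facilities"],
    }
    tables = {}
    for name, rows in raw.items():
        df = pd.DataFrame(rows, columns=TABLE_COLUMNS[name])
        tables[name] = _coerce_types(name, df) if len(df) else _coerce_types(
            name, pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_COLUMNS[name]})
        )
    return ClaimsBundle(**tables)


def rx(pid, date, ingredient="glecaprevir/pibrentasvir", atc="J05AP57",
       supply=28, facility="F1"):
    return {
        "patient_id": pid, "ingredient": ingredient, "atc_code": atc,
        "prescription_date": date, "days_supply": supply, "facility_id": facility,
    }


@pytest.fixture(scope="session")
def study():
    return StudyConfig()


@pytest.fixture(scope="session")
def kb():
    return load_knowledge_base()


@pytest.fixture
def tiny_bundle():
    """Three hand-made patients: one eligible, one under-age, one transplanted."""
    return make_bundle(
        patients=[
            {"patient_id": "P1", "birth_date": dt.date(1950, 3, 15), "sex": "female"},
            {"patient_id": "P2", "birth_date": dt.date(2002, 1, 1), "sex": "male"},
            {"patient_id": "P3", "birth_date": dt.date(1948, 7, 2), "sex": "male"},
        ],
        enrollment=[
            {"patient_id": "P1", "start_date": dt.date(2017, 1, 1),
             "end_date": dt.date(2024, 12, 31), "insurer_type": "NHI"},
            {"patient_id": "P2", "start_date": dt.date(2017, 1, 1),
             "end_date": dt.date(2024, 12, 31), "insurer_type": "SHI"},
            {"patient_id": "P3", "start_date": dt.date(2017, 1, 1),
             "end_date": dt.date(2024, 12, 31), "insurer_type": "LSEHS"},
        ],
        diagnoses=[
            {"patient_id": "P1", "icd10_code": "B18.2", "year_month": "2018-05"},
            {"patient_id": "P2", "icd10_code": "B18.2", "year_month": "2018-05"},
            {"patient_id": "P3", "icd10_code": "B18.2", "year_month": "2018-05"},
        ],
        prescriptions=[
            rx("P1", dt.date(2018, 5, 10)),
            rx("P1", dt.date(2018, 6, 7)),
            rx("P2", dt.date(2018, 5, 10)),
            rx("P3", dt.date(2018, 5, 10)),
        ],
        procedures=[
            {"patient_id": "P3", "procedure_code": "K697-7",
             "date": dt.date(2018, 3, 26)},
        ],
    )
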