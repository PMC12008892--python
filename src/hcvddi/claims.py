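"""The six-table claims data model and its delimited-file reader/writer.

A :class:`ClaimsBundle` holds the whole dataset as pandas DataFrames:
patients, enrollment intervals, month-granular diagnoses, day-granular
prescriptions and procedures, and facilities.  Files are UTF-8 CSV with a
header row, ISO-8601 dates (``YYYY-MM-DD``) and months (``YYYY-MM``); in
memory, date columns hold :class:`datetime.date` objects.

Validation enforces the structural invariants a downstream analysis relies
on: unique patient and facility ids, non-overlapping enrollment intervals,
positive days' supply, event dates inside the study period, and referential
integrity of every foreign key.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional

import pandas as pd

from .config import StudyConfig, month_of, parse_month

SEXES = ("male", "female")
INSURER_TYPES = ("SHI", "NHI", "LSEHS")
BED_CATEGORIES = (
    "unknown", "<20", "20-99", "100-199", "200-299", "300-399", "400-500", ">=500",
)

#: table name -> ordered column list (also the on-disk schema)
TABLE_COLUMNS = {
    "patients": ["patient_id", "birth_date", "sex"],
    "enrollment": ["patient_id", "start_date", "end_date", "insurer_type"],
    "diagnoses": ["patient_id", "icd10_code", "year_month"],
    "prescriptions": [
        "patient_id", "ingredient", "atc_code", "prescription_date",
        "days_supply", "facility_id",
    ],
    "procedures": ["patient_id", "procedure_code", "date"],
    "facilities": ["facility_id", "bed_category", "cancer_hub"],
}

_DATE_COLUMNS = {
    "patients": ["birth_date"],
    "enrollment": ["start_date", "end_date"],
    "prescriptions": ["prescription_date"],
    "procedures": ["date"],
}


class ClaimsValidationError(ValueError):
    """A claims table violates its schema or an invariant."""


@dataclass
class ClaimsBundle:
    patients: pd.DataFrame
    enrollment: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    procedures: pd.DataFrame
    facilities: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def equals(self, other: "ClaimsBundle") -> bool:
        return all(
            self.tables()[name].reset_index(drop=True).equals(
                other.tables()[name].reset_index(drop=True)
            )
            for name in TABLE_COLUMNS
        )


def empty_bundle() -> ClaimsBundle:
    tables = {}
    for name, cols in TABLE_COLUMNS.items():
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
        tables[name] = _coerce_types(name, df)
    return ClaimsBundle(**tables)


def _coerce_types(name: str, df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if name == "prescriptions":
        df["days_supply"] = df["days_supply"].astype("int64")
    if name == "facilities":
        df["cancer_hub"] = df["cancer_hub"].astype(bool)
    return df


def _parse_date(value: str, table: str, column: str, row: int) -> dt.date:
    try:
        return dt.date.fromisoformat(value)
    except ValueError:
        raise ClaimsValidationError(
            f"{table}: row {row}, column {column}: invalid date {value!r}"
        ) from None


def read_claims_bundle(
    directory: str | Path, config: Optional[StudyConfig] = None
) -> ClaimsBundle:
    """Read and validate the six claims tables from *directory*.

    Raises :class:`ClaimsValidationError` naming the file, row and column on
    any schema violation, and listing orphan ids on referential-integrity
    failures.
    """
    directory = Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    for name, cols in TABLE_COLUMNS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise ClaimsValidationError(f"missing claims file: {path.name}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if list(df.columns) != cols:
            raise ClaimsValidationError(
                f"{name}: expected columns {cols}, found {list(df.columns)}"
            )
        for col in _DATE_COLUMNS.get(name, []):
            df[col] = pd.Series(
                [_parse_date(v, name, col, i) for i, v in enumerate(df[col])],
                dtype=object,
                index=df.index,
            )
        if name == "prescriptions":
            supplies = []
            for i, v in enumerate(df["days_supply"]):
                try:
                    supplies.append(int(v))
                except ValueError:
                    raise ClaimsValidationError(
                        f"prescriptions: row {i}, column days_supply: "
                        f"not an integer: {v!r}"
                    ) from None
            df["days_supply"] = supplies
        if name == "facilities":
            hubs = []
            for i, v in enumerate(df["cancer_hub"]):
                if v not in ("True", "False"):
                    raise ClaimsValidationError(
                        f"facilities: row {i}, column cancer_hub: {v!r} "
                        "is not True/False"
                    )
                hubs.append(v == "True")
            df["cancer_hub"] = hubs
        tables[name] = _coerce_types(name, df)
    bundle = ClaimsBundle(**tables)
    validate_bundle(bundle, config)
    return bundle


def write_claims_bundle(bundle: ClaimsBundle, directory: str | Path) -> list[Path]:
    """Write the six tables as CSV; ``read_claims_bundle`` round-trips them."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, cols in TABLE_COLUMNS.items():
        df = bundle.tables()[name].copy()
        for col in _DATE_COLUMNS.get(name, []):
            df[col] = [d.isoformat() for d in df[col]]
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# validation


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ClaimsValidationError(message)


def validate_bundle(bundle: ClaimsBundle, config: Optional[StudyConfig] = None) -> None:
    """Check every invariant of the bundle; raise on the first violation."""
    cfg = config or StudyConfig()

    pat = bundle.patients
    dup = pat["patient_id"][pat["patient_id"].duplicated()]
    _require(dup.empty, f"patients: duplicated patient_id: {sorted(set(dup))}")
    for i, row in enumerate(pat.itertuples(index=False)):
        _require(
            row.birth_date < cfg.study_end,
            f"patients: row {i}: birth_date {row.birth_date} not before study end",
        )
        _require(row.sex in SEXES, f"patients: row {i}: invalid sex {row.sex!r}")

    enr = bundle.enrollment
    for i, row in enumerate(enr.itertuples(index=False)):
        _require(
            row.start_date <= row.end_date,
            f"enrollment: row {i}: start_date after end_date",
        )
        _require(
            row.insurer_type in INSURER_TYPES,
            f"enrollment: row {i}: invalid insurer_type {row.insurer_type!r}",
        )
    for pid, grp in enr.groupby("patient_id", sort=False):
        spans = sorted(zip(grp["start_date"], grp["end_date"]))
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            _require(
                e1 < s2,
                f"enrollment: overlapping intervals for patient {pid}",
            )

    start_month = parse_month(month_of(cfg.study_start))
    end_month = parse_month(month_of(cfg.study_end))
    dx = bundle.diagnoses
    for i, row in enumerate(dx.itertuples(index=False)):
        _require(bool(row.icd10_code), f"diagnoses: row {i}: empty icd10_code")
        try:
            ym = parse_month(row.year_month)
        except ValueError:
            raise ClaimsValidationError(
                f"diagnoses: row {i}, column year_month: "
                f"invalid month {row.year_month!r}"
            ) from None
        _require(
            start_month <= ym <= end_month,
            f"diagnoses: row {i}: year_month {row.year_month} outside study period",
        )

    rx = bundle.prescriptions
    for i, row in enumerate(rx.itertuples(index=False)):
        _require(
            row.days_supply >= 1,
            f"prescriptions: row {i}, column days_supply: must be >= 1, "
            f"got {row.days_supply}",
        )
        _require(
            cfg.study_start <= row.prescription_date <= cfg.study_end,
            f"prescriptions: row {i}: prescription_date outside study period",
        )

    for i, row in enumerate(bundle.procedures.itertuples(index=False)):
        _require(
            cfg.study_start <= row.date <= cfg.study_end,
            f"procedures: row {i}: date outside study period",
        )

    fac = bundle.facilities
    dup = fac["facility_id"][fac["facility_id"].duplicated()]
    _require(dup.empty, f"facilities: duplicated facility_id: {sorted(set(dup))}")
    for i, row in enumerate(fac.itertuples(index=False)):
        _require(
            row.bed_category in BED_CATEGORIES,
            f"facilities: row {i}: invalid bed_category {row.bed_category!r}",
        )

    # referential integrity
    known_patients = set(pat["patient_id"])
    for name in ("enrollment", "diagnoses", "prescriptions", "procedures"):
        orphans = sorted(set(bundle.tables()[name]["patient_id"]) - known_patients)
        _require(
            not orphans,
            f"{name}: unknown patient ids: {orphans}",
        )
    orphan_fac = sorted(set(rx["facility_id"]) - set(fac["facility_id"]))
    _require(not orphan_fac, f"prescriptions: unknown facility ids: {orphan_fac}")
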