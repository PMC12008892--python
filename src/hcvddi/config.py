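"""Study configuration and calendar arithmetic.

All numeric parameters of the observational design live in
:class:`StudyConfig`: the study and identification periods, the refill grace
period that defines treatment continuity, the pre-index enrollment look-back,
the liver-transplant exclusion window, the minimum age, and the drug codes
identifying the two DAA regimens.

Japanese claims record diagnoses at month granularity, so a few helpers here
work on ``YYYY-MM`` month strings rather than dates.
"""
from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Optional

import yaml
from dateutil.relativedelta import relativedelta
from pydantic import BaseModel, model_validator

#: Normalized ingredient name of each fixed-dose DAA regimen.
REGIMEN_INGREDIENTS = {
    "SOF/VEL": "sofosbuvir/velpatasvir",
    "GLE/PIB": "glecaprevir/pibrentasvir",
}


class StudyConfig(BaseModel):
    """Constants of the new-user cohort design.

    Defaults encode a Japanese claims study of DAA initiation: study period
    January 2017 .. August 2023, patient identification from April 2017 (the
    first months of the database are sparse), a 7-day grace period in the
    refill-gap rule, 3 calendar months of required pre-index enrollment,
    a 90-day transplant exclusion window and adult patients only.
    """

    study_start: dt.date = dt.date(2017, 1, 1)
    study_end: dt.date = dt.date(2023, 8, 31)
    identification_start: dt.date = dt.date(2017, 4, 1)
    identification_end: dt.date = dt.date(2023, 8, 31)
    gap_threshold_days: int = 7
    lookback_months: int = 3
    transplant_window_days: int = 90
    min_age_years: int = 18
    hcv_icd10: str = "B18.2"
    #: regimen name -> WHO ATC code of the fixed-dose combination product
    daa_regimens: dict[str, str] = {"SOF/VEL": "J05AP55", "GLE/PIB": "J05AP57"}
    transplant_procedure_codes: list[str] = ["K697-5", "K697-6", "K697-7"]

    @model_validator(mode="after")
    def _check(self) -> "StudyConfig":
        if not (
            self.study_start
            <= self.identification_start
            <= self.identification_end
            <= self.study_end
        ):
            raise ValueError(
                "require study_start <= identification_start <= "
                "identification_end <= study_end"
            )
        if self.gap_threshold_days < 1:
            raise ValueError("gap_threshold_days must be >= 1")
        if self.lookback_months < 0:
            raise ValueError("lookback_months must be >= 0")
        if self.transplant_window_days < 0:
            raise ValueError("transplant_window_days must be >= 0")
        if not self.daa_regimens:
            raise ValueError("at least one DAA regimen is required")
        return self

    @property
    def daa_atc_codes(self) -> set[str]:
        return set(self.daa_regimens.values())

    def regimen_of_atc(self, atc: str) -> Optional[str]:
        for name, code in self.daa_regimens.items():
            if code == atc:
                return name
        return None


def load_study_config(path: Optional[str | Path] = None) -> StudyConfig:
    """Load a :class:`StudyConfig`, optionally overriding defaults from YAML/JSON.

    The file may specify any subset of fields; missing fields keep their
    defaults.
    """
    if path is None:
        return StudyConfig()
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"study config {path} must be a mapping")
    return StudyConfig(**data)


# ---------------------------------------------------------------------------
# calendar helpers


def month_of(day: dt.date) -> str:
    """``YYYY-MM`` month containing *day*."""
    return f"{day.year:04d}-{day.month:02d}"


def parse_month(month: str) -> tuple[int, int]:
    y, m = month.split("-")
    year, mon = int(y), int(m)
    if not 1 <= mon <= 12:
        raise ValueError(f"invalid month {month!r}")
    return year, mon


def months_before(month: str, k: int) -> str:
    """The calendar month *k* months before *month* (``k >= 0``)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    year, mon = parse_month(month)
    total = year * 12 + (mon - 1) - k
    return f"{total // 12:04d}-{total % 12 + 1:02d}"


def month_first_day(month: str) -> dt.date:
    year, mon = parse_month(month)
    return dt.date(year, mon, 1)


def month_last_day(month: str) -> dt.date:
    year, mon = parse_month(month)
    nxt = dt.date(year + (mon == 12), mon % 12 + 1, 1)
    return nxt - dt.timedelta(days=1)


def age_at(birth_date: dt.date, on_date: dt.date) -> int:
    """Age in completed years (birthday arithmetic, not calendar-year diff)."""
    return relativedelta(on_date, birth_date).years
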