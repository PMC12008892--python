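"""Dual-source drug-interaction knowledge base and severity logic.

Each entry grades one (regimen, ingredient) pair against two sources: the
Japanese package insert (``none`` / ``caution`` / ``contraindicated``) and
the Liverpool hepatitis drug-interaction checker (``not_listed`` /
``no_interaction`` / ``yellow`` / ``amber`` / ``red``).

Classification rules:

* A comedication is a DDI if it carries any Liverpool interaction colour
  (yellow/amber/red) **or** any package-insert flag (union definition).
* Severity: an explicit Liverpool colour wins; otherwise the package insert
  maps ``contraindicated`` -> red and ``caution`` -> amber.  An explicit
  Liverpool ``no_interaction`` listing still yields a DDI with the
  package-insert severity when the insert flags the drug.
* A *potential* DDI is a drug with no package-insert flag that the Liverpool
  checker nonetheless colours — the gap between the two sources.

Severity forms a total order none < yellow < amber < red; a patient on
several interacting drugs is assigned the maximum.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

PI_STATUSES = ("none", "caution", "contraindicated")
LIVERPOOL_STATUSES = ("not_listed", "no_interaction", "yellow", "amber", "red")
REGIMENS = ("SOF/VEL", "GLE/PIB")


class Severity(enum.IntEnum):
    NONE = 0
    YELLOW = 1
    AMBER = 2
    RED = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Severity":
        return cls[label.upper()]


_LIVERPOOL_SEVERITY = {
    "yellow": Severity.YELLOW,
    "amber": Severity.AMBER,
    "red": Severity.RED,
}
_PI_SEVERITY = {
    "none": Severity.NONE,
    "caution": Severity.AMBER,
    "contraindicated": Severity.RED,
}


@dataclass(frozen=True)
class KnowledgeBaseEntry:
    regimen: str
    ingredient: str
    pi_status: str
    liverpool_status: str
    drug_class: str

    def __post_init__(self) -> None:
        if self.regimen not in REGIMENS:
            raise ValueError(f"unknown regimen {self.regimen!r}")
        if self.pi_status not in PI_STATUSES:
            raise ValueError(f"unknown pi_status {self.pi_status!r}")
        if self.liverpool_status not in LIVERPOOL_STATUSES:
            raise ValueError(f"unknown liverpool_status {self.liverpool_status!r}")


@dataclass(frozen=True)
class DDIClassification:
    ingredient: str
    is_ddi: bool
    severity: Severity
    is_potential: bool
    source: str  # liverpool | package_insert | both | none


def classify_entry(entry: Optional[KnowledgeBaseEntry], ingredient: str) -> DDIClassification:
    """Classify one ingredient given its knowledge-base entry (or absence)."""
    if entry is None:
        return DDIClassification(ingredient, False, Severity.NONE, False, "none")
    liverpool_flag = entry.liverpool_status in _LIVERPOOL_SEVERITY
    pi_flag = entry.pi_status != "none"
    if liverpool_flag:
        severity = _LIVERPOOL_SEVERITY[entry.liverpool_status]
    else:
        severity = _PI_SEVERITY[entry.pi_status]
    is_ddi = liverpool_flag or pi_flag
    is_potential = liverpool_flag and not pi_flag
    if liverpool_flag and pi_flag:
        source = "both"
    elif liverpool_flag:
        source = "liverpool"
    elif pi_flag:
        source = "package_insert"
    else:
        source = "none"
    return DDIClassification(ingredient, is_ddi, severity, is_potential, source)


def severity_max(severities: Iterable[Severity]) -> Severity:
    """Maximum severity in the collection; empty input yields ``NONE``."""
    return max(severities, default=Severity.NONE)


class KnowledgeBase:
    """Lookup structure over (regimen, ingredient) interaction entries."""

    def __init__(self, entries: Iterable[KnowledgeBaseEntry]):
        self._entries: list[KnowledgeBaseEntry] = []
        self._index: dict[tuple[str, str], KnowledgeBaseEntry] = {}
        for entry in entries:
            key = (entry.regimen, entry.ingredient)
            if key in self._index:
                raise ValueError(f"duplicate knowledge-base entry {key}")
            self._index[key] = entry
            self._entries.append(entry)

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def entries(self) -> list[KnowledgeBaseEntry]:
        return list(self._entries)

    def entries_for(self, regimen: str) -> list[KnowledgeBaseEntry]:
        return [e for e in self._entries if e.regimen == regimen]

    def get(self, regimen: str, ingredient: str) -> Optional[KnowledgeBaseEntry]:
        return self._index.get((regimen, ingredient))

    def classify(self, regimen: str, ingredient: str) -> DDIClassification:
        """Classify an ingredient against a regimen; absence is a valid outcome."""
        if regimen not in REGIMENS:
            raise ValueError(f"unknown regimen {regimen!r}")
        return classify_entry(self.get(regimen, ingredient), ingredient)

    def red_ingredients(self, regimen: str) -> list[str]:
        """Ingredients that classify as red for *regimen*, in KB order."""
        return [
            e.ingredient
            for e in self.entries_for(regimen)
            if classify_entry(e, e.ingredient).severity is Severity.RED
        ]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.regimen, e.ingredient, e.pi_status, e.liverpool_status, e.drug_class)
                for e in self._entries
            ],
            columns=["regimen", "ingredient", "pi_status", "liverpool_status", "drug_class"],
        )


def bundled_kb_path() -> Path:
    return Path(str(resources.files("hcvddi").joinpath("data/kb.csv")))


def load_knowledge_base(path: Optional[str | Path] = None) -> KnowledgeBase:
    """Load the knowledge base from CSV (the bundled one when *path* is None)."""
    path = Path(path) if path is not None else bundled_kb_path()
    if not path.exists():
        raise FileNotFoundError(f"knowledge base file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["regimen", "ingredient", "pi_status", "liverpool_status", "drug_class"]
    if list(df.columns) != expected:
        raise ValueError(
            f"knowledge base: expected columns {expected}, found {list(df.columns)}"
        )
    entries = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            entries.append(
                KnowledgeBaseEntry(
                    row.regimen, row.ingredient, row.pi_status,
                    row.liverpool_status, row.drug_class,
                )
            )
        except ValueError as exc:
            raise ValueError(f"knowledge base row {i}: {exc}") from None
    return KnowledgeBase(entries)
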