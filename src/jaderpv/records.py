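"""Domain records for spontaneous-reporting-system (SRS) case reports.

The JADER database distributes one safety report as rows in four linkable
tables (DEMO, DRUG, HIST, REAC).  The dataclasses here mirror those rows plus
the fully joined :class:`CaseReport` used by every downstream analysis stage.
Dates in SRS extracts are frequently partial (year only, or year+month), and
the time-to-onset stage relies on knowing completeness, so dates are kept as
:class:`PartialDate` triples rather than being coerced or imputed.
"""

from __future__ import annotations

import datetime as _dt
import enum
import re
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "Sex",
    "AgeBand",
    "Involvement",
    "Outcome",
    "IndicationCategory",
    "OutcomeClass",
    "HazardClass",
    "PartialDate",
    "DemoRecord",
    "DrugRecord",
    "ReacRecord",
    "HistRecord",
    "CaseReport",
    "normalize_name",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    MISSING = "missing"


class AgeBand(str, enum.Enum):
    """Decade age bands as reported by JADER (open-ended at both extremes)."""

    LE_29 = "<=29"
    IN_30S = "30-39"
    IN_40S = "40-49"
    IN_50S = "50-59"
    IN_60S = "60-69"
    IN_70S = "70-79"
    GE_80 = ">=80"
    MISSING = "missing"


class Involvement(str, enum.Enum):
    SUSPECT = "suspect"
    CONCOMITANT = "concomitant"
    INTERACTION = "interaction"


class Outcome(str, enum.Enum):
    DEATH = "death"
    WITH_SEQUELAE = "with_sequelae"
    NOT_RECOVERED = "not_recovered"
    IMPROVED = "improved"
    RECOVERED = "recovered"
    UNKNOWN = "unknown"
    MISSING = "missing"


class IndicationCategory(str, enum.Enum):
    COLORECTAL = "colorectal"
    NSCLC = "nsclc"
    BREAST = "breast"
    MALIGNANT_GLIOMA = "malignant_glioma"
    OVARIAN = "ovarian"
    CERVICAL = "cervical"
    HEPATOCELLULAR = "hepatocellular"
    OTHER = "other"
    NO_ENTRY = "no_entry"


class OutcomeClass(str, enum.Enum):
    IMPROVEMENT = "improvement"
    NO_IMPROVEMENT = "no_improvement"
    EXCLUDED = "excluded"


class HazardClass(str, enum.Enum):
    INITIAL_FAILURE = "initial_failure"
    CONSTANT = "constant"
    WEAR_OUT = "wear_out"


_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Normalize a drug name for exact matching.

    Trims, collapses internal whitespace, and case-folds.  Bracketed salt
    suffixes such as "(genetical recombination)" are deliberately *not*
    stripped: report item labels keep salt forms.
    """
    return _WS.sub(" ", name.strip()).casefold()


@dataclass(frozen=True)
class PartialDate:
    """A possibly incomplete calendar date (year, optional month/day)."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("a day without a month is not a valid partial date")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # Validates day-of-month (raises for e.g. Feb 30).
            _dt.date(self.year, self.month, self.day)

    @property
    def is_complete(self) -> bool:
        return self.month is not None and self.day is not None

    def to_date(self) -> _dt.date:
        if not self.is_complete:
            raise ValueError(f"partial date {self} has no complete day")
        return _dt.date(self.year, self.month, self.day)

    @classmethod
    def parse(cls, text: Optional[str]) -> Optional["PartialDate"]:
        """Parse ``YYYY``, ``YYYYMM``, ``YYYYMMDD`` or separator-delimited
        forms; blank/None yields None."""
        if text is None:
            return None
        s = str(text).strip()
        if not s:
            return None
        parts = re.split(r"[-/.]", s) if re.search(r"[-/.]", s) else None
        try:
            if parts:
                nums = [int(p) for p in parts if p != ""]
                return cls(*nums[:3])
            digits = re.sub(r"\D", "", s)
            if len(digits) == 4:
                return cls(int(digits))
            if len(digits) == 6:
                return cls(int(digits[:4]), int(digits[4:6]))
            if len(digits) == 8:
                return cls(int(digits[:4]), int(digits[4:6]), int(digits[6:8]))
        except ValueError:
            return None
        return None

    def isoformat(self) -> str:
        """Serialize back to the compact JADER form (YYYY / YYYYMM / YYYYMMDD)."""
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"


@dataclass(frozen=True)
class DemoRecord:
    case_id: str
    sex: Sex = Sex.MISSING
    age_band: AgeBand = AgeBand.MISSING
    reporting_year: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")


@dataclass(frozen=True)
class DrugRecord:
    case_id: str
    generic_name: str
    involvement: Involvement
    start_date: Optional[PartialDate] = None
    reason_for_use: str = ""


@dataclass(frozen=True)
class ReacRecord:
    case_id: str
    pt_code: str
    pt_name: str = ""
    outcome: Outcome = Outcome.MISSING
    event_date: Optional[PartialDate] = None


@dataclass(frozen=True)
class HistRecord:
    case_id: str
    primary_disease: str

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")


@dataclass
class CaseReport:
    """One fully joined safety report.

    ``drugs`` and ``reactions`` hold every child row of the case;
    ``suspect_drugs`` restricts to suspect involvement.  ``indications``,
    ``smq_reactions``, ``onset_days`` and ``outcome_class`` are annotations
    added by the extraction / time-to-onset stages.
    """

    case_id: str
    sex: Sex = Sex.MISSING
    age_band: AgeBand = AgeBand.MISSING
    reporting_year: Optional[int] = None
    drugs: list[DrugRecord] = field(default_factory=list)
    reactions: list[ReacRecord] = field(default_factory=list)
    primary_diseases: list[str] = field(default_factory=list)
    indications: frozenset[IndicationCategory] = frozenset()
    smq_reactions: list[ReacRecord] = field(default_factory=list)
    onset_days: Optional[int] = None
    outcome_class: Optional[OutcomeClass] = None

    @property
    def suspect_drugs(self) -> list[DrugRecord]:
        return [d for d in self.drugs if d.involvement is Involvement.SUSPECT]

    def annotated(self, **changes) -> "CaseReport":
        """Return a copy with the given annotation fields replaced."""
        return replace(self, **changes)
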