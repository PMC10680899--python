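"""Core in-memory containers for longitudinal coded EHR data.

The universal input unit is a :class:`PatientRecord`: demographics plus a
date-ordered list of encounters, each carrying coded events (diagnoses,
medications, lab tests with numeric values, demographic codes).  All other
modules consume and produce these containers; on disk they round-trip through
a long-format event table (see :mod:`ehrisk.io`).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional

DAYS_PER_YEAR = 365.25
#: "6 months" in days, used by inclusion criteria.
HALF_YEAR_DAYS = 183

CODE_TYPES = ("DX", "MED", "LAB", "DEMO")


def years_between(start: dt.date, end: dt.date) -> float:
    """Signed elapsed time from *start* to *end* in (fractional) years."""
    return (end - start).days / DAYS_PER_YEAR


def add_years(date: dt.date, years: float) -> dt.date:
    """Shift a date by a (possibly fractional) number of years."""
    return date + dt.timedelta(days=round(years * DAYS_PER_YEAR))


@dataclass(frozen=True)
class CodedEvent:
    """A single coded observation inside an encounter.

    Only LAB events may carry a numeric ``value`` (e.g. an ALT result in
    IU/mL); all other code types carry ``None``.
    """

    code_type: str
    code: str
    value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.code_type not in CODE_TYPES:
            raise ValueError(f"unknown code_type {self.code_type!r}")
        if self.value is not None and self.code_type != "LAB":
            raise ValueError("only LAB events may carry a numeric value")


@dataclass
class Encounter:
    """One dated visit; carries at least one coded event."""

    encounter_id: str
    date: dt.date
    events: list[CodedEvent] = field(default_factory=list)

    def codes(self, code_type: Optional[str] = None) -> list[str]:
        return [
            e.code for e in self.events if code_type is None or e.code_type == code_type
        ]


@dataclass
class PatientRecord:
    """A patient's demographics plus date-ordered encounters."""

    patient_id: str
    sex: str  # "male" | "female"
    birth_date: dt.date
    encounters: list[Encounter] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        self.sort_encounters()

    def sort_encounters(self) -> None:
        self.encounters.sort(key=lambda e: (e.date, e.encounter_id))

    @property
    def first_date(self) -> Optional[dt.date]:
        return self.encounters[0].date if self.encounters else None

    @property
    def last_date(self) -> Optional[dt.date]:
        return self.encounters[-1].date if self.encounters else None

    def span_years(self) -> float:
        """First-to-last encounter duration in years (0 for <2 encounters)."""
        if len(self.encounters) < 2:
            return 0.0
        return years_between(self.first_date, self.last_date)

    def age_at(self, date: dt.date) -> int:
        """Conventional integer age: floor of elapsed years since birth."""
        return int((date - self.birth_date).days // DAYS_PER_YEAR)

    def lab_events(self, code: str) -> list[tuple[dt.date, float]]:
        """All (date, value) pairs of a given LAB code, in date order."""
        out = []
        for enc in self.encounters:
            for ev in enc.events:
                if ev.code_type == "LAB" and ev.code == code and ev.value is not None:
                    out.append((enc.date, ev.value))
        return out

    def first_code_date(
        self, codes: Iterable[str], code_type: str = "DX"
    ) -> Optional[dt.date]:
        """Date of the first occurrence of any of *codes*, or None."""
        wanted = set(codes)
        for enc in self.encounters:
            for ev in enc.events:
                if ev.code_type == code_type and ev.code in wanted:
                    return enc.date
        return None

    def has_code(
        self,
        codes: Iterable[str],
        code_type: str = "DX",
        before: Optional[dt.date] = None,
    ) -> bool:
        """Whether any of *codes* occurs (optionally restricted to ``date <= before``)."""
        wanted = set(codes)
        for enc in self.encounters:
            if before is not None and enc.date > before:
                break
            for ev in enc.events:
                if ev.code_type == code_type and ev.code in wanted:
                    return True
        return False
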