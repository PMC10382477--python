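"""Parsing of FAERS numeric date fields.

FAERS date columns (``FDA_DT``, ``EVENT_DT``, ``START_DT``, ``END_DT``)
hold digit strings of varying precision: ``YYYYMMDD`` for a full date,
``YYYYMM`` for a year-month, ``YYYY`` for a year, or nothing at all.
Analyses that need calendar arithmetic (time-to-onset) may only use full
dates; deduplication merely needs a total ordering in which undated rows
sort first.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Literal

Precision = Literal["full", "month", "year", "missing"]

__all__ = ["FaersDate", "parse_faers_date", "MISSING_DATE"]


@dataclass(frozen=True)
class FaersDate:
    """A possibly partial FAERS date.

    ``year``/``month``/``day`` are ``None`` beyond the stated precision.
    """

    year: int | None
    month: int | None
    day: int | None
    precision: Precision

    @property
    def is_full(self) -> bool:
        return self.precision == "full"

    @property
    def is_missing(self) -> bool:
        return self.precision == "missing"

    def to_date(self) -> _dt.date:
        """Calendar date; only valid for full-precision values."""
        if not self.is_full:
            raise ValueError(f"not a full date: {self}")
        return _dt.date(self.year, self.month, self.day)  # type: ignore[arg-type]

    def sort_key(self) -> int:
        """Total-order key: missing < partial < full, chronological otherwise.

        Encodes as YYYYMMDD with zero padding for absent components, so a
        year-month partial sorts just before day 1 of that month and a
        wholly missing date sorts before every dated value.
        """
        return (self.year or 0) * 10000 + (self.month or 0) * 100 + (self.day or 0)


MISSING_DATE = FaersDate(None, None, None, "missing")


def parse_faers_date(raw: str | None) -> FaersDate:
    """Parse one raw FAERS date field. Total: never raises.

    8 digits -> full date (calendar-validated), 6 -> year-month,
    4 -> year only; anything else, including calendar-invalid forms such
    as month 13 or February 30, maps to missing.
    """
    if raw is None:
        return MISSING_DATE
    s = str(raw).strip()
    if not s.isdigit():
        return MISSING_DATE
    if len(s) == 4:
        return FaersDate(int(s), None, None, "year")
    if len(s) == 6:
        year, month = int(s[:4]), int(s[4:6])
        if not 1 <= month <= 12:
            return MISSING_DATE
        return FaersDate(year, month, None, "month")
    if len(s) == 8:
        try:
            d = _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
        except ValueError:
            return MISSING_DATE
        return FaersDate(d.year, d.month, d.day, "full")
    return MISSING_DATE
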