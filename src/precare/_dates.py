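"""Calendar arithmetic helpers.

Conventions used throughout the engine: ISO-8601 dates, ages in completed
years, and a leap-day birthday that rolls to Feb 28 in non-leap years.
"""

from __future__ import annotations

import calendar
import datetime as dt

from .errors import DomainError


def parse_date(value: str | dt.date) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(value)


def add_months(date: dt.date, months: int) -> dt.date:
    """Shift a date by whole months, clamping the day to the month's end.

    2015-01-31 + 1 month -> 2015-02-28; clamping keeps due dates valid
    calendar dates without inventing day-level precision the rules lack.
    """
    month_index = date.year * 12 + (date.month - 1) + months
    year, month = divmod(month_index, 12)
    month += 1
    day = min(date.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


def anniversary(date_of_birth: dt.date, year: int) -> dt.date:
    """Birthday in a given year; Feb 29 rolls back to Feb 28 off leap years."""
    try:
        return date_of_birth.replace(year=year)
    except ValueError:
        return dt.date(year, 2, 28)


def compute_age(date_of_birth: dt.date, as_of: dt.date) -> int:
    """Completed years of age at ``as_of``.

    Raises :class:`DomainError` if ``as_of`` precedes the birth date.
    """
    if as_of < date_of_birth:
        raise DomainError(f"as_of {as_of} precedes date_of_birth {date_of_birth}")
    age = as_of.year - date_of_birth.year
    if as_of < anniversary(date_of_birth, as_of.year):
        age -= 1
    return age
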