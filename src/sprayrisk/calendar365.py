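"""Fixed 365-day (non-leap) calendar used for julian-day <-> month mapping.

Application dates are given as plain julian day numbers that may exceed 365
for multi-year runs; the same non-leap year is recycled for every simulated
year, so day 366 is January 1 of year 2.
"""

from __future__ import annotations

import itertools

DAYS_PER_YEAR = 365
MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
#: cumulative day count at the end of each month (non-leap year)
_MONTH_END = tuple(itertools.accumulate(MONTH_LENGTHS))


def year_index_of_day(day: int) -> int:
    """0-based simulated year containing julian ``day`` (day 1 -> year 0)."""
    if day < 1:
        raise ValueError(f"julian day must be >= 1, got {day}")
    return (day - 1) // DAYS_PER_YEAR


def day_of_year(day: int) -> int:
    """Map a (possibly multi-year) julian day onto 1..365 of the recycled year."""
    if day < 1:
        raise ValueError(f"julian day must be >= 1, got {day}")
    return (day - 1) % DAYS_PER_YEAR + 1


def month_of_day(day: int) -> int:
    """Calendar month (1-12) of a julian day in the recycled non-leap year."""
    doy = day_of_year(day)
    for month, end in enumerate(_MONTH_END, start=1):
        if doy <= end:
            return month
    raise AssertionError("unreachable")  # pragma: no cover
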