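"""Temporal arithmetic for the privacy-preserving event representation.

Every event in the linked extracts carries the person's age in days and the
calendar year of the event, never a date.  A latent birthdate is therefore
only partially identified: an event at age ``a`` in year ``y`` constrains the
birthdate to ``[Jan 1 of y - a, Dec 31 of y - a]``.  Intersecting these
intervals over all of a person's events recovers a feasible birthdate window
that is used wherever a rule needs sub-year resolution (the Jun-Dec 2000
maternity window, study-period membership of year-2000 births).

All day arithmetic uses proleptic-Gregorian ordinals (``datetime.date
.toordinal``), purely internally; ordinals never appear in emitted tables.
"""

from __future__ import annotations

import math
from datetime import date

DAYS_PER_YEAR = 365.25

STUDY_START = date(2000, 7, 1).toordinal()
STUDY_END = date(2006, 12, 31).toordinal()
INCARCERATION_START = date(1998, 1, 1).toordinal()
INCARCERATION_END = date(2006, 12, 31).toordinal()
WINDOW_2000_START = date(2000, 6, 1).toordinal()
WINDOW_2000_END = date(2000, 12, 31).toordinal()


def year_start(year: int) -> int:
    return date(year, 1, 1).toordinal()


def year_end(year: int) -> int:
    return date(year, 12, 31).toordinal()


def year_of_ordinal(ordinal: int) -> int:
    return date.fromordinal(int(ordinal)).year


def completed_years(age_days: float) -> int:
    """Age in completed years, floor(age_days / 365.25)."""
    return int(math.floor(age_days / DAYS_PER_YEAR))


def feasible_birthdate_interval(events) -> tuple[int, int] | None:
    """Intersect the birthdate constraints from (age_days, year) pairs.

    Parameters
    ----------
    events : iterable of (age_days, year)
        All temporal observations for one person.  Pairs with a missing
        component are skipped.

    Returns
    -------
    (lo, hi) ordinals, or ``None`` if the constraints are contradictory
    (which indicates records from more than one true person under one key).
    """
    lo, hi = -10**9, 10**9
    for age_days, year in events:
        if age_days is None or year is None:
            continue
        try:
            a = int(age_days)
            y = int(year)
        except (TypeError, ValueError):
            continue
        lo = max(lo, year_start(y) - a)
        hi = min(hi, year_end(y) - a)
    if lo > hi:
        return None
    return lo, hi


def event_date_interval(
    birth_interval: tuple[int, int] | None, age_days: float
) -> tuple[int, int] | None:
    """Feasible calendar interval (ordinals) for an event at a given age."""
    if birth_interval is None:
        return None
    a = int(age_days)
    return birth_interval[0] + a, birth_interval[1] + a


def definitely_within(
    interval: tuple[int, int] | None, window: tuple[int, int]
) -> bool:
    """True only when the whole feasible interval lies inside the window."""
    if interval is None:
        return False
    return interval[0] >= window[0] and interval[1] <= window[1]


def definitely_before(interval: tuple[int, int] | None, cutoff: int) -> bool:
    if interval is None:
        return False
    return interval[1] < cutoff
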