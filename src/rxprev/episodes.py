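"""Refill-based exposure episodes and medication persistence.

A patient's acetylcholinesterase-inhibitor (AChEI) dispensing stream is cut
into *use periods*: maximal runs of dispensings in which consecutive
dispensings are at most ``gap_days`` (default 365) apart.  Each period is
extended past its last dispensing by that dispensing's days of supply, the
date through which the drug "was supposed to be consumed".

Days of supply are derived from the number of units dispensed and an assumed
daily consumption rate: two units per day for rivastigmine (ATC N06DA03,
taken twice daily) and one unit per day for the other AChEIs.

Persistence at a horizon (default 240 days, i.e. 8 months) is inferred from
the refill pattern of the *index period*.  With day 0 the index date, an
incident user is persistent if any of three rules holds:

1. a new dispensing is dated in the closed interval [210, 240];
2. the dispensings dated in [0, 210) together supply at least 210 days of
   consumption; or
3. the latest dispensing dated before day 210 has supply extending to
   day 210 or beyond.

Rule 2 sums supply across dispensings (stockpiling); rules 1 and 3 look at
single dispensings, each supplying from its own date without carry-over.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

#: ATC prefix shared by all acetylcholinesterase inhibitors.
ACHEI_PREFIX = "N06DA"

#: Default daily consumption rates (units/day) by ATC prefix; anything not
#: matched consumes one unit per day.  Rivastigmine capsules are taken twice
#: daily, hence 2 units/day for all of N06DA03.
DEFAULT_DAILY_RATES: Mapping[str, float] = {"N06DA03": 2.0}


def daily_rate(atc_code: str, rates: Optional[Mapping[str, float]] = None) -> float:
    """Units consumed per day for ``atc_code`` (longest matching prefix wins)."""
    if rates is None:
        rates = DEFAULT_DAILY_RATES
    best: Optional[float] = None
    best_len = -1
    for prefix, rate in rates.items():
        if atc_code.startswith(prefix) and len(prefix) > best_len:
            if rate <= 0:
                raise ValueError(f"daily rate for {prefix!r} must be positive")
            best, best_len = rate, len(prefix)
    return 1.0 if best is None else best


def supply_days(n_units: int, rate: float) -> int:
    """Whole days of supply from one dispensing; a partial final day counts."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    return math.ceil(n_units / rate)


@dataclass(frozen=True)
class Dispensing:
    """One pharmacy dispensation relevant to episode construction."""

    date: dt.date
    atc_code: str
    n_units: int


@dataclass(frozen=True)
class UsePeriod:
    """Maximal run of dispensings separated by at most ``gap_days``.

    ``end_date`` is the last day on which the final dispensing's supply was
    supposed to be consumed.
    """

    prescriptions: tuple[Dispensing, ...]
    end_date: dt.date

    @property
    def start_date(self) -> dt.date:
        return self.prescriptions[0].date

    @property
    def n_prescriptions(self) -> int:
        return len(self.prescriptions)

    @property
    def duration_days(self) -> int:
        """Days from first dispensing through end of supply, inclusive."""
        return (self.end_date - self.start_date).days + 1


def build_use_periods(
    dispensings: Sequence[Dispensing],
    gap_days: int = 365,
    rates: Optional[Mapping[str, float]] = None,
) -> list[UsePeriod]:
    """Partition a sorted dispensing stream into use periods.

    A new period starts whenever the gap to the previous dispensing exceeds
    ``gap_days``; a gap of exactly ``gap_days`` keeps one period.

    Raises
    ------
    ValueError
        If the input is not sorted by date.
    """
    if not dispensings:
        return []
    runs: list[list[Dispensing]] = [[dispensings[0]]]
    for prev, cur in zip(dispensings, dispensings[1:]):
        gap = (cur.date - prev.date).days
        if gap < 0:
            raise ValueError("dispensings must be sorted by date")
        if gap > gap_days:
            runs.append([cur])
        else:
            runs[-1].append(cur)
    periods = []
    for run in runs:
        last = run[-1]
        end = last.date + dt.timedelta(days=supply_days(last.n_units, daily_rate(last.atc_code, rates)) - 1)
        periods.append(UsePeriod(prescriptions=tuple(run), end_date=end))
    return periods


def select_index_period(periods: Sequence[UsePeriod]) -> UsePeriod:
    """Period that starts follow-up: most prescriptions, then longest, then earliest.

    The period with the largest number of dispensings wins; ties are broken
    by longer duration (start through end of supply), then by earlier start.
    """
    if not periods:
        raise ValueError("select_index_period requires a non-empty list of periods")
    return max(
        periods,
        key=lambda p: (p.n_prescriptions, p.duration_days, -p.start_date.toordinal()),
    )


def treatment_length(index_period: UsePeriod) -> int:
    """Days from the index date through the last supposed day of consumption."""
    return index_period.duration_days


def classify_persistent(
    index_period: UsePeriod,
    horizon_days: int = 240,
    rule_day: int = 210,
    rates: Optional[Mapping[str, float]] = None,
) -> tuple[bool, Optional[int]]:
    """Apply the three refill-pattern persistence rules to the index period.

    Returns ``(persistent, rule_fired)`` where ``rule_fired`` is the
    lowest-numbered rule that holds, or ``None``.  Day 0 is the index date;
    rule 1 uses the closed interval [rule_day, horizon_days]; rule 2 sums
    exact (fractional) days of supply over dispensings dated in
    [0, rule_day); rule 3 checks whether the latest dispensing dated before
    ``rule_day`` supplies through day ``rule_day``.
    """
    start = index_period.start_date
    days = [(d.date - start).days for d in index_period.prescriptions]

    rule1 = any(rule_day <= day <= horizon_days for day in days)

    rule2 = (
        sum(
            d.n_units / daily_rate(d.atc_code, rates)
            for d, day in zip(index_period.prescriptions, days)
            if 0 <= day < rule_day
        )
        >= rule_day
    )

    rule3 = False
    pre = [(day, d) for d, day in zip(index_period.prescriptions, days) if day < rule_day]
    if pre:
        day, d = max(pre, key=lambda t: t[0])
        rule3 = day + supply_days(d.n_units, daily_rate(d.atc_code, rates)) - 1 >= rule_day

    for rule, fired in ((1, rule1), (2, rule2), (3, rule3)):
        if fired:
            return True, rule
    return False, None


def coverage_oracle(
    index_period: UsePeriod,
    horizon_days: int,
    rates: Optional[Mapping[str, float]] = None,
    stockpile: bool = False,
) -> np.ndarray:
    """Brute-force per-day supply array over [0, horizon_days).

    In the basic (no-carry) mode, entry ``d`` counts the dispensings whose
    own supply interval covers day ``d``: each dispensing supplies from its
    date for ``ceil(n_units/rate)`` days, overlaps are not summed into later
    days.  In stockpiling mode a single pill stock is walked one day at a
    time: units are added on the dispensing date and consumed at the daily
    rate of the most recent dispensing, so entry ``d`` is the stock available
    on day ``d`` (before that day's consumption).  Both modes exist so the
    per-prescription supply convention used by rule 3 and by treatment
    length can be checked against the cumulative reading.
    """
    arr = np.zeros(horizon_days, dtype=float)
    if not index_period.prescriptions:
        return arr
    start = index_period.start_date
    events = sorted(
        ((d.date - start).days, d) for d in index_period.prescriptions
    )
    if not stockpile:
        for day, d in events:
            lo = max(day, 0)
            hi = min(day + supply_days(d.n_units, daily_rate(d.atc_code, rates)), horizon_days)
            if hi > lo:
                arr[lo:hi] += 1.0
        return arr
    stock = 0.0
    rate = 1.0
    idx = 0
    for day in range(horizon_days):
        while idx < len(events) and events[idx][0] <= day:
            stock += events[idx][1].n_units
            rate = daily_rate(events[idx][1].atc_code, rates)
            idx += 1
        arr[day] = stock
        stock = max(stock - rate, 0.0)
    return arr
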