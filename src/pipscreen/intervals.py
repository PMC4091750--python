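"""Half-open calendar-day interval sets.

All exposure logic in the screening engine is expressed over sets of
``[start, end)`` date intervals. A *day set* is a list of ``(start, end)``
tuples of :class:`datetime.date`, kept sorted and disjoint by
:func:`normalize`. The empty list is the empty set.
"""

from __future__ import annotations

from datetime import date, timedelta

Interval = tuple[date, date]
DaySet = list[Interval]

#: Sentinels for unbounded constraints ("coded at any time before ...").
DATE_MIN = date(1800, 1, 1)
DATE_MAX = date(2200, 1, 1)

ONE_DAY = timedelta(days=1)


def normalize(intervals: DaySet) -> DaySet:
    """Sort, drop empty intervals and merge touching/overlapping ones."""
    ivs = sorted((s, e) for s, e in intervals if s < e)
    out: DaySet = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def union(a: DaySet, b: DaySet) -> DaySet:
    return normalize(list(a) + list(b))


def intersect(a: DaySet, b: DaySet) -> DaySet:
    out: DaySet = []
    i = j = 0
    a = normalize(a)
    b = normalize(b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def difference(a: DaySet, b: DaySet) -> DaySet:
    """Days in *a* not in *b*."""
    a = normalize(a)
    b = normalize(b)
    out: DaySet = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def total_days(intervals: DaySet) -> int:
    return sum((e - s).days for s, e in normalize(intervals))


def first_day(intervals: DaySet) -> date | None:
    ivs = normalize(intervals)
    return ivs[0][0] if ivs else None


def nth_day(intervals: DaySet, n: int) -> date | None:
    """The n-th covered calendar day (1-indexed), or None if fewer days."""
    if n < 1:
        raise ValueError("n must be >= 1")
    remaining = n
    for s, e in normalize(intervals):
        length = (e - s).days
        if remaining <= length:
            return s + timedelta(days=remaining - 1)
        remaining -= length
    return None


def contains(intervals: DaySet, day: date) -> bool:
    return any(s <= day < e for s, e in intervals)


def clip(intervals: DaySet, start: date, end: date) -> DaySet:
    return intersect(intervals, [(start, end)])
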