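"""Noon-anchored clock arithmetic for nightly sleep times.

A night labeled with date D spans noon of D-1 to noon of D (the night ends
on the morning of its label, the final-awakening date). Clock times are
mapped to minutes since the *anchor noon* so that 22:30 -> 630 and 00:30
(after midnight) -> 750; onset times then average and subtract correctly
across midnight.
"""

from __future__ import annotations

from datetime import date, datetime, time, timedelta
from typing import Iterable

MINUTES_PER_DAY = 1440.0
NOON_MIN = 720.0


def minutes_since_noon(t: time | datetime) -> float:
    """Minutes since the most recent noon (range [0, 1440))."""
    if isinstance(t, datetime):
        t = t.time()
    m = t.hour * 60 + t.minute + t.second / 60.0
    return m - NOON_MIN if m >= NOON_MIN else m + NOON_MIN


def clock_from_noon_minutes(m: float) -> time:
    """Inverse of :func:`minutes_since_noon` (result in [00:00, 24:00))."""
    m = m % MINUTES_PER_DAY
    total = (m + NOON_MIN) % MINUTES_PER_DAY
    h, rem = divmod(total, 60.0)
    mins, secs = divmod(rem * 60.0, 60.0)
    return time(int(h), int(mins), int(round(secs)) % 60)


def mean_clock_time(times: Iterable[time | datetime]) -> time:
    """Arithmetic mean of clock times on the noon-anchored axis."""
    vals = [minutes_since_noon(t) for t in times]
    if not vals:
        raise ValueError("mean_clock_time requires at least one time")
    return clock_from_noon_minutes(sum(vals) / len(vals))


def night_datetime(night: date, noon_minutes: float) -> datetime:
    """Wall-clock datetime for a noon-anchored offset within night ``night``.

    Offsets < 720 fall on the evening of ``night - 1 day``; offsets >= 720
    (past midnight) fall on the morning of ``night`` itself.
    """
    anchor = datetime.combine(night - timedelta(days=1), time(12, 0))
    return anchor + timedelta(minutes=noon_minutes)


def noon_minutes_of(dt: datetime, night: date) -> float:
    """Minutes from night's anchor noon (noon of ``night - 1``) to ``dt``.

    Unlike :func:`minutes_since_noon` this keeps multi-day offsets, so a
    late final awakening after the following noon stays monotone.
    """
    anchor = datetime.combine(night - timedelta(days=1), time(12, 0))
    return (dt - anchor).total_seconds() / 60.0
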