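"""Absolute- and relative-time codecs for harmonized fall-signal files.

The exchange format timestamps every sample twice: as seconds relative to the
start of the file and as an absolute *serial day number* — a real number of
days since a reference epoch, where the fractional part is the fraction of the
day elapsed since midnight.  The serial-day convention used here is the one
made ubiquitous by MATLAB's ``datenum``: the reference date January 1st of
year 0 (proleptic Gregorian) carries day number 1, so noon on that date is
1.5 and midnight of January 2nd, year 0, is 2.0.  Python date ordinals place
0001-01-01 at 1; year 0 is a leap year under proleptic Gregorian rules (366
days), hence the fixed offset of 366 between the two conventions.

Times are opaque local clock times: no timezone or DST handling, matching the
way fall reports record time of day.  Sub-second precision is kept to 1 ms,
an order of magnitude finer than the 10 ms sample period of the fastest
(100 Hz) recordings handled here.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DAY_SECONDS",
    "CalendarDateTime",
    "to_absolute_days",
    "from_absolute_days",
    "relative_seconds",
]

DAY_SECONDS = 86400.0

#: Day number of 0001-01-01 (Python ordinal 1) minus 1: year 0 contributes 366
#: days and the reference date itself is day 1, not day 0.
EPOCH_OFFSET = 366


@dataclass(frozen=True, order=True)
class CalendarDateTime:
    """A proleptic-Gregorian wall-clock instant with millisecond precision."""

    year: int
    month: int
    day: int
    hour: int = 0
    minute: int = 0
    second: int = 0
    millisecond: int = 0

    def __post_init__(self) -> None:
        try:
            _dt.date(self.year, self.month, self.day)
        except ValueError as exc:
            raise ValueError(f"invalid calendar date: {exc}") from None
        for name, value, upper in (
            ("hour", self.hour, 23),
            ("minute", self.minute, 59),
            ("second", self.second, 59),
            ("millisecond", self.millisecond, 999),
        ):
            if not (0 <= value <= upper):
                raise ValueError(f"invalid {name}: {value} not in 0..{upper}")

    # -- conversions ---------------------------------------------------------

    @classmethod
    def from_datetime(cls, dt: _dt.datetime) -> "CalendarDateTime":
        return cls(
            dt.year, dt.month, dt.day, dt.hour, dt.minute, dt.second,
            round(dt.microsecond / 1000) % 1000,
        )

    def to_datetime(self) -> _dt.datetime:
        return _dt.datetime(
            self.year, self.month, self.day, self.hour, self.minute,
            self.second, self.millisecond * 1000,
        )

    @property
    def date(self) -> _dt.date:
        return _dt.date(self.year, self.month, self.day)

    def seconds_of_day(self) -> float:
        return (
            self.hour * 3600.0
            + self.minute * 60.0
            + self.second
            + self.millisecond / 1000.0
        )

    def add_seconds(self, seconds: float) -> "CalendarDateTime":
        return CalendarDateTime.from_datetime(
            self.to_datetime() + _dt.timedelta(seconds=seconds)
        )

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return self.to_datetime().isoformat(timespec="milliseconds")


def to_absolute_days(t: CalendarDateTime) -> float:
    """Encode a calendar datetime as a serial day number.

    The integer part counts days since the reference date (January 1st, year
    0 = day 1); the fractional part is seconds-since-midnight / 86400, so
    noon falls at .5 and midnight at .0.
    """
    if not isinstance(t, CalendarDateTime):
        t = CalendarDateTime.from_datetime(t)
    ordinal = _dt.date(t.year, t.month, t.day).toordinal() + EPOCH_OFFSET
    return ordinal + t.seconds_of_day() / DAY_SECONDS


def from_absolute_days(d: float) -> CalendarDateTime:
    """Decode a serial day number back to a calendar datetime (1 ms rounding)."""
    if not math.isfinite(d):
        raise ValueError(f"day number must be finite, got {d!r}")
    day = math.floor(d)
    ms = round((d - day) * DAY_SECONDS * 1000.0)
    if ms >= 86_400_000:  # fraction rounded up to a full day
        day += 1
        ms -= 86_400_000
    ordinal = day - EPOCH_OFFSET
    if not (1 <= ordinal <= _dt.date.max.toordinal()):
        raise ValueError(f"day number {d!r} outside the representable calendar range")
    date = _dt.date.fromordinal(ordinal)
    second, ms = divmod(ms, 1000)
    minute, second = divmod(second, 60)
    hour, minute = divmod(minute, 60)
    return CalendarDateTime(date.year, date.month, date.day, hour, minute, second, ms)


def relative_seconds(timestamps, start) -> np.ndarray:
    """Convert serial-day timestamps to seconds relative to ``start``.

    ``timestamps`` must be nondecreasing; the first violation is reported.
    """
    ts = np.asarray(timestamps, dtype=float)
    if isinstance(start, CalendarDateTime):
        start = to_absolute_days(start)
    if ts.ndim != 1:
        raise ValueError("timestamps must be one-dimensional")
    if ts.size:
        diffs = np.diff(ts)
        bad = np.nonzero(diffs < 0)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"timestamps decrease at index {i + 1}: {ts[i + 1]!r} < {ts[i]!r}"
            )
    return (ts - float(start)) * DAY_SECONDS
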