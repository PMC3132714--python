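"""Schedule grammar: ISO-8601-style durations and 5-field cron expressions.

Durations cover the common deployment case ("rebuild weekly" = ``P7D``);
cron expressions cover calendar-anchored schedules.  Only the subset of
cron needed for scheduling checks is implemented: ``*``, numbers, lists,
ranges and ``/step``, over minute, hour, day-of-month, month and
day-of-week fields (day-of-week 0 and 7 both mean Sunday, as in vixie
cron, and day-of-month/day-of-week combine with OR when both are
restricted).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone

from .errors import ValidationError

_DURATION_RE = re.compile(
    r"^P(?:(?P<weeks>\d+(?:\.\d+)?)W)?(?:(?P<days>\d+(?:\.\d+)?)D)?"
    r"(?:T(?:(?P<hours>\d+(?:\.\d+)?)H)?(?:(?P<minutes>\d+(?:\.\d+)?)M)?"
    r"(?:(?P<seconds>\d+(?:\.\d+)?)S)?)?$"
)

_FIELD_RANGES = [(0, 59), (0, 23), (1, 31), (1, 12), (0, 7)]


def parse_duration(text: str) -> float:
    """Parse an ISO-8601-style duration (``P7D``, ``PT1S``, ``P1W``...)
    into seconds."""
    m = _DURATION_RE.match(text.strip().upper())
    if m is None or not any(m.groupdict().values()):
        raise ValidationError(f"unparseable duration: {text!r}")
    g = {k: float(v) if v else 0.0 for k, v in m.groupdict().items()}
    return (
        g["weeks"] * 604800 + g["days"] * 86400
        + g["hours"] * 3600 + g["minutes"] * 60 + g["seconds"]
    )


def _parse_cron_field(field: str, lo: int, hi: int) -> set[int]:
    values: set[int] = set()
    for part in field.split(","):
        part, _, step_s = part.partition("/")
        step = int(step_s) if step_s else 1
        if step < 1:
            raise ValidationError(f"bad cron step in {field!r}")
        if part == "*":
            start, end = lo, hi
        elif "-" in part:
            a, _, b = part.partition("-")
            start, end = int(a), int(b)
        else:
            start = end = int(part)
            if step_s:  # "n/step" means n..hi by step
                end = hi
        if not (lo <= start <= hi and lo <= end <= hi and start <= end):
            raise ValidationError(f"cron field {field!r} out of range [{lo},{hi}]")
        values.update(range(start, end + 1, step))
    return values


@dataclass(frozen=True)
class CronExpression:
    minutes: frozenset[int]
    hours: frozenset[int]
    days_of_month: frozenset[int]
    months: frozenset[int]
    days_of_week: frozenset[int]
    dom_restricted: bool
    dow_restricted: bool

    @classmethod
    def parse(cls, text: str) -> "CronExpression":
        fields = text.split()
        if len(fields) != 5:
            raise ValidationError(f"cron expression needs 5 fields: {text!r}")
        sets = [
            frozenset(_parse_cron_field(f, lo, hi))
            for f, (lo, hi) in zip(fields, _FIELD_RANGES)
        ]
        dow = frozenset(d % 7 for d in sets[4])
        return cls(
            sets[0], sets[1], sets[2], sets[3], dow,
            dom_restricted=fields[2] != "*",
            dow_restricted=fields[4] != "*",
        )

    def matches(self, dt: datetime) -> bool:
        if dt.minute not in self.minutes or dt.hour not in self.hours:
            return False
        if dt.month not in self.months:
            return False
        dom_ok = dt.day in self.days_of_month
        dow_ok = (dt.weekday() + 1) % 7 in self.days_of_week  # Sunday=0
        if self.dom_restricted and self.dow_restricted:
            return dom_ok or dow_ok
        return dom_ok and dow_ok

    def occurs_between(self, start: float, end: float) -> bool:
        """True iff some cron occurrence lies in the half-open epoch
        interval (start, end]."""
        if end <= start:
            return False
        dt = datetime.fromtimestamp(start, tz=timezone.utc).replace(
            second=0, microsecond=0
        ) + timedelta(minutes=1)
        end_dt = datetime.fromtimestamp(end, tz=timezone.utc)
        while dt <= end_dt:
            if self.matches(dt):
                return True
            dt += timedelta(minutes=1)
        return False


@dataclass(frozen=True)
class Schedule:
    """Either a fixed interval (seconds) or a cron expression."""

    interval_seconds: float | None = None
    cron: CronExpression | None = None

    @classmethod
    def parse(cls, text: str) -> "Schedule":
        text = text.strip()
        if text.upper().startswith("P"):
            return cls(interval_seconds=parse_duration(text))
        return cls(cron=CronExpression.parse(text))

    def due(self, last_success: float | None, now: float) -> bool:
        """A rebuild is due if none has ever succeeded, or the interval
        has elapsed since the last success, or a cron occurrence lies in
        (last_success, now]."""
        if last_success is None:
            return True
        if self.interval_seconds is not None:
            return now - last_success >= self.interval_seconds
        assert self.cron is not None
        return self.cron.occurs_between(last_success, now)
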