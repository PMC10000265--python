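"""ISO-8601 age durations and RFC-3339 timestamps.

Clinical phenotype exchange records ages as calendar durations built from
years, months and days (``P42Y7M13D`` for 42 years, 7 months, 13 days).
This module provides the canonical encoder/decoder for those duration
strings, a deterministic ordering over them, and helpers for the RFC-3339
instants used by timestamp-valued fields.

Two deliberate restrictions keep the ordering calendar-free and total:

* Week (``W``) and time-of-day (``T...``) components are rejected — no
  clinical age in this schema uses them, and mixing them with months would
  make the ordering depend on a calendar.
* Ordering treats 1 year as exactly 12 months but never converts days into
  months (months vary in length), so ``P1Y`` equals ``P12M`` while ``P30D``
  sorts strictly below ``P1M``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime, timezone
from enum import Enum

__all__ = [
    "AgeComponents",
    "DurationError",
    "Ordering",
    "TimestampError",
    "canonicalize_timestamp",
    "compare_durations",
    "duration_sort_key",
    "encode_duration",
    "format_timestamp",
    "parse_duration",
    "parse_timestamp",
]


class DurationError(ValueError):
    """Raised for text that is not an ISO-8601 date duration.

    ``offending`` carries the substring (or whole text) that broke the
    grammar, for actionable error messages.
    """

    def __init__(self, text: str, offending: str, reason: str) -> None:
        self.text = text
        self.offending = offending
        self.reason = reason
        super().__init__(f"malformed ISO-8601 duration {text!r}: {reason} (at {offending!r})")


class TimestampError(ValueError):
    """Raised for text that is not an RFC-3339 instant."""

    def __init__(self, text: str, reason: str) -> None:
        self.text = text
        self.reason = reason
        super().__init__(f"malformed RFC-3339 timestamp {text!r}: {reason}")


@dataclass(frozen=True)
class AgeComponents:
    """A calendar age duration split into years, months and days."""

    years: int = 0
    months: int = 0
    days: int = 0

    def __post_init__(self) -> None:
        for name in ("years", "months", "days"):
            value = getattr(self, name)
            if isinstance(value, bool) or not isinstance(value, int):
                raise TypeError(f"{name} must be an integer, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")


_DURATION_RE = re.compile(r"^P(?:(\d+)Y)?(?:(\d+)M)?(?:(\d+)D)?$")


def encode_duration(components: AgeComponents) -> str:
    """Render an age as a canonical ISO-8601 date duration.

    Zero components are omitted; a fully zero duration is written ``P0D``
    (ISO-8601 requires at least one component).

    >>> encode_duration(AgeComponents(42, 7, 13))
    'P42Y7M13D'
    >>> encode_duration(AgeComponents(0, 6, 0))
    'P6M'
    """
    parts = ["P"]
    if components.years:
        parts.append(f"{components.years}Y")
    if components.months:
        parts.append(f"{components.months}M")
    if components.days:
        parts.append(f"{components.days}D")
    if len(parts) == 1:
        parts.append("0D")
    return "".join(parts)


def parse_duration(text: str) -> AgeComponents:
    """Parse an ISO-8601 date duration into its components.

    Accepts non-canonical but valid forms such as ``P0Y6M``. Rejects week
    and time components and anything outside the Y/M/D grammar, raising
    :class:`DurationError` that names the offending substring.
    """
    if not isinstance(text, str):
        raise DurationError(str(text), str(text), "not a string")
    if not text.startswith("P"):
        raise DurationError(text, text[:1] or "<empty>", "must start with 'P'")
    body = text[1:]
    if not body:
        raise DurationError(text, text, "requires at least one component")
    if "W" in body:
        raise DurationError(text, "W", "week components are not allowed in ages")
    if "T" in body:
        raise DurationError(text, "T" + body.split("T", 1)[1], "time-of-day components are not allowed in ages")
    match = _DURATION_RE.match(text)
    if match is None or not any(match.groups()):
        # locate the first character that is neither a digit nor an allowed designator
        bad = next((ch for ch in body if ch not in "0123456789YMD"), body)
        raise DurationError(text, bad, "does not match P[nY][nM][nD]")
    years, months, days = (int(g) if g else 0 for g in match.groups())
    return AgeComponents(years=years, months=months, days=days)


class Ordering(Enum):
    LESS = -1
    EQUAL = 0
    GREATER = 1


def duration_sort_key(components: AgeComponents) -> tuple[int, int]:
    """Sort key: (total months, days). 1 year == 12 months; days never promote."""
    return (12 * components.years + components.months, components.days)


def compare_durations(a: AgeComponents, b: AgeComponents) -> Ordering:
    """Compare two ages lexicographically on (total months, days)."""
    ka, kb = duration_sort_key(a), duration_sort_key(b)
    if ka < kb:
        return Ordering.LESS
    if ka > kb:
        return Ordering.GREATER
    return Ordering.EQUAL


def parse_timestamp(text: str) -> datetime:
    """Parse an RFC-3339 instant to a timezone-aware UTC datetime.

    Sub-second precision is preserved. Naive (zone-less) instants are
    rejected: the wire form is always an absolute point in time.
    """
    if not isinstance(text, str) or not text:
        raise TimestampError(str(text), "empty or not a string")
    try:
        parsed = datetime.fromisoformat(text)
    except ValueError as exc:
        raise TimestampError(text, str(exc)) from None
    if parsed.tzinfo is None:
        raise TimestampError(text, "missing UTC offset")
    return parsed.astimezone(timezone.utc)


def format_timestamp(instant: datetime) -> str:
    """Render a datetime as a canonical RFC-3339 UTC string (``...Z``)."""
    if instant.tzinfo is None:
        raise TimestampError(instant.isoformat(), "naive datetime")
    instant = instant.astimezone(timezone.utc)
    if instant.microsecond:
        base = instant.strftime("%Y-%m-%dT%H:%M:%S.%f").rstrip("0")
    else:
        base = instant.strftime("%Y-%m-%dT%H:%M:%S")
    return base + "Z"


def canonicalize_timestamp(text: str) -> str:
    """Parse and re-render a timestamp in canonical UTC ``Z`` form."""
    return format_timestamp(parse_timestamp(text))
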