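"""Small unit helpers for gestational age and lengths.

GA is carried internally in days (float). Weeks+days ("W+d") notation is a
presentation concern only.
"""

from __future__ import annotations

DAYS_PER_WEEK = 7.0


def weeks_days_to_days(weeks: int, days: int = 0) -> float:
    """Convert W+d notation to days (e.g. 24+0 -> 168)."""
    if days < 0 or days > 6:
        raise ValueError(f"day part must be 0-6, got {days}")
    return float(weeks * 7 + days)


def days_to_weeks_days(ga_days: float) -> tuple[int, int]:
    """Convert days to (weeks, days), truncating partial days."""
    total = int(ga_days)
    return total // 7, total % 7


def format_weeks_days(ga_days: float) -> str:
    w, d = days_to_weeks_days(ga_days)
    return f"{w}+{d}"


def convert_length(value: float, from_unit: str, to_unit: str) -> float:
    """Convert between cm and mm."""
    if from_unit == to_unit:
        return value
    if (from_unit, to_unit) == ("cm", "mm"):
        return value * 10.0
    if (from_unit, to_unit) == ("mm", "cm"):
        return value / 10.0
    raise ValueError(f"unsupported length conversion {from_unit!r} -> {to_unit!r}")
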