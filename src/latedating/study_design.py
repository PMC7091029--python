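"""Shared study-design constants: sites and scan-window day ranges."""

from __future__ import annotations

SITES = ("A", "B", "C")

#: Scan windows as closed day ranges: W1 = 24+0 to 29+6 wk, W2 = 30+0 to 36+6 wk.
WINDOWS: dict[str, tuple[float, float]] = {
    "W1": (168.0, 209.0),
    "W2": (210.0, 258.0),
}


def assign_window(ga_days: float) -> str | None:
    """Window label for a gold-standard GA at scan, or None if out of window."""
    for name, (lo, hi) in WINDOWS.items():
        # upper bound is inclusive through the last day (e.g. 209.99 is still 29+6)
        if lo <= ga_days < hi + 1.0:
            return name
    return None
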