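"""Dosing-schedule arithmetic for intermittent treatment designs."""

from __future__ import annotations

from .exceptions import ConfigurationError

__all__ = ["treatment_days"]


def treatment_days(total_days: int = 30, days_on: int = 5, days_off: int = 2) -> list[int]:
    """1-based days on which treatment is given under an on/off cycle.

    The default 5-days-on / 2-days-off pattern over 30 days (a standard
    chronic intermittent dosing schedule) yields 22 treatment days.
    """
    if total_days < 1 or days_on < 1 or days_off < 0:
        raise ConfigurationError("schedule parameters must be positive (days_off >= 0)")
    cycle = days_on + days_off
    return [d for d in range(1, total_days + 1) if (d - 1) % cycle < days_on]
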