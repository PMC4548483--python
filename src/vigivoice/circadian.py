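"""Circadian phase covariate and circular time-of-day error.

The phase covariate summarises where a clock time falls in the circadian
cycle as ``P = cos(omega * (t - alpha))`` with ``omega = 2*pi / period``.
With the default reference ``alpha = 3`` h and a 24 h period the cosine
peaks at 03:00, near the commonly cited circadian low point, so higher P
means "deeper into the biological night".

Errors between two clock times are scored on the circle: a prediction of
23:00 for an observation of 01:00 is 2 h off, not 22 h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, time

__all__ = ["PhaseSpec", "phase_value", "circular_error", "MINUTES_PER_DAY"]

MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class PhaseSpec:
    """Parameters of the cosine phase covariate.

    Attributes
    ----------
    alpha_hours:
        Clock hour at which the covariate peaks (default 3, i.e. 03:00).
    period_hours:
        Length of one cycle; the default 24 h makes the covariate a pure
        time-of-day function.
    """

    alpha_hours: float = 3.0
    period_hours: float = 24.0

    def __post_init__(self) -> None:
        if self.period_hours <= 0:
            raise ValueError(f"period_hours must be > 0, got {self.period_hours}")

    @property
    def omega(self) -> float:
        """Angular frequency in radians per hour."""
        return 2.0 * math.pi / self.period_hours


def _to_hours_of_day(t: float | datetime | time) -> float:
    """Coerce a clock time to fractional hours of day in [0, 24)."""
    if isinstance(t, datetime):
        return (t.hour + t.minute / 60.0 + t.second / 3600.0 + t.microsecond / 3.6e9) % 24.0
    if isinstance(t, time):
        return (t.hour + t.minute / 60.0 + t.second / 3600.0) % 24.0
    return float(t) % 24.0


def phase_value(t: float | datetime | time, spec: PhaseSpec | None = None) -> float:
    """Circadian phase covariate ``cos(omega * (t - alpha))`` in [-1, 1].

    Parameters
    ----------
    t:
        Clock time: a datetime, a time, or fractional hours of day.
    spec:
        Phase parameters; defaults to a 24 h cycle peaking at 03:00.
    """
    if spec is None:
        spec = PhaseSpec()
    hours = _to_hours_of_day(t)
    return math.cos(spec.omega * (hours - spec.alpha_hours))


def circular_error(predicted: float | datetime | time, observed: float | datetime | time) -> float:
    """Smallest time-of-day difference between two clock times, in minutes.

    Both arguments may be datetimes, times, or minutes-of-day. The result
    lies in [0, 720]: two times can never be more than 12 h apart on a
    24 h clock.
    """
    p = _as_minutes_of_day(predicted)
    o = _as_minutes_of_day(observed)
    delta = abs(p - o) % MINUTES_PER_DAY
    return min(delta, MINUTES_PER_DAY - delta)


def _as_minutes_of_day(t: float | datetime | time) -> float:
    if isinstance(t, (datetime, time)):
        return _to_hours_of_day(t) * 60.0
    return float(t) % MINUTES_PER_DAY
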