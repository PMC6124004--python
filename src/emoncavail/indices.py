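"""Closed-form availability index formulas.

Every index is the mean over observed shifts of a per-shift score, times
100, and therefore lies in [-100, 100] whenever the scoring categories
partition the shifts:

* doctor-style:          (a + b/2 + c - d) / N x 100
* graded, morning ward:  (m3 + 2 m2/3 + m1/3 - m0) / N x 100
* graded, off-peak ward: (m2 + m1/2 - m0) / N x 100
* operating theatre:     (m2 + m1/2 + m2a + m1a/2 - m0) / N x 100
* support pool:          (s2 + s1/2 - s0) / N x 100

Partial staffing earns the fraction of the minimum that was present; an
adequate on-call response earns the same credit as on-site presence at the
same headcount; a confirmed failure (no provider and an unanswered call)
scores -1. Shifts where responsiveness could not be observed score 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Union

from .core import (
    DoctorTally,
    GradedTally,
    Shift,
    SupportTally,
    UndefinedIndexError,
)

DAY_AVERAGE = "day_average"


@dataclass(frozen=True)
class IndexValue:
    """One availability index on the [-100, 100] percentage scale."""

    value: float
    shift: str  # a Shift value or "day_average"

    @property
    def negative_flag(self) -> bool:
        return self.value < 0

    def rounded(self, decimals: int = 1, clamp_negative: bool = False) -> float:
        """Presentation value: half-away-from-zero rounding, optional clamp.

        All chaining happens at full precision; rounding is applied once,
        here, because rounding intermediate values fails to reproduce some
        reported day averages.
        """
        v = max(self.value, 0.0) if clamp_negative else self.value
        q = Decimal(1).scaleb(-decimals)
        return float(Decimal(repr(v)).quantize(q, rounding=ROUND_HALF_UP))


def _check_n(n: int) -> None:
    if n <= 0:
        raise UndefinedIndexError("index undefined over zero observed shifts")


def doctor_index(t: DoctorTally) -> IndexValue:
    """(a + b/2 + c - d)/N x 100 for doctor-style cadres.

    Medical technologists and nurse aides use the same formula.
    """
    _check_n(t.N)
    return IndexValue((t.a + t.b / 2 + t.c - t.d) / t.N * 100, "pooled")


def graded_index(t: GradedTally, minimum: int) -> IndexValue:
    """Graded headcount index against a shift minimum of 2 or 3.

    A shift with k providers (0 < k < minimum) earns k/minimum; at or above
    the minimum earns 1; none earns -1. On-call categories earn the on-site
    credit for the same headcount.
    """
    _check_n(t.N)
    if minimum == 3:
        score = t.m3 + 2 * t.m2 / 3 + t.m1 / 3 - t.m0
        if t.m2a or t.m1a:
            score += t.m2a * 2 / 3 + t.m1a / 3
    elif minimum == 2:
        score = (t.m3 + t.m2) + t.m1 / 2 + t.m2a + t.m1a / 2 - t.m0
    else:
        raise ValueError(f"unsupported graded minimum {minimum}")
    return IndexValue(score / t.N * 100, "pooled")


def graded_index_morning(t: GradedTally) -> IndexValue:
    """(m3 + 2 m2/3 + m1/3 - m0)/N x 100 — ward shifts requiring 3."""
    return graded_index(t, minimum=3)


def graded_index_offpeak(t: GradedTally) -> IndexValue:
    """(m2 + m1/2 - m0)/N x 100 — ward shifts requiring 2."""
    return graded_index(t, minimum=2)


def ot_index(t: GradedTally) -> IndexValue:
    """(m2 + m1/2 + m2a + m1a/2 - m0)/N x 100 — operating-theatre nurses.

    On-call arrival (m2a, m1a) earns the same credit as on-site presence at
    the same headcount; arrival delay is not discounted.
    """
    return graded_index(t, minimum=2)


def support_index(t: SupportTally) -> IndexValue:
    """(s2 + s1/2 - s0)/N x 100 — pooled support staff."""
    _check_n(t.N)
    return IndexValue((t.s2 + t.s1 / 2 - t.s0) / t.N * 100, "pooled")


def day_average(morning: IndexValue, evening: IndexValue,
                night: IndexValue) -> IndexValue:
    """Unweighted mean of the three full-precision per-shift indices.

    Shifts are weighted equally despite unequal nominal durations.
    """
    vals = (morning.value, evening.value, night.value)
    return IndexValue(sum(vals) / 3, DAY_AVERAGE)


def snap_to_shift_grid(value: float, n_shifts: int = 30,
                       resolution: float = 0.5) -> float:
    """Recover the full-precision index behind a 1-decimal printed value.

    Over N equally weighted shifts every attainable doctor-style index is a
    multiple of ``resolution``/N x 100 (the half-credit category makes the
    grid step one half-shift). Snapping a rounded value back to that grid
    lets day averages be taken at full precision, which chained rounding
    cannot reproduce (e.g. printed 58.3, 28.3, 8.3 stand for 58.33, 28.33,
    8.33 and average to 31.7, not 31.6).
    """
    step = resolution / n_shifts * 100
    return round(value / step) * step


# per-shift scores, used by tests as an independent brute-force oracle and
# by the sampled-scenario expectation calculation
DOCTOR_SCORES = {"a": 1.0, "b": 0.5, "c": 1.0, "d": -1.0, "x": 0.0}
GRADED_SCORES_MIN3 = {"m3": 1.0, "m2": 2 / 3, "m1": 1 / 3, "m0": -1.0,
                      "m2a": 2 / 3, "m1a": 1 / 3, "x": 0.0}
GRADED_SCORES_MIN2 = {"m3": 1.0, "m2": 1.0, "m1": 0.5, "m0": -1.0,
                      "m2a": 1.0, "m1a": 0.5, "x": 0.0}
SUPPORT_SCORES = {"s2": 1.0, "s1": 0.5, "s0": -1.0}


__all__ = [
    "IndexValue", "snap_to_shift_grid", "doctor_index", "graded_index",
    "graded_index_morning",
    "graded_index_offpeak", "ot_index", "support_index", "day_average",
    "DAY_AVERAGE", "DOCTOR_SCORES", "GRADED_SCORES_MIN3",
    "GRADED_SCORES_MIN2", "SUPPORT_SCORES",
]
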