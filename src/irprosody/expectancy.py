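"""Expectancy and closure calculus.

Interval labels translate into *arrows* (quanta of expectancy) and *tails*
(quanta of closure) which accumulate over a grouping; secondary features —
durational change and descent — translate into *commas* (closure) and
*inverted commas* (counterclosure) which apply to their own tone only.

Net implication on a tone is

    net = (a - t) + (i - c)

with ``a``/``t`` the arrows and tails tallied since the grouping began and
``i``/``c`` the inverted commas and commas on the tone itself. A grouping
closes when the net falls to zero or below.

Durational commas: a tone ``d_c/d_p`` times as long as its predecessor
earns ``floor(log_base(d_c/d_p))`` commas (clamped to [0, 3]); shortening
earns inverted commas per factor-of-``r`` reduction, likewise clamped. A
small snap tolerance is applied before flooring so that printed, rounded
base constants (e.g. 1.225 for a two-comma 1.5x lengthening, where the
exact base is sqrt(1.5)) reproduce their intended integer counts.
"""

from __future__ import annotations

import math

from .model import ExpectancyMarks, IntervalLabel, InvalidInputError, Role

__all__ = [
    "arrows_for_label",
    "descent_commas",
    "duration_commas",
    "duration_inverted_commas",
    "net_implication",
]

#: absorbed rounding of threshold constants before flooring log-ratios
_FLOOR_SNAP = 1e-2
_MAX_COMMAS = 3


def arrows_for_label(lbl: IntervalLabel) -> ExpectancyMarks:
    """Arrows and tails contributed by one interval label.

    Initial intervals: L and S receive two arrows (implication of both
    direction and size), 0 receives one. Continuations: each ``+`` adds an
    arrow, each ``-`` a tail, and a reversal (R) adds a tail; P, ~, 0, and
    D add nothing. Retrospection has no effect.
    """
    if lbl.role is Role.INITIAL:
        arrows = 1 if lbl.initial_class == "0" else 2
        return ExpectancyMarks(arrows=arrows)
    arrows = 1 if lbl.size_class == "+" else 0
    tails = 1 if lbl.size_class == "-" else 0
    if lbl.direction_class == "R":
        tails += 1
    return ExpectancyMarks(arrows=arrows, tails=tails)


def _log_count(ratio: float, base: float) -> int:
    count = math.floor(math.log(ratio) / math.log(base) + _FLOOR_SNAP)
    return max(0, min(_MAX_COMMAS, count))


def duration_commas(d_p: float, d_c: float, c: float) -> int:
    """Commas of closure from durational increase.

    ``d_p``/``d_c`` are the preceding and current tone durations in
    seconds; ``c`` (> 1) is the lengthening factor worth one comma. The
    count is ``floor(log_c(d_c / d_p))`` clamped to [0, 3]; a tone no
    longer than its predecessor earns none.
    """
    if not (d_p > 0 and d_c > 0):
        raise InvalidInputError("durations must be positive")
    if not (c > 1):
        raise InvalidInputError("comma base must be > 1")
    return _log_count(d_c / d_p, c)


def duration_inverted_commas(d_p: float, d_c: float, r: float) -> int:
    """Inverted commas of counterclosure from durational decrease.

    One inverted comma per factor-of-``r`` shortening (0 < r < 1):
    ``floor(log(d_c / d_p) / log(r))`` clamped to [0, 3]. A tone no shorter
    than its predecessor earns none.
    """
    if not (d_p > 0 and d_c > 0):
        raise InvalidInputError("durations must be positive")
    if not (0 < r < 1):
        raise InvalidInputError("inverted-comma base must be in (0, 1)")
    return _log_count(d_c / d_p, r)


def descent_commas(lbl: IntervalLabel) -> int:
    """One comma of secondary closure for a descending L or descending +."""
    if not lbl.descending:
        return 0
    if lbl.role is Role.INITIAL:
        return 1 if lbl.initial_class == "L" else 0
    return 1 if lbl.size_class == "+" else 0


def net_implication(a: int, t: int, i: int, c: int) -> int:
    """Net implication ``(a - t) + (i - c)`` on one tone.

    ``a`` and ``t`` are arrows and tails accrued since the start of the
    grouping; ``i`` and ``c`` are the inverted commas and commas on this
    tone only.
    """
    for name, v in (("a", a), ("t", t), ("i", i), ("c", c)):
        if v < 0:
            raise InvalidInputError(f"count {name} must be >= 0, got {v}")
    return (a - t) + (i - c)
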