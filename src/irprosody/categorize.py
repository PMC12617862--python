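"""Categorical labeling of IR intervals.

Initial intervals of a grouping are labeled by absolute size (0 / S / L);
continuations are labeled by comparing the current transition with the one
before it, in direction (P = same, R = reversed, D = duplication of an
already-repeated pitch) and in size (+ distinctly larger, - distinctly
smaller, ~ non-distinctively similar, 0 unnoticeably different).

Boundary conventions (speech preset): the zero band is strict (< 0.2 st),
S is inclusive at its upper bound (<= 2.5 st) with L strictly above,
distinctness is inclusive (>= 2 st for P, >= 1.5 st for R), and size
equality is strict (< 0.2 st). The music preset makes S exclusive at 5 st
and treats equality bands as exact.
"""

from __future__ import annotations

from .model import (
    Direction,
    IntervalLabel,
    IntervalObservation,
    InvalidInputError,
    Role,
    Thresholds,
)

__all__ = ["classify_initial", "classify_continuation"]


def _initial_class(size_st: float, th: Thresholds) -> str:
    if th.is_zero_interval(size_st):
        return "0"
    if th.small_max_inclusive:
        return "S" if size_st <= th.small_max_st else "L"
    return "S" if size_st < th.small_max_st else "L"


def classify_initial(obs: IntervalObservation, th: Thresholds) -> IntervalLabel:
    """Label the first interval of a grouping.

    Returns an initial label 0, S, or L, with the descending flag set from
    the interval's direction and the repeated-pitch flag set when the
    second tone repeats the first's pitch (size below the zero threshold).
    """
    cls = _initial_class(obs.size_st, th)
    return IntervalLabel(
        role=Role.INITIAL,
        initial_class=cls,
        descending=obs.direction is Direction.DOWN,
        repeated_pitch=cls == "0",
    )


def _size_class(i1: float, i2: float, distinct_st: float, th: Thresholds) -> str:
    diff = i2 - i1
    if th.is_equal_size(diff):
        return "0"
    if abs(diff) < distinct_st:
        return "~"
    return "+" if diff > 0 else "-"


def classify_continuation(
    prev: IntervalObservation,
    curr: IntervalObservation,
    prev_label: IntervalLabel,
    th: Thresholds,
) -> IntervalLabel:
    """Label a continuation interval against the transition before it.

    ``prev_label`` is the label already assigned to ``prev``; when it is the
    grouping's initial label it also supplies the governing expectation used
    for the retrospective flag (an L followed by P, or an S followed by R,
    violates the initial implication and is parenthesized; retrospection has
    no effect on closure).

    Special cases:

    * duplication — both transitions repeat the pitch (three consecutive
      equal tones) -> ``D`` with size class 0;
    * no established direction — when the previous transition was a pitch
      repetition (or the current one is, without duplication), same-vs-
      reversed direction is undefined, so the label carries a size class
      only and no direction class (and contributes no directional arrow or
      tail).
    """
    if prev.to_index != curr.from_index:
        raise InvalidInputError("continuation must extend the previous transition")

    prev_zero = prev.direction is Direction.ZERO
    curr_zero = curr.direction is Direction.ZERO

    if prev_zero and curr_zero:
        return IntervalLabel(
            role=Role.CONTINUATION,
            direction_class="D",
            size_class="0",
            repeated_pitch=True,
        )

    if prev_zero or curr_zero:
        # no direction is established; classify size only (P thresholds,
        # the neutral default)
        return IntervalLabel(
            role=Role.CONTINUATION,
            direction_class=None,
            size_class=_size_class(prev.size_st, curr.size_st, th.p_distinct_st, th),
            descending=curr.direction is Direction.DOWN,
            repeated_pitch=curr_zero,
        )

    same_direction = prev.direction is curr.direction
    direction_class = "P" if same_direction else "R"
    distinct = th.p_distinct_st if same_direction else th.r_distinct_st
    size_class = _size_class(prev.size_st, curr.size_st, distinct, th)

    retrospective = prev_label.role is Role.INITIAL and (
        (prev_label.initial_class == "L" and direction_class == "P")
        or (prev_label.initial_class == "S" and direction_class == "R")
    )

    return IntervalLabel(
        role=Role.CONTINUATION,
        direction_class=direction_class,
        size_class=size_class,
        retrospective=retrospective,
        descending=curr.direction is Direction.DOWN,
    )
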