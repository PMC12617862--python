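"""Left-to-right grouping parser for one level of tones.

The scan opens a grouping on the level's first tone, labels each successive
interval (initial, then continuations), tallies arrows and tails, evaluates
per-tone secondary marks, and closes the grouping when net implication
falls to zero or below. Absent a separation break, the closing tone also
initiates the next grouping, so interior grouping boundaries are shared
tones.

Top-down break annotations modify the scan: time-in and time-out rewrite
the timeline before parsing; halts stop a grouping unclosed; suspends
releasably suppress closure and force a closing bracket on the following
tone; separations delay the next grouping's start past a closing tone;
forced/suppressed closure override the net test on a single tone; elevated
tones act as obligatory grouping boundaries on their origin level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .categorize import classify_continuation, classify_initial
from .expectancy import (
    arrows_for_label,
    descent_commas,
    duration_commas,
    duration_inverted_commas,
    net_implication,
)
from .model import (
    BreakAnnotation,
    BreakKind,
    ExpectancyMarks,
    Grouping,
    GroupingStatus,
    IntervalLabel,
    InvalidAnnotationError,
    InvalidInputError,
    Thresholds,
    Tone,
    observe_interval,
    validate_breaks,
    validate_tone_sequence,
)

__all__ = ["ParserState", "apply_break", "parse_level"]

_GAP_TOL = 1e-9


@dataclass
class ParserState:
    """Mutable state threaded through one level's parse.

    Gap breaks rewrite ``tones`` in place; tone breaks register directives
    that the scan consults at the corresponding positions.
    """

    tones: list[Tone]
    halts: set[int] = field(default_factory=set)
    separations: set[int] = field(default_factory=set)
    suspends: set[int] = field(default_factory=set)
    forced: set[int] = field(default_factory=set)
    suppressed: set[int] = field(default_factory=set)
    elevated: set[int] = field(default_factory=set)


def _gap_length(tones: list[Tone], gap: int) -> float:
    return tones[gap + 1].onset - tones[gap].end


def apply_break(state: ParserState, brk: BreakAnnotation) -> ParserState:
    """Fold one break annotation into the parser state.

    Time-in extends the preceding tone's duration over the silence;
    time-out deletes the silence, shifting all later tones earlier. The
    remaining kinds register per-position directives.
    """
    if brk.kind is BreakKind.TIME_IN or brk.kind is BreakKind.TIME_OUT:
        gap = _gap_length(state.tones, brk.position)
        if gap <= _GAP_TOL:
            raise InvalidAnnotationError(
                f"{brk.kind.value} at gap {brk.position}: no silence between the tones"
            )
        pre = state.tones[brk.position]
        if brk.kind is BreakKind.TIME_IN:
            state.tones[brk.position] = replace(pre, duration=pre.duration + gap)
        else:
            state.tones = state.tones[: brk.position + 1] + [
                t.shifted(-gap) for t in state.tones[brk.position + 1 :]
            ]
    elif brk.kind is BreakKind.HALT:
        state.halts.add(brk.position)
    elif brk.kind is BreakKind.SEPARATION:
        state.separations.add(brk.position)
    elif brk.kind is BreakKind.SUSPEND:
        state.suspends.add(brk.position)
    elif brk.kind is BreakKind.FORCE_CLOSURE:
        state.forced.add(brk.position)
    elif brk.kind is BreakKind.SUPPRESS_CLOSURE:
        state.suppressed.add(brk.position)
    else:  # elevation: obligatory boundary on the origin level
        state.elevated.add(brk.position)
    return state


def _prepare(tones: list[Tone], breaks: list[BreakAnnotation]) -> ParserState:
    state = ParserState(tones=list(tones))
    # apply gap (time) breaks right-to-left so positions stay valid while
    # the timeline is being rewritten, then register tone directives
    for brk in sorted(
        (b for b in breaks if b.at_gap), key=lambda b: -b.position
    ):
        apply_break(state, brk)
    for brk in (b for b in breaks if not b.at_gap):
        apply_break(state, brk)
    return state


class _OpenGrouping:
    """Tally bookkeeping for the grouping currently being built."""

    def __init__(self, start: int, shared_start: bool) -> None:
        self.indices = [start]
        self.shared_start = shared_start
        self.labels: list[IntervalLabel] = []
        self.marks: list[ExpectancyMarks] = [ExpectancyMarks()]
        self.nets: list[int] = [0]
        self.arrows = 0
        self.tails = 0
        self.prev_obs = None
        self.prev_label = None
        self.suspended_after: int | None = None

    def finalize(self, level: int, status: GroupingStatus) -> Grouping:
        return Grouping(
            level=level,
            tone_indices=self.indices,
            interval_labels=self.labels,
            marks=self.marks,
            nets=self.nets,
            status=status,
            suspended_after=self.suspended_after,
        )


def parse_level(
    tones: list[Tone],
    breaks: list[BreakAnnotation] | None = None,
    th: Thresholds | None = None,
) -> tuple[list[Grouping], list[Tone]]:
    """Parse one level's tones into bracketed groupings.

    Returns ``(groupings, adjusted_tones)`` where ``adjusted_tones`` is the
    level's tone sequence after time-in/time-out application (identical to
    the input when no gap breaks are present). Every tone belongs to at
    least one grouping; each grouping's final tone either satisfies
    ``net <= 0``, carries a halt/suspend/forced closure, or is the level's
    last tone (status ``open_at_end``).
    """
    if not tones:
        raise InvalidInputError("parse_level requires at least one tone")
    validate_tone_sequence(tones)
    breaks = breaks or []
    th = th or Thresholds.speech()
    validate_breaks(breaks, len(tones))

    state = _prepare(list(tones), breaks)
    seq = state.tones
    n = len(seq)
    level = seq[0].level

    groupings: list[Grouping] = []
    cur = _OpenGrouping(0, shared_start=False)
    suspend_pending = False  # suspend on the previous tone forces closure here

    for j in range(1, n):
        if cur.indices[-1] >= j:
            # the grouping was restarted at this tone (separation/halt);
            # there is no transition to evaluate into its own first tone
            continue
        prev_idx = cur.indices[-1]
        if prev_idx in state.halts and prev_idx == j - 1:
            # the grouping stops unclosed; no interval label spans the break
            groupings.append(cur.finalize(level, GroupingStatus.HALTED))
            cur = _OpenGrouping(j, shared_start=False)
            suspend_pending = False
            continue

        obs = observe_interval(seq[j - 1], seq[j], th, j - 1, j)
        if cur.prev_obs is None:
            label = classify_initial(obs, th)
        else:
            label = classify_continuation(cur.prev_obs, obs, cur.prev_label, th)

        delta = arrows_for_label(label)
        commas = duration_commas(seq[j - 1].duration, seq[j].duration, th.comma_base)
        commas = min(3, commas + descent_commas(label))
        inverted = duration_inverted_commas(
            seq[j - 1].duration, seq[j].duration, th.inverted_comma_base
        )
        cur.arrows += delta.arrows
        cur.tails += delta.tails
        net = net_implication(cur.arrows, cur.tails, inverted, commas)

        cur.indices.append(j)
        cur.labels.append(label)
        cur.marks.append(
            ExpectancyMarks(delta.arrows, delta.tails, commas, inverted)
        )
        cur.nets.append(net)
        cur.prev_obs = obs
        cur.prev_label = label

        suspended_here = j in state.suspends
        if suspended_here:
            cur.suspended_after = j
        forced = j in state.forced or j in state.elevated or suspend_pending
        suppressed = j in state.suppressed or suspended_here
        closing = forced or (net <= 0 and not suppressed)
        suspend_pending = suspended_here

        if closing:
            groupings.append(cur.finalize(level, GroupingStatus.CLOSED))
            if j == n - 1:
                cur = None
                break
            if j in state.separations or j in state.halts:
                # the next grouping starts on the *following* tone; a halt
                # at a closing tone acts as a separation
                cur = _OpenGrouping(j + 1, shared_start=False)
            else:
                cur = _OpenGrouping(j, shared_start=True)
            suspend_pending = False

    if cur is not None:
        if len(cur.indices) == 1 and cur.shared_start:
            pass  # final closure already covered this tone
        elif cur.suspended_after == cur.indices[-1]:
            groupings.append(cur.finalize(level, GroupingStatus.SUSPENDED))
        elif cur.indices[-1] in state.halts:
            groupings.append(cur.finalize(level, GroupingStatus.HALTED))
        else:
            groupings.append(cur.finalize(level, GroupingStatus.OPEN_AT_END))

    return groupings, seq
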