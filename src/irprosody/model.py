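"""Core data model for Implication-Realization (IR) prosody parsing.

The model treats a spoken (or sung) utterance as a sequence of discrete
*tones* — perceived pitch events, normally one per syllable — each with an
onset, a duration, and a single target pitch. Pitch is measured in semitones
relative to 100 Hz, ``st = 12 * log2(f / 100)``, so that interval arithmetic
is additive and speaker-register differences reduce to an offset.

Everything downstream of the raw tones is symbolic: categorical interval
labels, per-tone expectancy marks (arrows, tails, commas, inverted commas),
bracketed groupings, top-down break annotations, and the multi-level parse
tree they assemble into.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

__all__ = [
    "BreakAnnotation",
    "BreakKind",
    "Direction",
    "ExpectancyMarks",
    "Grouping",
    "GroupingStatus",
    "IntervalLabel",
    "IntervalObservation",
    "InvalidAnnotationError",
    "InvalidInputError",
    "Level",
    "ParseTree",
    "Thresholds",
    "Tone",
    "from_semitones",
    "to_semitones",
]

SEMITONE_REF_HZ = 100.0


class InvalidInputError(ValueError):
    """A value or combination of values violates a precondition."""


class InvalidAnnotationError(ValueError):
    """A break annotation is malformed, misplaced, or conflicting."""


def to_semitones(pitch_hz: float) -> float:
    """Convert a frequency in Hz to semitones relative to 100 Hz.

    Parameters
    ----------
    pitch_hz : float
        Frequency in Hz; must be strictly positive.

    Returns
    -------
    float
        ``12 * log2(pitch_hz / 100)``. 100 Hz maps to 0 st, 200 Hz to 12 st.
    """
    if not (pitch_hz > 0) or not math.isfinite(pitch_hz):
        raise InvalidInputError(f"pitch must be a positive frequency, got {pitch_hz!r}")
    return 12.0 * math.log2(pitch_hz / SEMITONE_REF_HZ)


def from_semitones(pitch_st: float) -> float:
    """Inverse of :func:`to_semitones`: semitones re 100 Hz back to Hz."""
    if not math.isfinite(pitch_st):
        raise InvalidInputError(f"pitch must be a finite semitone value, got {pitch_st!r}")
    return SEMITONE_REF_HZ * 2.0 ** (pitch_st / 12.0)


class Direction(str, Enum):
    UP = "up"
    DOWN = "down"
    ZERO = "zero"


class GroupingStatus(str, Enum):
    CLOSED = "closed"
    HALTED = "halted"
    SUSPENDED = "suspended"
    OPEN_AT_END = "open_at_end"


class BreakKind(str, Enum):
    """Top-down break and elevation annotations.

    Silence handling: ``TIME_IN`` folds a silence into the preceding tone's
    duration; ``TIME_OUT`` deletes the silence from the timeline. Implicative
    interruptions: ``SEPARATION`` delays the next grouping's start past the
    closing tone; ``HALT`` stops a grouping unclosed; ``SUSPEND`` releasably
    suppresses implication and forces a closing bracket on the following
    tone. ``ELEVATE_UP``/``ELEVATE_DOWN`` promote a tone directly to the
    next level. ``FORCE_CLOSURE``/``SUPPRESS_CLOSURE`` override the
    net-implication test on one tone.
    """

    TIME_IN = "time_in"
    TIME_OUT = "time_out"
    SEPARATION = "separation"
    HALT = "halt"
    SUSPEND = "suspend"
    ELEVATE_UP = "elevate_up"
    ELEVATE_DOWN = "elevate_down"
    FORCE_CLOSURE = "force_closure"
    SUPPRESS_CLOSURE = "suppress_closure"


#: break kinds that attach to a silence gap (gap index i = between tones i, i+1)
GAP_BREAKS = frozenset({BreakKind.TIME_IN, BreakKind.TIME_OUT})
#: break kinds that attach to a tone
TONE_BREAKS = frozenset(BreakKind) - GAP_BREAKS
#: tone-break kinds that are mutually exclusive at one position
_EXCLUSIVE_TONE_BREAKS = frozenset(
    {
        BreakKind.SEPARATION,
        BreakKind.HALT,
        BreakKind.SUSPEND,
        BreakKind.FORCE_CLOSURE,
        BreakKind.SUPPRESS_CLOSURE,
    }
)

_ST_TOL = 1e-9


@dataclass(frozen=True)
class Tone:
    """A perceived pitch event.

    ``duration`` follows the melodic convention: it runs from the tone's
    onset (its P-center) to the onset of the next tone or of a silence —
    never from orthographic syllable edges or vowel length.
    """

    label: str
    onset: float
    duration: float
    pitch_st: float
    level: int = 1
    source_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.onset < 0 or not math.isfinite(self.onset):
            raise InvalidInputError(f"tone onset must be >= 0, got {self.onset!r}")
        if not (self.duration > 0) or not math.isfinite(self.duration):
            raise InvalidInputError(f"tone duration must be > 0, got {self.duration!r}")
        if not math.isfinite(self.pitch_st):
            raise InvalidInputError(f"tone pitch must be finite, got {self.pitch_st!r}")
        if self.level < 1:
            raise InvalidInputError(f"tone level must be >= 1, got {self.level!r}")

    @property
    def pitch_hz(self) -> float:
        return from_semitones(self.pitch_st)

    @property
    def end(self) -> float:
        return self.onset + self.duration

    @classmethod
    def from_hz(
        cls,
        label: str,
        onset: float,
        duration: float,
        pitch_hz: float,
        level: int = 1,
        source_index: Optional[int] = None,
    ) -> "Tone":
        return cls(label, onset, duration, to_semitones(pitch_hz), level, source_index)

    def shifted(self, dt: float) -> "Tone":
        return replace(self, onset=self.onset + dt)


def validate_tone_sequence(tones: Sequence[Tone]) -> None:
    """Check strict onset ordering and non-overlap of a one-level sequence."""
    for i in range(1, len(tones)):
        prev, cur = tones[i - 1], tones[i]
        if cur.onset <= prev.onset:
            raise InvalidInputError(
                f"tones must be strictly ordered by onset: tone {i} at {cur.onset} "
                f"does not follow tone {i - 1} at {prev.onset}"
            )
        if prev.end > cur.onset + _ST_TOL:
            raise InvalidInputError(
                f"tones must not overlap: tone {i - 1} ends at {prev.end} after "
                f"tone {i} starts at {cur.onset}"
            )


def silences(tones: Sequence[Tone], tol: float = 1e-9) -> list[tuple[float, float]]:
    """Silence gaps ``(start, end)`` between consecutive tones of one level."""
    gaps = []
    for i in range(1, len(tones)):
        if tones[i].onset - tones[i - 1].end > tol:
            gaps.append((tones[i - 1].end, tones[i].onset))
    return gaps


@dataclass(frozen=True)
class Thresholds:
    """Categorical thresholds of the IR interval calculus.

    All pitch thresholds are in semitones; they must be held constant over
    the course of an analysis. ``small_max_inclusive`` records the boundary
    convention between S and L: in the speech preset the small category is
    inclusive at its upper bound (S <= 2.5 st, L > 2.5 st), in the music
    preset it is exclusive (S < 5 st, L >= 5 st).

    ``equality_st`` governs the P0/R0 (unnoticeable size difference) band;
    a value of 0 means exact equality, as in the music preset where P0 is
    the degenerate special case of P~.
    """

    zero_st: float = 0.2
    small_max_st: float = 2.5
    small_max_inclusive: bool = True
    p_distinct_st: float = 2.0
    r_distinct_st: float = 1.5
    equality_st: float = 0.2
    comma_base: float = 1.2
    inverted_comma_base: float = 0.8
    name: str = "speech"

    def __post_init__(self) -> None:
        if self.zero_st < 0 or self.equality_st < 0:
            raise InvalidInputError("zero/equality thresholds must be >= 0")
        for attr in ("small_max_st", "p_distinct_st", "r_distinct_st"):
            if not (getattr(self, attr) > 0):
                raise InvalidInputError(f"{attr} must be > 0")
        if not (self.comma_base > 1):
            raise InvalidInputError("comma_base must be > 1")
        if not (0 < self.inverted_comma_base < 1):
            raise InvalidInputError("inverted_comma_base must be in (0, 1)")

    def is_zero_interval(self, size_st: float) -> bool:
        if self.zero_st == 0:
            return size_st == 0
        return size_st < self.zero_st

    def is_equal_size(self, diff_st: float) -> bool:
        if self.equality_st == 0:
            return diff_st == 0
        return abs(diff_st) < self.equality_st

    @classmethod
    def speech(cls) -> "Thresholds":
        return cls()

    @classmethod
    def music(cls) -> "Thresholds":
        return cls(
            zero_st=0.0,
            small_max_st=5.0,
            small_max_inclusive=False,
            p_distinct_st=4.0,
            r_distinct_st=3.0,
            equality_st=0.0,
            comma_base=1.225,
            inverted_comma_base=0.8,
            name="music",
        )

    @classmethod
    def preset(cls, name: str) -> "Thresholds":
        try:
            return {"speech": cls.speech, "music": cls.music}[name]()
        except KeyError:
            raise InvalidInputError(f"unknown threshold preset {name!r}") from None


@dataclass(frozen=True)
class IntervalObservation:
    """Raw size/direction of one tone-to-tone transition.

    ``direction`` is ``ZERO`` exactly when the size falls below the
    configured zero threshold (a perceived pitch repetition).
    """

    size_st: float
    direction: Direction
    from_index: int
    to_index: int

    def __post_init__(self) -> None:
        if self.size_st < 0:
            raise InvalidInputError("interval size must be an absolute value >= 0")


def observe_interval(
    t1: Tone, t2: Tone, th: Thresholds, i1: int = 0, i2: int = 1
) -> IntervalObservation:
    """Measure the interval from ``t1`` to ``t2`` under thresholds ``th``.

    The direction is ``zero`` iff the absolute semitone difference falls
    below the zero threshold, else ``up``/``down`` by sign.
    """
    if t1.level != t2.level:
        raise InvalidInputError("interval tones must lie on the same level")
    if t1.onset >= t2.onset:
        raise InvalidInputError("t1 must precede t2 (and differ from it)")
    delta = t2.pitch_st - t1.pitch_st
    size = abs(delta)
    if th.is_zero_interval(size):
        direction = Direction.ZERO
    else:
        direction = Direction.UP if delta > 0 else Direction.DOWN
    return IntervalObservation(size, direction, i1, i2)


class Role(str, Enum):
    INITIAL = "initial"
    CONTINUATION = "continuation"


@dataclass(frozen=True)
class IntervalLabel:
    """Categorical IR label of an interval.

    Initial intervals carry ``initial_class`` (0 / S / L); continuations
    carry ``direction_class`` (P / R / D, or None when no direction is
    established) and ``size_class`` (+ / - / ~ / 0). ``retrospective``
    labels are rendered in parentheses, ``descending`` ones in italics,
    and ``repeated_pitch`` transitions are underlined.
    """

    role: Role
    initial_class: Optional[str] = None  # "0" | "S" | "L"
    direction_class: Optional[str] = None  # "P" | "R" | "D"
    size_class: Optional[str] = None  # "+" | "-" | "~" | "0"
    retrospective: bool = False
    descending: bool = False
    repeated_pitch: bool = False

    def __post_init__(self) -> None:
        if self.role is Role.INITIAL:
            if self.initial_class not in {"0", "S", "L"}:
                raise InvalidInputError("initial label requires initial_class in {0,S,L}")
            if self.direction_class is not None or self.size_class is not None:
                raise InvalidInputError("initial label must not carry continuation classes")
        else:
            if self.initial_class is not None:
                raise InvalidInputError("continuation label must not carry initial_class")
            if self.size_class not in {"+", "-", "~", "0"}:
                raise InvalidInputError("continuation label requires size_class")
            if self.direction_class not in {"P", "R", "D", None}:
                raise InvalidInputError("direction_class must be P, R, D or None")
            if self.direction_class == "D" and self.size_class != "0":
                raise InvalidInputError("duplication (D) implies size_class '0'")

    @property
    def symbol(self) -> str:
        """Plain-text symbol, e.g. ``L``, ``R-``, ``(P~)``, ``D``."""
        if self.role is Role.INITIAL:
            core = self.initial_class or "?"
        elif self.direction_class == "D":
            core = "D"
        else:
            core = (self.direction_class or "") + (self.size_class or "")
        if self.retrospective:
            core = f"({core})"
        return core


@dataclass(frozen=True)
class ExpectancyMarks:
    """Arrows/tails/commas/inverted commas carried by one tone.

    Arrows (a) and tails (t) are interval-driven and accumulate over a
    grouping; commas (c) and inverted commas (i) are secondary (duration,
    descent) and apply to their own tone only. Net implication on a tone is
    ``(a - t) + (i - c)`` with a/t cumulative and i/c tone-local. Comma and
    inverted-comma counts are capped at 3 (distinctive, highly distinctive,
    exceedingly distinctive).
    """

    arrows: int = 0
    tails: int = 0
    commas: int = 0
    inverted_commas: int = 0

    def __post_init__(self) -> None:
        for name in ("arrows", "tails", "commas", "inverted_commas"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise InvalidInputError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.commas > 3 or self.inverted_commas > 3:
            raise InvalidInputError("comma/inverted-comma counts are capped at 3")

    def __add__(self, other: "ExpectancyMarks") -> "ExpectancyMarks":
        return ExpectancyMarks(
            self.arrows + other.arrows,
            self.tails + other.tails,
            min(3, self.commas + other.commas),
            min(3, self.inverted_commas + other.inverted_commas),
        )


@dataclass(frozen=True)
class BreakAnnotation:
    """A top-down annotation at a tone or inter-tone gap on one level."""

    kind: BreakKind
    position: int
    level: int = 1

    def __post_init__(self) -> None:
        if self.position < 0:
            raise InvalidAnnotationError("break position must be >= 0")
        if self.level < 1:
            raise InvalidAnnotationError("break level must be >= 1")

    @property
    def at_gap(self) -> bool:
        return self.kind in GAP_BREAKS


def validate_breaks(breaks: Sequence[BreakAnnotation], n_tones: int) -> None:
    """Validate positions and mutual exclusion of one level's annotations."""
    seen_tone: dict[int, BreakKind] = {}
    seen_gap: dict[int, BreakKind] = {}
    for brk in breaks:
        if brk.at_gap:
            if not (0 <= brk.position < n_tones - 1):
                raise InvalidAnnotationError(
                    f"{brk.kind.value} at gap {brk.position}: no such gap "
                    f"(level has {n_tones} tones)"
                )
            if brk.position in seen_gap and seen_gap[brk.position] != brk.kind:
                raise InvalidAnnotationError(
                    f"conflicting time annotations at gap {brk.position}"
                )
            seen_gap[brk.position] = brk.kind
        else:
            if not (0 <= brk.position < n_tones):
                raise InvalidAnnotationError(
                    f"{brk.kind.value} at tone {brk.position}: no such tone "
                    f"(level has {n_tones} tones)"
                )
            if brk.kind in _EXCLUSIVE_TONE_BREAKS:
                prior = seen_tone.get(brk.position)
                compatible = {prior, brk.kind} == {
                    BreakKind.SEPARATION,
                    BreakKind.FORCE_CLOSURE,
                }  # a forced closure may be combined with a separation
                if prior is not None and prior != brk.kind and not compatible:
                    raise InvalidAnnotationError(
                        f"conflicting break annotations at tone {brk.position}: "
                        f"{prior.value} vs {brk.kind.value}"
                    )
                if prior is None:
                    seen_tone[brk.position] = brk.kind


@dataclass
class Grouping:
    """A bracketed span of tones on one level.

    ``tone_indices`` index into the level's tone list. ``interval_labels``
    align with the transitions inside the grouping (one fewer than tones),
    and ``marks``/``nets`` align with the tones: the initial tone carries
    empty marks because every grouping starts with zero implication.
    """

    level: int
    tone_indices: list[int]
    interval_labels: list[IntervalLabel] = field(default_factory=list)
    marks: list[ExpectancyMarks] = field(default_factory=list)
    nets: list[int] = field(default_factory=list)
    status: GroupingStatus = GroupingStatus.CLOSED
    suspended_after: Optional[int] = None  # tone index carrying releasable suppression

    def __post_init__(self) -> None:
        if not self.tone_indices:
            raise InvalidInputError("a grouping must span at least one tone")
        if self.interval_labels and len(self.interval_labels) != len(self.tone_indices) - 1:
            raise InvalidInputError("interval_labels must align with transitions")

    @property
    def start(self) -> int:
        return self.tone_indices[0]

    @property
    def end(self) -> int:
        return self.tone_indices[-1]


@dataclass
class Level:
    """One level of the parse: its tones, groupings, and applied breaks."""

    index: int
    tones: list[Tone]
    groupings: list[Grouping] = field(default_factory=list)
    breaks: list[BreakAnnotation] = field(default_factory=list)


@dataclass
class ParseTree:
    """Ordered levels of tones with their groupings and break annotations."""

    levels: list[Level] = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds.speech)
    provenance: list[str] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level(self, k: int) -> Level:
        """Level by 1-based index (Level 1 = surface)."""
        return self.levels[k - 1]

    def log(self, message: str) -> None:
        self.provenance.append(message)
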