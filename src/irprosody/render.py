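"""Text rendering of multi-level IR parse diagrams.

One block per level, deepest level last. Each tone is rendered as a token:
its syllable label, then (for non-initial tones of a grouping) a colon,
the interval symbol, and the tone's expectancy marks. Symbol conventions:

==================  ===========================  =========
feature             ASCII                        Unicode
==================  ===========================  =========
arrow (expectancy)  ``^``                        ``↑``
tail (closure)      ``v``                        ``↓``
comma               ``,``                        ``,``
inverted comma      ``'``                        ``‘``
open bracket        ``[``                        ``[``
close bracket       ``]``                        ``]``
close + re-open     ``][``                       ``][``
halted end          ``|``                        ``|``
releasable suppr.   ``%``                        ``⌐``
retrospective       parentheses                  same
descending          ``*`` prefix (italics)       same
repeated pitch      ``_`` suffix (underline)     same
duplication         ``D``                        same
==================  ===========================  =========

Marks are printed in the order inverted commas, arrows, tails, commas.
Rendering is a pure function of the parse tree.
"""

from __future__ import annotations

from .model import (
    ExpectancyMarks,
    Grouping,
    GroupingStatus,
    IntervalLabel,
    Level,
    ParseTree,
)

__all__ = ["render_text", "tone_token"]

_ASCII = {"arrow": "^", "tail": "v", "comma": ",", "inverted": "'", "broken": "%"}
_UNICODE = {"arrow": "↑", "tail": "↓", "comma": ",", "inverted": "‘", "broken": "⌐"}


def _label_text(lbl: IntervalLabel) -> str:
    core = lbl.symbol
    if lbl.descending:
        core = "*" + core
    if lbl.repeated_pitch:
        core = core + "_"
    return core


def _marks_text(marks: ExpectancyMarks, g: dict) -> str:
    return (
        g["inverted"] * marks.inverted_commas
        + g["arrow"] * marks.arrows
        + g["tail"] * marks.tails
        + g["comma"] * marks.commas
    )


def tone_token(
    label: str,
    interval_label: IntervalLabel | None,
    marks: ExpectancyMarks | None,
    unicode: bool = False,
) -> str:
    """Render one tone's core token (no brackets)."""
    glyphs = _UNICODE if unicode else _ASCII
    if interval_label is None:
        return label
    return f"{label}:{_label_text(interval_label)}{_marks_text(marks, glyphs)}"


def _level_annotations(level: Level) -> dict[int, tuple[IntervalLabel, ExpectancyMarks]]:
    """Per tone index: the label/marks it carries as a grouping member."""
    ann: dict[int, tuple[IntervalLabel, ExpectancyMarks]] = {}
    for g in level.groupings:
        for pos in range(1, len(g.tone_indices)):
            ann[g.tone_indices[pos]] = (g.interval_labels[pos - 1], g.marks[pos])
    return ann


def _close_glyph(g: Grouping, glyphs: dict) -> str:
    if g.status is GroupingStatus.CLOSED:
        return "]"
    if g.status is GroupingStatus.HALTED:
        return "|"
    if g.status is GroupingStatus.SUSPENDED:
        return glyphs["broken"]
    return ""  # open at end: bracket never closes


def render_level(level: Level, unicode: bool = False) -> str:
    """Render one level's token stream."""
    glyphs = _UNICODE if unicode else _ASCII
    ann = _level_annotations(level)
    opens: dict[int, int] = {}
    closes: dict[int, str] = {}
    suppressed: set[int] = set()
    for g in level.groupings:
        opens[g.start] = opens.get(g.start, 0) + 1
        glyph = _close_glyph(g, glyphs)
        if glyph:
            closes[g.tone_indices[-1]] = glyph
        if g.suspended_after is not None and g.suspended_after != g.tone_indices[-1]:
            suppressed.add(g.suspended_after)

    tokens: list[str] = []
    for i, tone in enumerate(level.tones):
        pair = ann.get(i)
        core = tone_token(
            tone.label, pair[0] if pair else None, pair[1] if pair else None, unicode
        )
        closing = closes.get(i, "")
        opening = "[" * opens.get(i, 0)
        if closing and opening:
            token = core + closing + opening  # shared boundary: "...]["
        else:
            token = opening + core + closing
        if i in suppressed:
            token += glyphs["broken"]
        tokens.append(token)
    return " ".join(tokens)


def render_text(parse: ParseTree, unicode: bool = False) -> str:
    """Render the full multi-level diagram, surface first, deepest last."""
    out = [f"IR parse ({parse.thresholds.name} thresholds, {parse.n_levels} levels)"]
    for level in parse.levels:
        if not level.tones:
            continue
        out.append(f"Level {level.index}: {render_level(level, unicode)}")
    return "\n".join(out) + "\n"
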