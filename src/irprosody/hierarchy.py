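"""Emergent levels: from grouping boundaries to a multi-level parse tree.

Each start or end of a grouping on level *k* appears on level *k+1* as a
tone sharing the source tone's pitch and onset; each emergent tone ends at
the onset of the next emergent tone or the next silence on the level below.
The emergent level is parsed with the same rules, and the process iterates
until a level would hold fewer than three tones (no classifiable
continuation exists), reproduce the level below unchanged, or the level cap
is reached.

A replication-avoidance rule prunes the start of a candidate level: its
initial tone is dropped when the grouping it would open consists of exactly
the same tones (by onset) as a grouping already present one level below, so
the hierarchy never restates a structure it has already expressed.
"""

from __future__ import annotations

import math
from dataclasses import replace

from .model import (
    BreakAnnotation,
    BreakKind,
    Grouping,
    InvalidInputError,
    Level,
    ParseTree,
    Thresholds,
    Tone,
    silences,
    validate_tone_sequence,
)
from .parser import parse_level

__all__ = ["build_hierarchy", "emerge_level", "suppress_replication"]

_T_TOL = 1e-9
_ELEVATIONS = {BreakKind.ELEVATE_UP, BreakKind.ELEVATE_DOWN}


def emerge_level(
    groupings: list[Grouping],
    prior_tones: list[Tone],
    elevated: set[int] | None = None,
    new_level: int | None = None,
) -> list[Tone]:
    """Promote grouping-boundary tones of one level to the next.

    Boundary tones shared between adjacent groupings emerge once. Tones
    carrying an elevation annotation are always promoted. Each emergent
    tone's duration runs to the next emergent onset or the next silence on
    the source level, whichever comes first, falling back to the end of the
    source level's last tone.
    """
    if not groupings:
        return []
    if new_level is None:
        new_level = prior_tones[0].level + 1
    boundary = set(elevated or ())
    for g in groupings:
        boundary.add(g.start)
        boundary.add(g.end)
    indices = sorted(boundary)

    gap_starts = [start for start, _ in silences(prior_tones)]
    speech_end = prior_tones[-1].end

    emergent: list[Tone] = []
    for pos, idx in enumerate(indices):
        src = prior_tones[idx]
        if pos + 1 < len(indices):
            end = prior_tones[indices[pos + 1]].onset
        else:
            end = speech_end
        for s in gap_starts:
            if src.onset + _T_TOL < s < end:
                end = s
                break
        emergent.append(
            Tone(
                label=src.label,
                onset=src.onset,
                duration=end - src.onset,
                pitch_st=src.pitch_st,
                level=new_level,
                source_index=idx,
            )
        )
    return emergent


def _onsets(tones: list[Tone]) -> tuple[float, ...]:
    return tuple(t.onset for t in tones)


def _same_onsets(a: tuple[float, ...], b: tuple[float, ...]) -> bool:
    return len(a) == len(b) and all(
        math.isclose(x, y, rel_tol=0.0, abs_tol=_T_TOL) for x, y in zip(a, b)
    )


def suppress_replication(
    candidate: list[Tone],
    below_tones: list[Tone],
    below_groupings: list[Grouping],
    th: Thresholds,
) -> list[Tone]:
    """Drop a candidate level's initial tone(s) that would only replicate.

    The candidate is parsed bottom-up (without top-down edits); if its
    first grouping spans exactly the same tones, by onset, as a grouping
    one level below, the candidate's initial tone is dropped and the check
    repeats on the remainder.
    """
    below_sets = [
        tuple(below_tones[i].onset for i in g.tone_indices) for g in below_groupings
    ]
    cand = list(candidate)
    while len(cand) >= 2:
        groupings, _ = parse_level(cand, [], th)
        first = tuple(cand[i].onset for i in groupings[0].tone_indices)
        if len(first) < 2 or not any(_same_onsets(first, b) for b in below_sets):
            break
        cand = cand[1:]
    return cand


def build_hierarchy(
    surface: list[Tone],
    breaks: list[BreakAnnotation] | None = None,
    th: Thresholds | None = None,
    max_levels: int = 8,
) -> ParseTree:
    """Parse a surface tone sequence into a full multi-level IR hierarchy.

    ``breaks`` carry a ``level`` field and are applied when their level is
    parsed; elevation annotations make their tones obligatory grouping
    boundaries on the origin level and guarantee their promotion.
    """
    if max_levels < 1:
        raise InvalidInputError("max_levels must be >= 1")
    if not surface:
        raise InvalidInputError("build_hierarchy requires at least one tone")
    validate_tone_sequence(surface)
    breaks = breaks or []
    th = th or Thresholds.speech()

    tree = ParseTree(thresholds=th)
    tones = [replace(t, level=1) for t in surface]
    k = 1
    while True:
        level_breaks = [b for b in breaks if b.level == k]
        groupings, adjusted = parse_level(tones, level_breaks, th)
        tree.levels.append(Level(k, adjusted, groupings, level_breaks))
        tree.log(f"level {k}: {len(adjusted)} tones, {len(groupings)} groupings")
        if len(adjusted) < 3:
            break
        if k >= max_levels:
            tree.log(f"stopped at the configured cap of {max_levels} levels")
            break
        elevated = {
            b.position for b in level_breaks if b.kind in _ELEVATIONS
        }
        candidate = emerge_level(groupings, adjusted, elevated, new_level=k + 1)
        if _same_onsets(_onsets(candidate), _onsets(adjusted)):
            tree.log(f"level {k + 1} would replicate level {k}; stopping")
            break
        pruned = suppress_replication(candidate, adjusted, groupings, th)
        if len(pruned) < len(candidate):
            dropped = len(candidate) - len(pruned)
            tree.log(
                f"level {k + 1}: suppressed {dropped} replicating initial tone(s)"
            )
        if not pruned or _same_onsets(_onsets(pruned), _onsets(adjusted)):
            break
        tones = pruned
        k += 1
    return tree
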