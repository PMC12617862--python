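"""Reading and writing tone tables, TextGrids, and parse exports.

Tone tables are CSVs with one row per tone: ``utterance`` (optional when
the file holds a single sequence), ``label``, ``start``, ``end`` (seconds),
``pitch`` (Hz or semitones re 100 Hz, auto-detected unless a ``unit``
column or an explicit override says otherwise), and optional ``break`` /
``break_level`` columns carrying top-down glyphs. Intervals are half-open
``[start, end)``; a gap between one row's end and the next row's start is
a silence.

TextGrids must contain a tone/syllable interval tier (empty intervals are
silences) and a pitch tier; tiers named ``topdown`` (optionally suffixed
with a level number, e.g. ``topdown2``) carry break glyphs.

Break glyphs: ``- - -`` time-in, ``…`` time-out, ``/`` separation, ``|``
halt, ``#`` (or ``%``) suspend, ``<``/``>`` elevation, ``!]`` forced
closure, ``!x`` suppressed closure.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import praat_textgrid as ptg
from .model import (
    BreakAnnotation,
    BreakKind,
    ExpectancyMarks,
    Grouping,
    GroupingStatus,
    IntervalLabel,
    InvalidAnnotationError,
    InvalidInputError,
    Level,
    ParseTree,
    Role,
    Thresholds,
    Tone,
    to_semitones,
)
from .render import tone_token

__all__ = [
    "FormatError",
    "estimate_target_pitch",
    "glyph_for_kind",
    "kind_for_glyph",
    "read_parse",
    "read_textgrid",
    "read_tone_csv",
    "read_utterances_csv",
    "write_parse",
    "write_tone_csv",
]


class FormatError(ValueError):
    """A file does not conform to the expected schema."""


#: pitch values above this are taken to be Hz, at or below it semitones
HZ_AUTO_THRESHOLD = 45.0

_GLYPH_TO_KIND = {
    "- - -": BreakKind.TIME_IN,
    "---": BreakKind.TIME_IN,
    "…": BreakKind.TIME_OUT,
    "...": BreakKind.TIME_OUT,
    "/": BreakKind.SEPARATION,
    "|": BreakKind.HALT,
    "#": BreakKind.SUSPEND,
    "%": BreakKind.SUSPEND,
    "<": BreakKind.ELEVATE_UP,
    ">": BreakKind.ELEVATE_DOWN,
    "!]": BreakKind.FORCE_CLOSURE,
    "!x": BreakKind.SUPPRESS_CLOSURE,
}
_KIND_TO_GLYPH = {
    BreakKind.TIME_IN: "- - -",
    BreakKind.TIME_OUT: "...",
    BreakKind.SEPARATION: "/",
    BreakKind.HALT: "|",
    BreakKind.SUSPEND: "#",
    BreakKind.ELEVATE_UP: "<",
    BreakKind.ELEVATE_DOWN: ">",
    BreakKind.FORCE_CLOSURE: "!]",
    BreakKind.SUPPRESS_CLOSURE: "!x",
}


def kind_for_glyph(glyph: str) -> BreakKind:
    try:
        return _GLYPH_TO_KIND[glyph.strip()]
    except KeyError:
        raise InvalidAnnotationError(f"unknown break glyph {glyph!r}") from None


def glyph_for_kind(kind: BreakKind) -> str:
    return _KIND_TO_GLYPH[kind]


def _pitch_to_st(value: float, unit: str) -> float:
    if unit == "hz":
        return to_semitones(value)
    if unit == "st":
        return float(value)
    # auto-detection by magnitude: spoken f0 in Hz is far above the
    # plausible semitone range re 100 Hz
    return to_semitones(value) if value > HZ_AUTO_THRESHOLD else float(value)


# ---------------------------------------------------------------------------
# tone tables (CSV)
# ---------------------------------------------------------------------------


def _frame_to_tones(
    df: pd.DataFrame, pitch_unit: str, where: str
) -> tuple[list[Tone], list[BreakAnnotation]]:
    if not df["start"].is_monotonic_increasing:
        warnings.warn(f"{where}: rows out of order; re-sorting by start time")
        df = df.sort_values("start", kind="stable")
    starts = df["start"].to_numpy(float)
    ends = df["end"].to_numpy(float)
    overlaps = [
        int(df.index[i])
        for i in range(1, len(df))
        if ends[i - 1] > starts[i] + 1e-9
    ]
    if overlaps:
        raise FormatError(f"{where}: overlapping intervals at rows {overlaps}")

    tones = []
    breaks: list[BreakAnnotation] = []
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            pitch_st = _pitch_to_st(float(row["pitch"]), _row_unit(row, pitch_unit))
        except (ValueError, InvalidInputError) as exc:
            raise FormatError(f"{where}: bad pitch in row {row.name}: {exc}") from None
        tones.append(
            Tone(
                label=str(row["label"]),
                onset=float(row["start"]),
                duration=float(row["end"]) - float(row["start"]),
                pitch_st=pitch_st,
            )
        )
        cell = row.get("break")
        if isinstance(cell, str) and cell.strip():
            level = int(row.get("break_level", 1) or 1)
            for glyph in cell.split(";"):
                if glyph.strip():
                    breaks.append(
                        BreakAnnotation(kind_for_glyph(glyph), i, level)
                    )
    return tones, breaks


def _row_unit(row: pd.Series, default: str) -> str:
    unit = row.get("unit")
    if isinstance(unit, str) and unit.strip():
        u = unit.strip().lower()
        if u not in {"hz", "st"}:
            raise FormatError(f"unknown pitch unit {unit!r} (expected hz or st)")
        return u
    return default


def _load_tone_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = {"label", "start", "end", "pitch"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_utterances_csv(
    path: str | Path, pitch_unit: str = "auto"
) -> dict[str, tuple[list[Tone], list[BreakAnnotation]]]:
    """Read a tone-table CSV as ``utterance id -> (tones, breaks)``."""
    df = _load_tone_frame(path)
    if "utterance" in df.columns:
        return {
            str(name): _frame_to_tones(g, pitch_unit, f"{path}[{name}]")
            for name, g in df.groupby("utterance", sort=False)
        }
    return {"": _frame_to_tones(df, pitch_unit, str(path))}


def read_tone_csv(
    path: str | Path, utterance: str | None = None, pitch_unit: str = "auto"
) -> tuple[list[Tone], list[BreakAnnotation]]:
    """Read one utterance's tones (and optional breaks) from a tone table.

    When the file holds several utterances, ``utterance`` selects one.
    """
    table = read_utterances_csv(path, pitch_unit)
    if utterance is None:
        if len(table) > 1:
            raise FormatError(
                f"{path} holds utterances {sorted(table)}; pass utterance="
            )
        return next(iter(table.values()))
    try:
        return table[utterance]
    except KeyError:
        raise FormatError(
            f"{path}: no utterance {utterance!r} (has {sorted(table)})"
        ) from None


def write_tone_csv(
    table: dict[str, tuple[list[Tone], list[BreakAnnotation]]], path: str | Path
) -> None:
    """Write utterances to the tone-table schema (pitch in semitones)."""
    rows = []
    for name, (tones, breaks) in table.items():
        cell: dict[int, list[str]] = {}
        for brk in breaks:
            cell.setdefault(brk.position, []).append(glyph_for_kind(brk.kind))
        for i, t in enumerate(tones):
            rows.append(
                {
                    "utterance": name,
                    "label": t.label,
                    "start": t.onset,
                    "end": t.end,
                    "pitch": t.pitch_st,
                    "unit": "st",
                    "break": ";".join(cell.get(i, [])),
                    "break_level": 1,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# TextGrid
# ---------------------------------------------------------------------------


def read_textgrid(
    path: str | Path,
    tone_tier: str | None = None,
    pitch_tier: str | None = None,
    pitch_unit: str = "auto",
) -> tuple[list[Tone], list[BreakAnnotation]]:
    """Read tones and break annotations from a Praat TextGrid.

    Requires an interval tier of tones/syllables (empty intervals are
    silences) and a pitch tier giving one value per tone; ``topdown``
    tiers contribute break annotations (suffix digits select the level,
    e.g. ``topdown2``).
    """
    try:
        grid = ptg.load(path)
    except ptg.TextGridError as exc:
        raise FormatError(f"{path}: {exc}") from None

    tones_tier = (
        grid.tier(tone_tier) if tone_tier else grid.find_tier("tone", "syll")
    )
    if tones_tier is None or not tones_tier.is_interval:
        raise FormatError(f"{path}: no tone/syllable interval tier found")
    pitches_tier = grid.tier(pitch_tier) if pitch_tier else grid.find_tier("pitch")
    if pitches_tier is None:
        raise FormatError(f"{path}: no pitch tier found")

    def pitch_at(t0: float, t1: float, index: int) -> float:
        mid = 0.5 * (t0 + t1)
        for iv in pitches_tier.intervals:
            if iv.xmin - 1e-9 <= mid <= iv.xmax + 1e-9 and iv.text.strip():
                try:
                    return _pitch_to_st(float(iv.text.strip()), pitch_unit)
                except (ValueError, InvalidInputError) as exc:
                    raise FormatError(
                        f"{path}: unparseable pitch {iv.text!r} for tone "
                        f"interval {index}: {exc}"
                    ) from None
        raise FormatError(f"{path}: no pitch value covers tone interval {index}")

    tones: list[Tone] = []
    spans: list[tuple[float, float, bool]] = []  # (xmin, xmax, is_tone)
    for idx, iv in enumerate(tones_tier.intervals):
        if iv.text.strip():
            tones.append(
                Tone(
                    label=iv.text.strip(),
                    onset=iv.xmin,
                    duration=iv.xmax - iv.xmin,
                    pitch_st=pitch_at(iv.xmin, iv.xmax, idx),
                )
            )
            spans.append((iv.xmin, iv.xmax, True))
        else:
            spans.append((iv.xmin, iv.xmax, False))

    breaks: list[BreakAnnotation] = []
    for tier in grid.tiers:
        low = tier.name.lower()
        if not low.startswith("topdown"):
            continue
        suffix = low.removeprefix("topdown").strip("-_ ")
        level = int(suffix) if suffix.isdigit() else 1
        marks = (
            [(0.5 * (iv.xmin + iv.xmax), iv.text) for iv in tier.intervals]
            if tier.is_interval
            else [(pt.time, pt.mark) for pt in tier.points]
        )
        for time, text in marks:
            for glyph in text.split(";"):
                if not glyph.strip():
                    continue
                kind = kind_for_glyph(glyph)
                breaks.append(
                    BreakAnnotation(kind, _position_at(time, tones, kind), level)
                )
    return tones, breaks


def _position_at(time: float, tones: list[Tone], kind: BreakKind) -> int:
    """Map a tier time to a tone index or (for time breaks) a gap index."""
    if not tones:
        raise InvalidAnnotationError("break annotation without any tones")
    if kind in {BreakKind.TIME_IN, BreakKind.TIME_OUT}:
        for i in range(len(tones) - 1):
            if tones[i].end - 1e-9 <= time <= tones[i + 1].onset + 1e-9:
                return i
        raise InvalidAnnotationError(
            f"time annotation at {time:.3f}s does not fall in a silence"
        )
    for i, t in enumerate(tones):
        if t.onset - 1e-9 <= time <= t.end + 1e-9:
            return i
    # an interruption glyph written over a pause attaches to the preceding tone
    for i in range(len(tones) - 1):
        if tones[i].end <= time <= tones[i + 1].onset:
            return i
    raise InvalidAnnotationError(f"break at {time:.3f}s lies outside the utterance")


# ---------------------------------------------------------------------------
# target-pitch estimation
# ---------------------------------------------------------------------------


def estimate_target_pitch(samples, slice_s: float = 0.010) -> float:
    """Intensity-weighted mean f0 of a syllable nucleus, in Hz.

    ``samples`` is a sequence of ``(time_s, f0_hz, intensity)`` rows.
    Unvoiced samples (f0 <= 0 or non-finite) are excluded; the remainder
    are averaged within consecutive time slices (default 10 ms), and the
    slice means are combined weighted by mean slice intensity. The result
    always lies within the voiced f0 range.
    """
    arr = np.asarray(list(samples), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise InvalidInputError("samples must be (time, f0, intensity) triples")
    voiced = arr[np.isfinite(arr[:, 1]) & (arr[:, 1] > 0)]
    if len(voiced) == 0:
        raise InvalidInputError("no voiced samples to estimate a target pitch from")
    idx = np.floor((voiced[:, 0] - voiced[0, 0]) / slice_s).astype(int)
    f0 = np.array([voiced[idx == k, 1].mean() for k in np.unique(idx)])
    w = np.array([voiced[idx == k, 2].mean() for k in np.unique(idx)])
    w = np.clip(w, 0.0, None)
    if w.sum() <= 0:
        return float(f0.mean())
    return float(np.average(f0, weights=w))


# ---------------------------------------------------------------------------
# parse export / import
# ---------------------------------------------------------------------------


def _label_dict(lbl: IntervalLabel) -> dict:
    return {
        "role": lbl.role.value,
        "initial_class": lbl.initial_class,
        "direction_class": lbl.direction_class,
        "size_class": lbl.size_class,
        "retrospective": lbl.retrospective,
        "descending": lbl.descending,
        "repeated_pitch": lbl.repeated_pitch,
    }


def _label_from_dict(d: dict) -> IntervalLabel:
    return IntervalLabel(
        role=Role(d["role"]),
        initial_class=d["initial_class"],
        direction_class=d["direction_class"],
        size_class=d["size_class"],
        retrospective=d["retrospective"],
        descending=d["descending"],
        repeated_pitch=d["repeated_pitch"],
    )


def _parse_records(parse: ParseTree):
    yield {
        "record": "meta",
        "thresholds": vars(parse.thresholds).copy(),
        "n_levels": parse.n_levels,
    }
    for level in parse.levels:
        for i, t in enumerate(level.tones):
            yield {
                "record": "tone",
                "level": level.index,
                "index": i,
                "label": t.label,
                "onset": t.onset,
                "duration": t.duration,
                "pitch_st": t.pitch_st,
                "source_index": t.source_index,
            }
        for g in level.groupings:
            yield {
                "record": "grouping",
                "level": level.index,
                "tone_indices": g.tone_indices,
                "interval_labels": [_label_dict(x) for x in g.interval_labels],
                "marks": [
                    [m.arrows, m.tails, m.commas, m.inverted_commas] for m in g.marks
                ],
                "nets": g.nets,
                "status": g.status.value,
                "suspended_after": g.suspended_after,
            }
        for b in level.breaks:
            yield {
                "record": "break",
                "level": level.index,
                "kind": b.kind.value,
                "position": b.position,
            }
    yield {"record": "provenance", "messages": parse.provenance}


def _tree_from_records(records) -> ParseTree:
    tree = ParseTree(levels=[])
    levels: dict[int, Level] = {}

    def level(k: int) -> Level:
        if k not in levels:
            levels[k] = Level(index=k, tones=[])
        return levels[k]

    for rec in records:
        kind = rec["record"]
        if kind == "meta":
            tree.thresholds = Thresholds(**rec["thresholds"])
        elif kind == "tone":
            src = rec["source_index"]
            level(rec["level"]).tones.append(
                Tone(
                    label=rec["label"],
                    onset=rec["onset"],
                    duration=rec["duration"],
                    pitch_st=rec["pitch_st"],
                    level=rec["level"],
                    source_index=None if src is None else int(src),
                )
            )
        elif kind == "grouping":
            level(rec["level"]).groupings.append(
                Grouping(
                    level=rec["level"],
                    tone_indices=[int(i) for i in rec["tone_indices"]],
                    interval_labels=[
                        _label_from_dict(d) for d in rec["interval_labels"]
                    ],
                    marks=[ExpectancyMarks(*m) for m in rec["marks"]],
                    nets=[int(n) for n in rec["nets"]],
                    status=GroupingStatus(rec["status"]),
                    suspended_after=rec["suspended_after"],
                )
            )
        elif kind == "break":
            level(rec["level"]).breaks.append(
                BreakAnnotation(BreakKind(rec["kind"]), rec["position"], rec["level"])
            )
        elif kind == "provenance":
            tree.provenance = list(rec["messages"])
    tree.levels = [levels[k] for k in sorted(levels)]
    return tree


def _parse_to_textgrid(parse: ParseTree) -> ptg.TextGrid:
    xmax = max((lv.tones[-1].end for lv in parse.levels if lv.tones), default=0.0)
    grid = ptg.TextGrid(xmin=0.0, xmax=xmax)
    for level in parse.levels:
        tier = ptg.Tier(name=f"level{level.index}", xmin=0.0, xmax=xmax)
        ann = {
            g.tone_indices[pos]: (g.interval_labels[pos - 1], g.marks[pos])
            for g in level.groupings
            for pos in range(1, len(g.tone_indices))
        }
        cursor = 0.0
        for i, t in enumerate(level.tones):
            if t.onset > cursor + 1e-9:
                tier.intervals.append(ptg.Interval(cursor, t.onset, ""))
            pair = ann.get(i)
            text = tone_token(
                t.label, pair[0] if pair else None, pair[1] if pair else None
            )
            tier.intervals.append(ptg.Interval(t.onset, t.end, text))
            cursor = t.end
        if cursor < xmax - 1e-9:
            tier.intervals.append(ptg.Interval(cursor, xmax, ""))
        grid.tiers.append(tier)
    return grid


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    ext = path.suffix.lower()
    if ext in {".jsonl", ".json"}:
        return "json-lines"
    if ext == ".csv":
        return "csv"
    if ext == ".textgrid":
        return "textgrid"
    raise FormatError(f"cannot infer parse format from extension {ext!r}")


def write_parse(parse: ParseTree, path: str | Path, format: str | None = None) -> None:
    """Write a parse tree as json-lines, CSV, or a TextGrid.

    The json-lines and CSV representations round-trip losslessly through
    :func:`read_parse`; the TextGrid export carries one interval tier per
    level with bracket/label token strings.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "json-lines":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in _parse_records(parse):
                fh.write(json.dumps(rec) + "\n")
    elif fmt == "csv":
        rows = [
            {"payload": json.dumps(rec)} for rec in _parse_records(parse)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    elif fmt == "textgrid":
        ptg.dump(_parse_to_textgrid(parse), path)
    else:
        raise FormatError(f"unknown parse format {fmt!r}")


def read_parse(path: str | Path, format: str | None = None) -> ParseTree:
    """Read a parse tree written by :func:`write_parse` (json-lines/CSV)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "json-lines":
        with open(path, encoding="utf-8") as fh:
            records = [json.loads(line) for line in fh if line.strip()]
    elif fmt == "csv":
        df = pd.read_csv(path)
        records = [json.loads(s) for s in df["payload"]]
    else:
        raise FormatError(f"cannot read parse format {fmt!r}")
    return _tree_from_records(records)
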