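"""Minimal Praat TextGrid reader/writer.

Supports interval tiers and point (text) tiers in both the long
("verbose") and short dialects. Reading tolerates either dialect by
reducing the file to its value stream: every line contributes at most one
value — the right-hand side of a ``key = value`` pair in the long dialect,
or the bare value itself in the short dialect — so both reduce to the same
token sequence. Writing always produces the long dialect.

Only the structure needed for tone/pitch/annotation tiers is modeled; this
is not a general Praat object serializer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["Interval", "Point", "TextGrid", "TextGridError", "Tier"]


class TextGridError(ValueError):
    """The file is not a readable TextGrid."""


@dataclass
class Interval:
    xmin: float
    xmax: float
    text: str = ""


@dataclass
class Point:
    time: float
    mark: str = ""


@dataclass
class Tier:
    name: str
    xmin: float = 0.0
    xmax: float = 0.0
    intervals: list[Interval] = field(default_factory=list)
    points: list[Point] = field(default_factory=list)
    is_interval: bool = True


@dataclass
class TextGrid:
    xmin: float = 0.0
    xmax: float = 0.0
    tiers: list[Tier] = field(default_factory=list)

    def tier(self, name: str) -> Tier | None:
        for t in self.tiers:
            if t.name == name:
                return t
        return None

    def find_tier(self, *fragments: str) -> Tier | None:
        """First tier whose lowercase name contains any given fragment."""
        for t in self.tiers:
            low = t.name.lower()
            if any(f in low for f in fragments):
                return t
        return None


_NUMBER_RE = re.compile(r"^[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?$")


def _decode(raw: bytes) -> str:
    for enc in ("utf-8-sig", "utf-16"):
        try:
            return raw.decode(enc)
        except UnicodeError:
            continue
    return raw.decode("latin-1")


def _tokenize(text: str) -> list[object]:
    """Reduce a TextGrid (either dialect) to its value stream."""
    tokens: list[object] = []
    for line in text.splitlines():
        frag = line.split("=", 1)[1] if "=" in line else line
        frag = frag.strip()
        if not frag:
            continue
        if frag.startswith('"'):
            body = frag[1:]
            if body.endswith('"'):
                body = body[:-1]
            tokens.append(("str", body.replace('""', '"')))
        elif _NUMBER_RE.match(frag):
            tokens.append(("num", float(frag)))
        elif "<exists>" in frag:
            tokens.append(("exists", True))
        # anything else ("item [1]:", "intervals [2]:", flag lines) carries
        # no value and is skipped
    return tokens


class _Stream:
    def __init__(self, tokens: list[object]) -> None:
        self.tokens = tokens
        self.pos = 0

    def next(self, kind: str):
        while self.pos < len(self.tokens):
            k, v = self.tokens[self.pos]
            self.pos += 1
            if k == kind:
                return v
        raise TextGridError(f"unexpected end of TextGrid (wanted {kind})")

    def peek_str(self) -> str | None:
        for k, v in self.tokens[self.pos :]:
            if k == "str":
                return v
        return None


def loads(text: str) -> TextGrid:
    tokens = _tokenize(text)
    stream = _Stream(tokens)
    header = stream.next("str")
    if header != "ooTextFile":
        raise TextGridError(f'not an ooTextFile (header {header!r})')
    objclass = stream.next("str")
    if objclass != "TextGrid":
        raise TextGridError(f'not a TextGrid (object class {objclass!r})')
    grid = TextGrid(xmin=stream.next("num"), xmax=stream.next("num"))
    n_tiers = int(stream.next("num"))
    for _ in range(n_tiers):
        klass = stream.next("str")
        tier = Tier(name=stream.next("str"))
        tier.xmin = stream.next("num")
        tier.xmax = stream.next("num")
        count = int(stream.next("num"))
        if klass == "IntervalTier":
            tier.is_interval = True
            for _ in range(count):
                xmin = stream.next("num")
                xmax = stream.next("num")
                tier.intervals.append(Interval(xmin, xmax, stream.next("str")))
        elif klass == "TextTier":
            tier.is_interval = False
            for _ in range(count):
                time = stream.next("num")
                tier.points.append(Point(time, stream.next("str")))
        else:
            raise TextGridError(f"unsupported tier class {klass!r}")
        grid.tiers.append(tier)
    return grid


def load(path: str | Path) -> TextGrid:
    return loads(_decode(Path(path).read_bytes()))


def _q(s: str) -> str:
    return '"' + s.replace('"', '""') + '"'


def dumps(grid: TextGrid) -> str:
    """Serialize in the long dialect."""
    out = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {grid.xmin!r}",
        f"xmax = {grid.xmax!r}",
        "tiers? <exists>",
        f"size = {len(grid.tiers)}",
        "item []:",
    ]
    for ti, tier in enumerate(grid.tiers, start=1):
        out.append(f"    item [{ti}]:")
        klass = "IntervalTier" if tier.is_interval else "TextTier"
        out.append(f"        class = {_q(klass)}")
        out.append(f"        name = {_q(tier.name)}")
        out.append(f"        xmin = {tier.xmin!r}")
        out.append(f"        xmax = {tier.xmax!r}")
        if tier.is_interval:
            out.append(f"        intervals: size = {len(tier.intervals)}")
            for ii, iv in enumerate(tier.intervals, start=1):
                out.append(f"        intervals [{ii}]:")
                out.append(f"            xmin = {iv.xmin!r}")
                out.append(f"            xmax = {iv.xmax!r}")
                out.append(f"            text = {_q(iv.text)}")
        else:
            out.append(f"        points: size = {len(tier.points)}")
            for pi, pt in enumerate(tier.points, start=1):
                out.append(f"        points [{pi}]:")
                out.append(f"            number = {pt.time!r}")
                out.append(f"            mark = {_q(pt.mark)}")
    return "\n".join(out) + "\n"


def dump(grid: TextGrid, path: str | Path) -> None:
    Path(path).write_text(dumps(grid), encoding="utf-8")
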