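"""Synthetic tone sequences with controlled categorical structure.

Real spoken material cannot ship with the package, so every behaviour of
the engine — each interval category, each secondary-closure rule, each
top-down break kind — is exercised by constructed tone sequences whose
successive semitone steps and duration ratios are chosen to land squarely
inside (or deliberately on the boundaries of) the categorical bands of the
speech preset.

The canonical fixtures emulate the *shapes* of the demonstration analyses:

* ``fig3_sequence`` — a six-tone utterance containing a closed S P~
  grouping whose final tone re-opens the next, a closed L R- grouping with
  the worked +2 / -3 expectancy tallies on its second and third tones,
  three emergent levels, and a replicating initial suppressed on the
  deepest level.
* ``case1_sequences`` — four "intonations" of one nine-tone sentence,
  differing in pivot tones only, all of whose deepest-level tones land on
  the two designated stressed tones.
* ``case2_sequences`` — a question-plus-answer pair across a pause, in a
  *suspend* reading (releasable suppression, closure forced on the next
  tone) and a *halt* reading (grouping stopped unclosed).
* ``case3_sequences`` — a longer utterance under three break
  interpretations (bottom-up with time-ins; elevations plus suspends and
  separations; an alternative separation placement).

These are structural emulations: the pitch and duration values are the
package's own, not measurements of any recording.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .model import BreakAnnotation, BreakKind, InvalidInputError, Tone

__all__ = [
    "case1_sequences",
    "case2_sequences",
    "case3_sequences",
    "fig3_sequence",
    "fig3a_grouping",
    "label_zoo",
    "load_packaged_csv",
    "locate_s1_file",
    "make_grouping_fixture",
    "packaged_fixtures",
    "random_utterance",
]


def make_grouping_fixture(
    steps: list[tuple[float, float]],
    base_pitch_st: float = 10.0,
    base_duration: float = 0.3,
    labels: list[str] | None = None,
) -> list[Tone]:
    """Build a contiguous tone sequence from (interval, duration-ratio) steps.

    ``steps[k] = (dst, ratio)`` makes tone ``k+1`` lie ``dst`` semitones
    from tone ``k`` (signed) with ``ratio`` times its duration. Onsets are
    contiguous (no silences).
    """
    if not steps:
        raise InvalidInputError("a grouping fixture needs at least one step")
    for _, ratio in steps:
        if not ratio > 0:
            raise InvalidInputError("duration ratios must be > 0")
    if not base_duration > 0:
        raise InvalidInputError("base duration must be > 0")
    n = len(steps) + 1
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n)]
    if len(labels) != n:
        raise InvalidInputError(f"expected {n} labels, got {len(labels)}")

    tones = [Tone(labels[0], 0.0, base_duration, base_pitch_st)]
    for k, (dst, ratio) in enumerate(steps):
        prev = tones[-1]
        tones.append(
            Tone(labels[k + 1], prev.end, prev.duration * ratio, prev.pitch_st + dst)
        )
    return tones


def _sequence(
    labels: list[str],
    pitches: list[float],
    durations: list[float],
    gaps: dict[int, float] | None = None,
) -> list[Tone]:
    """Tones from explicit per-tone values; ``gaps[i]`` = silence after tone i."""
    gaps = gaps or {}
    tones = []
    onset = 0.0
    for i, (lab, p, d) in enumerate(zip(labels, pitches, durations, strict=True)):
        tones.append(Tone(lab, onset, d, p))
        onset += d + gaps.get(i, 0.0)
    return tones


def fig3a_grouping() -> list[Tone]:
    """Three tones forming a large descending interval answered by R-.

    The interval shape is L (descending) then R-; the second tone is
    moderately shorter (one inverted comma) and carries the L-descent
    comma, the third is 2.5 times longer (three commas). Under the speech
    preset its per-tone expectancy tallies are +2 and -3.
    """
    return make_grouping_fixture(
        [(-4.0, 0.7), (+1.0, 2.5)], base_pitch_st=12.5, labels=["mar", "ma", "lade"]
    )


def fig3_sequence() -> list[Tone]:
    """Six-tone utterance with the S P~ / L R- demonstration structure.

    Level 1 parses as a closed [S P~] grouping (three commas on its final
    tone, which re-opens the next grouping), a closed [L R-] grouping with
    the +2 / -3 worked tallies, and a trailing implicative dyad left open
    at the end of the utterance. Boundary tones emerge on Level 2; the
    Level-3 candidate initial is suppressed because its grouping would
    replicate Level 2's opening two-tone grouping.
    """
    return _sequence(
        labels=["Mar", "i", "an", "na", "ma", "lade"],
        pitches=[10.0, 11.0, 12.5, 8.5, 9.5, 10.5],
        durations=[0.3, 0.27, 0.675, 0.4725, 1.18125, 1.18125],
    )


_CASE1_LABELS = ["Ma", "ri", "an", "na", "made", "the", "mar", "ma", "lade"]
_CASE1_DURATIONS = [0.2, 0.2, 0.36, 0.40, 0.5, 0.55, 0.87, 0.5, 1.7]
#: indices of the two designated stressed tones of the case-1 sentence
CASE1_STRESSED = (2, 8)


def case1_sequences() -> dict[str, list[Tone]]:
    """Four intonations of one nine-tone sentence.

    The variants share all grouping-boundary tones (so they share their
    deeper levels) and differ in the two pivot tones: the second tone
    shapes the opening interval pair (S P~ vs S P+), the eighth shapes the
    final cadence (retrospective R-, plain R- after L, or a rising P~).
    The deepest level of each variant holds the designated stressed tones.
    """
    base = [10.0, 11.0, 12.5, 8.5, 11.5, 11.0, 10.2, 12.6, 11.9]
    variants = {
        "statement": dict(t2=11.0, t8=12.6),  # S P~ ... S (R-) fall
        "both_new": dict(t2=11.0, t8=13.4),  # ... L R- fall
        "contrastive": dict(t2=10.25, t8=12.6),  # S P+ opening
        "question": dict(t2=11.0, t8=10.5),  # ... S P~ rising end
    }
    out = {}
    for name, pivots in variants.items():
        pitches = list(base)
        pitches[1] = pivots["t2"]
        pitches[7] = pivots["t8"]
        out[name] = _sequence(_CASE1_LABELS, pitches, list(_CASE1_DURATIONS))
    return out


def case2_sequences() -> dict[str, tuple[list[Tone], list[BreakAnnotation]]]:
    """Question-plus-answer across a pause: suspend vs halt readings.

    Both variants share the tones: a five-tone question left implicative
    on its final syllable, a half-second pause, then a three-tone answer.
    The *suspend* reading releasably suppresses closure on the question's
    last tone, removes the pause from the timeline, labels the straddling
    interval normally, and forces a closing bracket on the answer's first
    tone. The *halt* reading stops the question's grouping unclosed and
    starts the answer fresh.
    """
    labels = ["you", "want", "ex", "am", "ple", "Mo", "re", "sa"]
    pitches = [10.0, 12.0, 13.0, 14.5, 13.5, 16.0, 13.0, 12.2]
    durations = [0.3, 0.3, 0.3, 0.3, 0.3, 0.35, 0.35, 0.8]
    tones = _sequence(labels, pitches, durations, gaps={4: 0.5})
    return {
        "suspend": (
            list(tones),
            [
                BreakAnnotation(BreakKind.TIME_OUT, 4),
                BreakAnnotation(BreakKind.SUSPEND, 4),
            ],
        ),
        "halt": (
            list(tones),
            [
                BreakAnnotation(BreakKind.TIME_OUT, 4),
                BreakAnnotation(BreakKind.HALT, 4),
            ],
        ),
    }


def case3_sequences() -> dict[str, tuple[list[Tone], list[BreakAnnotation]]]:
    """A ten-tone utterance under three break interpretations.

    Variant ``bottom_up`` folds the articulative silences into the
    preceding tones (time-in) and otherwise lets the bottom-up rules run.
    Variant ``annotated`` elevates two slow tones, suspends after a weak
    syllable, and separates two consecutive strong syllables; variant
    ``alternative`` moves the separation, shifting which tone reaches the
    deepest level.
    """
    labels = ["The", "Pen", "ta", "gon", "re", "ports", "figh", "ting", "six", "ties"]
    pitches = [9.5, 12.0, 11.0, 10.5, 10.8, 13.0, 12.0, 11.2, 14.0, 11.5]
    durations = [0.2, 0.35, 0.25, 0.3, 0.5, 0.45, 0.35, 0.3, 0.55, 0.8]
    gaps = {3: 0.2, 5: 0.3}
    tones = _sequence(labels, pitches, durations, gaps)
    time_ins = [
        BreakAnnotation(BreakKind.TIME_IN, 3),
        BreakAnnotation(BreakKind.TIME_IN, 5),
    ]
    annotated = time_ins + [
        BreakAnnotation(BreakKind.ELEVATE_UP, 4),
        BreakAnnotation(BreakKind.ELEVATE_DOWN, 8),
        BreakAnnotation(BreakKind.SUSPEND, 7),
        BreakAnnotation(BreakKind.SEPARATION, 5),
    ]
    alternative = time_ins + [
        BreakAnnotation(BreakKind.ELEVATE_UP, 4),
        BreakAnnotation(BreakKind.ELEVATE_DOWN, 8),
        BreakAnnotation(BreakKind.SUSPEND, 7),
        BreakAnnotation(BreakKind.SEPARATION, 8),
    ]
    return {
        "bottom_up": (list(tones), list(time_ins)),
        "annotated": (list(tones), annotated),
        "alternative": (list(tones), alternative),
    }


def label_zoo() -> dict[str, tuple[list[Tone], list[BreakAnnotation]]]:
    """Small sequences that each realize one categorical corner.

    Together with the canonical fixtures these reach every initial class,
    every direction/size combination, the duplication and no-direction
    cases, both retrospective violations, and the closure-override breaks.
    """
    seqs: dict[str, tuple[list[Tone], list[BreakAnnotation]]] = {}

    def add(name, pitches, durations=None, gaps=None, breaks=()):
        durations = durations or [0.3] * len(pitches)
        labels = [f"{name[:3]}{i}" for i in range(len(pitches))]
        seqs[name] = (_sequence(labels, pitches, durations, gaps), list(breaks))

    add("zero_initial", [10.0, 10.05, 13.0])  # 0 initial, then size-only '+'
    add("duplication", [10.0, 10.1, 10.05, 11.0])  # 0 then D then size-only
    add("retro_L_then_P", [10.0, 14.5, 18.0])  # L up, (P~)
    add("retro_S_then_R", [10.0, 11.0, 10.5])  # S up, (R~)
    add("p_minus", [10.0, 12.5, 12.8])  # S, P-
    add("r_plus", [10.0, 6.0, 12.0])  # L desc, R+
    add("r_zero", [10.0, 13.0, 10.0])  # L up, R0
    add("p_zero", [10.0, 11.0, 12.0])  # S, P0
    add("p_plus_descending", [10.0, 9.5, 7.0])  # S desc, P+ desc (comma)
    add(
        "overrides",
        [10.0, 11.0, 12.0, 13.0],
        durations=[0.3, 0.3, 0.9, 0.9],
        breaks=[
            BreakAnnotation(BreakKind.FORCE_CLOSURE, 1),
            BreakAnnotation(BreakKind.SUPPRESS_CLOSURE, 2),
        ],
    )
    return seqs


def packaged_fixtures() -> dict[str, tuple[list[Tone], list[BreakAnnotation]]]:
    """All named fixtures as ``name -> (tones, breaks)``."""
    out: dict[str, tuple[list[Tone], list[BreakAnnotation]]] = {
        "fig3": (fig3_sequence(), []),
        "fig3a": (fig3a_grouping(), []),
    }
    for name, tones in case1_sequences().items():
        out[f"case1_{name}"] = (tones, [])
    for name, pair in case2_sequences().items():
        out[f"case2_{name}"] = pair
    for name, pair in case3_sequences().items():
        out[f"case3_{name}"] = pair
    for name, pair in label_zoo().items():
        out[f"zoo_{name}"] = pair
    return out


def load_packaged_csv() -> dict[str, tuple[list[Tone], list[BreakAnnotation]]]:
    """The canonical fixtures as shipped in the package's CSV copy.

    The CSV under ``data/`` is generated from :func:`packaged_fixtures`
    and kept in sync by the test suite; loading it exercises the same
    tone-table reader users rely on.
    """
    from .formats import read_utterances_csv

    path = Path(__file__).parent / "data" / "canonical.csv"
    return read_utterances_csv(path)


_S1_CANDIDATE_NAMES = (
    "s1_file.csv",
    "S1_File.csv",
    "S1File.csv",
    "pone.0336780.s003.csv",
)


def locate_s1_file(extra_dirs: tuple[Path, ...] = ()) -> Path | None:
    """Find a local copy of the supplementary pitch/time table, if any.

    The supplementary table of pitch and time values behind the published
    figures is not redistributable with this package; when a copy is
    placed in the working directory (or a given directory) under one of
    the conventional names, golden comparisons against it become
    available.
    """
    for d in (Path.cwd(), Path(__file__).parent / "data", *extra_dirs):
        for name in _S1_CANDIDATE_NAMES:
            p = d / name
            if p.is_file():
                return p
    return None


def random_utterance(
    n_tones: int,
    seed: int,
    base_pitch_st: float = 10.0,
    interval_scale_st: float = 1.5,
    max_interval_st: float = 6.0,
    median_duration: float = 0.2,
    duration_sigma: float = 0.4,
    pitch_floor_st: float = 0.0,
    pitch_ceil_st: float = 20.0,
) -> list[Tone]:
    """Reproducible random tone sequence with speech-like interval sizes.

    Interval sizes are drawn from a zero-clustered Laplace distribution
    (scale 1.5 st, truncated at 6 st), reflecting the observation that
    spoken intervals cluster near zero and mostly stay under four
    semitones; durations are lognormal around 200 ms. The pitch walk is
    reflected into a fixed register band.
    """
    if n_tones < 1:
        raise InvalidInputError("n_tones must be >= 1")
    rng = np.random.default_rng(seed)
    steps = np.clip(
        rng.laplace(0.0, interval_scale_st, size=max(0, n_tones - 1)),
        -max_interval_st,
        max_interval_st,
    )
    durations = np.exp(rng.normal(np.log(median_duration), duration_sigma, n_tones))

    tones = []
    onset = 0.0
    pitch = base_pitch_st
    for i in range(n_tones):
        tones.append(Tone(f"syl{i + 1}", onset, float(durations[i]), pitch))
        onset += float(durations[i])
        if i < n_tones - 1:
            pitch += float(steps[i])
            # reflect off the register band edges
            if pitch > pitch_ceil_st:
                pitch = 2 * pitch_ceil_st - pitch
            if pitch < pitch_floor_st:
                pitch = 2 * pitch_floor_st - pitch
    return tones
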