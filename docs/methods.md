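# Methods

## Model

`irprosody` implements an adapted Implication-Realization (IR) analysis of
melodic structure, applied to speech intonation. Its input is a sequence
of *tones*: discrete pitch events, normally one per syllable, each with an
onset (the syllable's P-center), a duration, and a single target pitch.
The model deliberately ignores linguistic function — it parses the melodic
contour into an event hierarchy purely from pitch-interval comparisons,
durations, and top-down break judgments.

The model assumes:

* perceived spoken pitch can be reduced to one target per tone, expressed
  in semitones re 100 Hz (`12·log₂(f/100)`), so that intervals are
  differences and register shifts cancel;
* a tone's melodic duration runs from its onset to the onset of the next
  tone or of a silence — never from orthographic syllable edges;
* interval perception is categorical and context-sensitive: what matters
  is whether the current interval is *distinctly* different in size or
  direction from the one before it, with constant thresholds over one
  analysis;
* expectancy and closure are additive quanta (arrows, tails, commas,
  inverted commas) and a grouping closes exactly when its net implication
  `(a − t) + (i − c)` falls to 0 or below, where arrows/tails accumulate
  over the grouping and commas/inverted commas act on their own tone only.

The hierarchy arises by iteration: both boundary tones of every grouping
on level *k* emerge on level *k+1*, carrying their source pitch and onset;
an emergent tone ends at the next emergent onset or the next silence. The
new level is parsed by the same rules. Iteration stops when a level would
hold fewer than three tones (no continuation interval can be classified),
when it would reproduce the level below unchanged, or at a configurable
cap (default 8).

## Parameters

All pitch thresholds in semitones; duration bases are dimensionless
ratios. Presets (`Thresholds.speech()` / `Thresholds.music()`):

| parameter            | speech | music | meaning |
|----------------------|--------|-------|---------|
| `zero_st`            | 0.2    | 0 (exact) | below this an interval is a perceived repetition |
| `small_max_st`       | 2.5 (inclusive) | 5.0 (exclusive) | S/L boundary for initial intervals |
| `p_distinct_st`      | 2.0    | 4.0   | distinctness bound for same-direction continuations |
| `r_distinct_st`      | 1.5    | 3.0   | distinctness bound after a reversal |
| `equality_st`        | 0.2    | 0 (exact) | P0/R0 band (unnoticeable size difference) |
| `comma_base`         | 1.2    | 1.225 | lengthening factor worth one comma |
| `inverted_comma_base`| 0.8    | 0.8   | shortening factor worth one inverted comma |

The speech values reflect that spoken intervals cluster near zero and
rarely exceed four semitones, so speech distinctness bounds sit at half
the musical ones; the 0.2 st zero band approximates the point of
subjective equality for spoken interval comparison. The music comma base
1.225 ≈ √1.5 encodes the calibration that a tone 1.5× as long as its
predecessor is as closural as two tails (it closes an `L P~` grouping on
its own). The P0/R0 band is deliberately tied to the initial zero
threshold rather than exposed as an eighth knob. Thresholds are frozen per
analysis — the CLI applies preset, config file, and flag overrides once,
globally.

## Numerical choices

* **Floor snapping.** Comma counts are `⌊log_base(ratio) + 0.01⌋`, clamped
  to [0, 3]. The +0.01 snap absorbs the rounding of printed base constants
  (1.225 vs the exact √1.5 ≈ 1.22474): without it a 1.5× lengthening under
  base 1.225 would yield ⌊1.99792⌋ = 1 comma instead of the calibrated 2.
  The snap moves category boundaries by under 1 % in ratio terms.
* **Polarity clamping.** The comma formula ignores shortening and the
  inverted-comma formula ignores lengthening (each count is clamped at 0),
  so at most one of the two is nonzero for any duration pair.
* **Caps.** Commas and inverted commas saturate at three (distinctive,
  highly distinctive, exceedingly distinctive). The cap on inverted commas
  mirrors the comma cap by symmetry; it is an interpretation, since only
  the comma side has a stated three-tier scale.
* **Boundary conventions.** Speech S is inclusive at 2.5 st (L strictly
  above); distinctness is inclusive (`≥`); the equality and zero bands are
  strict (`<`). The music preset treats its zero/equality bands as exact
  equality (P0 being the degenerate case of P~) and makes S exclusive at
  5 st. Fixture pitch values are chosen off these boundaries by at least
  0.05 st so binary floating point cannot flip a category.
* **Descent commas** apply to descending `L` initials and descending `+`
  continuations only, and add onto duration commas on the same tone
  (jointly capped at 3).

## Break semantics

Breaks are top-down listener judgments, entered per level; the engine
never infers them from silence durations.

* *time-in* (gap): the preceding tone's duration absorbs the silence;
  later onsets do not move.
* *time-out* (gap): the silence is deleted and later tones shift earlier.
  Deeper levels are built from the adjusted timeline, so the represented
  span is identical across levels.
* *halt* (tone): the grouping ends there unclosed (status `halted`); no
  interval label spans the break; the next tone opens a fresh grouping. A
  halt on a tone that closes normally acts as a separation.
* *suspend* (tone): closure on the tone is releasably suppressed, the
  straddling interval is labeled as if there were no break, and a closing
  bracket is forced on the following tone (duration comparison across an
  interrupted timeline is not trusted to decide closure). A suspend on the
  level's last tone leaves the grouping `suspended`.
* *separation* (tone): when the grouping closes there, the next grouping
  starts on the following tone instead of sharing the boundary; both
  flanking tones emerge.
* *elevation* (tone): the tone becomes an obligatory grouping boundary on
  its origin level and is always promoted. This is the minimal reading of
  "moved directly to the next level" that keeps the surrounding tones
  parseable; the two glyphs `<` and `>` are accepted interchangeably so a
  span can be bracketed.
* *forced / suppressed closure* (tone): override the net test once. Their
  glyphs `!]` and `!x` are this package's own convention.

## Design decisions on open points

Several behaviours are not fully pinned down by the source material; the
package resolves them as follows.

* **Emergence of never-closed finals.** The first *and* last tone of every
  grouping emerges, including the final tone of an `open_at_end` or
  `halted` grouping. Halted dyads visibly project both tones to deeper
  levels, and treating end-of-speech as a boundary keeps emergence
  uniform; the cost is that the utterance-final tone propagates to every
  level.
* **Replication avoidance** is applied only to the candidate level's
  initial tone (iteratively, with a fixed-point guard), comparing
  tone-onset sets — not labels — against groupings one level below. Only
  the initial-tone case is attested; extending it to interior tones would
  break shared-boundary bookkeeping.
* **Retrospective labels** are produced exactly for the two attested
  violations — `L` then `P`, `S` then `R` — and only when the governing
  previous label is the grouping's initial. Retrospection never affects
  closure.
* **Direction after a repetition.** `P` and `R` are defined relative to an
  established direction; after a zero interval none exists, so the next
  moving interval carries a size class only (classified with the `P`
  bound as the neutral default) and contributes no directional arrow or
  tail. Three consecutive equal pitches yield `D` (duplication), which
  adds nothing.
* **Closure tie.** The closing condition is `net ≤ 0` exactly. A level's
  final tone with positive net yields status `open_at_end` rather than an
  error, as utterance-final implicative tones are meaningful (question
  endings).
* **Singleton tail groupings.** When the final closure lands on the
  level's last tone, no trailing one-tone grouping is opened; after a
  separation immediately before the last tone, the stranded tone does form
  its own (open) grouping so that every tone belongs to at least one.

## Synthetic fixtures

The fixture generator produces tone sequences whose successive semitone
steps and duration ratios are exact, so every categorical band, secondary
rule, and break kind is exercised by construction
(`fixtures.packaged_fixtures()`, also shipped as `data/canonical.csv`).
The canonical sequences emulate the *categorical shape* of the published
demonstration analyses — a six-tone sequence with the S P~ / L R−
structure and the worked +2 / −3 tallies, four "intonations" of one
nine-tone sentence whose two designated stressed tones reach the deepest
level, a question-answer pair under suspend vs halt readings, and a longer
utterance under three break interpretations — not their acoustic values,
which are not redistributable. In the nine-tone sentence the second stress
anchor is deliberately placed on the utterance-final tone, since under the
uniform emergence rule the final tone reaches every level.

`random_utterance` draws interval sizes from a zero-clustered Laplace
distribution (scale 1.5 st, truncated at 6 st, reflected into a 20 st
register band) and lognormal durations around 200 ms — a caricature of
speech statistics adequate for property testing (determinism, level-size
monotonicity, bracket conservation, tally re-computation).

What passing these tests does **not** show: that target-pitch reduction of
real f0 tracks is perceptually valid, that the thresholds are right for
any given speaker, or that parses of real utterances match published
hand analyses — the pitch/time values behind those analyses live in a
supplementary table that users must supply locally (the corresponding
golden test skips when it is absent). The intensity-weighted target-pitch
estimator is provided for users with sampled (time, f0, intensity) tracks,
with 10 ms slices as the default; it is not a pitch tracker.

## Test and script scale

The property ensemble runs 1000 seeded random utterances of 3–14 tones
through the full hierarchy (a few seconds on one core); the categorical
partition check sweeps a 0.05 st grid over 0–6 st in both directions
against an independently coded inequality table. `scripts/acceptance.py`
re-runs the engine on the six-tone demonstration (n = 6) and reports the
comma term of its L R− grouping's closing tone.

## Known limitations

* No audio handling: no f0 extraction, P-center detection, or resynthesis;
  inputs are tone tables or TextGrids prepared elsewhere.
* One parameter (pitch) is primary; duration enters only through the
  comma calculus. Parallel implicative analysis of loudness or timbre is
  out of scope.
* Break positions on emergent levels index the level as finally built;
  annotating them is inherently iterative (parse, inspect, annotate,
  re-parse), as in the interactive workflow the tool descends from.
* TextGrid support covers interval and point tiers of the two standard
  dialects, not arbitrary embedded Praat objects.
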