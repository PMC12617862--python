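# irprosody

Hierarchical parsing of speech intonation (and simple musical melody) with
an adapted **Implication-Realization (IR)** calculus.

Most intonation annotation systems (AM/ToBI and relatives) describe a pitch
contour as a single-level sequence of salient events — pitch accents,
phrase accents, boundary tones. `irprosody` takes the complementary,
natively *syntagmatic* view: an utterance is a stream of discrete tones
(normally one per syllable, each with an onset at its perceptual P-center,
a duration, and a target pitch), and structure arises from comparing each
pitch interval with the interval before it. Successive intervals create
*expectancy* (the sense that a melodic grouping will continue) or *closure*
(the sense that it is complete); closed groupings hand their boundary tones
to the next, deeper level, where the same rules apply again. The result is
a multi-level parse in which the tones that survive to the deepest levels
tend to be exactly the syllables a ToBI annotator would mark with pitch
accents.

The package is for phoneticians, prosody researchers, and music cognition
researchers who want reproducible, scriptable IR parses of tone tables or
Praat TextGrids.

## The calculus

Pitch is measured in semitones re 100 Hz, `st(f) = 12·log₂(f/100)`.

**Interval categories.** The first interval of a grouping is labeled by
size: `0` (below the zero threshold, 0.2 st in the speech preset), `S`
(small, ≤ 2.5 st), or `L` (large). Each continuation is labeled against the
previous interval: direction `P` (process, same direction), `R` (reversal),
or `D` (duplication of an already-repeated pitch), and size `+` (distinctly
larger: ≥ 2 st difference after `P`, ≥ 1.5 st after `R`), `−` (distinctly
smaller), `~` (non-distinctively similar), or `0` (unnoticeably different,
< 0.2 st). Descending intervals are italicized (rendered `*`), violations
of the initial implication (`L` then `P`, `S` then `R`) are retrospective
(rendered in parentheses), and repeated pitches are underlined (`_`).

**Expectancy.** Non-zero initial intervals carry two arrows of expectancy,
zero initials one; each `+` adds an arrow, each `−` a tail (a quantum of
closure), and each reversal a tail. Arrows and tails accumulate over a
grouping. Secondary features act on single tones only: a tone `d_c/d_p`
times as long as its predecessor carries

    commas = ⌊ log_c (d_c / d_p) ⌋        (clamped to 0…3, c = 1.2 speech / 1.225 music)

commas of closure, a shorter tone carries inverted commas of counterclosure
(one per factor-of-r shortening, r = 0.8), and descending `L` or `+`
intervals carry one extra comma. Net implication on a tone is

    net = (a − t) + (i − c)

with `a`,`t` the arrows/tails since the grouping began and `i`,`c` the
tone's own inverted commas and commas. When net falls to 0 or below the
grouping closes; its final tone also opens the next grouping and both
boundary tones emerge on the next level. An emergent initial is suppressed
when the grouping it would open merely replicates one already present a
level below.

**Top-down breaks.** Listener judgments about pauses and interruptions are
entered as annotations: *time-in* `- - -` (fold a silence into the
preceding tone), *time-out* `…` (delete it from the timeline),
*separation* `/`, *halt* `|` (stop a grouping unclosed), *suspend* `#`
(releasable suppression; the straddling interval is labeled as if there
were no break and a closing bracket is forced on the following tone),
elevation `<` `>` (promote a tone directly to the next level), and forced
`!]` / suppressed `!x` closure.

## Worked example

The packaged six-tone demonstration sequence contains a small ascending
pair answered in kind, then a large descent answered by a reversal:

```sh
$ irprosody fixtures -o demo --seed 7
$ irprosody analyze -i demo/canonical.csv -u fig3
IR parse (speech thresholds, 3 levels)
Level 1: [Mar i:S^^ an:P~,,,][ na:*L'^^, ma:R-vv,,,][ lade:S^^
Level 2: [Mar an:S^^,,,][ ma:*L^^, lade:R-vv]
Level 3: [an lade:*S'''^^
```

Reading Level 1: the grouping `[Mar i an` opens with a small ascent `S`
(two arrows `^^` of expectancy on *i*); the next interval is `P~` (same
direction, similar size — implicatively neutral), but *an* is so much
longer than *i* that it carries three commas `,,,` of secondary closure:
net implication is (2−0)+(0−3) = −1, the grouping closes (`][`), and *an*
re-opens the next one. There, *na* completes a large descending interval
`*L` (two arrows, plus one comma for the descent and one inverted comma
`'` for its shortness: net (2−0)+(1−1) = +2, still open), and *ma* answers
with a reversal, distinctly smaller — `R-`, two tails `vv`, three duration
commas: net (2−2)+(0−3) = −3 closes the grouping. The boundary tones
emerge on Level 2 and are parsed again; on Level 3 the initial *Mar* is
suppressed because its grouping would only replicate Level 2's opening
`S`, leaving the two "stressed" tones *an* and *lade* as the deepest
events.

A question-plus-answer with a pause read as a *suspend* (releasable
suppression, `%` marking the suspension point):

```sh
$ irprosody analyze -i demo/canonical.csv -u case2_suspend
IR parse (speech thresholds, 3 levels)
Level 1: [you want:S^^ ex:P~ am:P~ ple:*R~v% Mo:R+^v][ re:*L^^, sa:*(P-)v,,,]
Level 2: [you Mo:L'''^^ sa:*R-vv]
Level 3: [you sa:S'''^^
```

The same tones with the pause read as a *halt* (`case2_halt`) leave the
question's grouping unclosed (`|`) and start the answer fresh — run it to
compare.

The same pipeline is available as a library:

```python
from irprosody import Thresholds, build_hierarchy, render_text
from irprosody.fixtures import fig3_sequence

tree = build_hierarchy(fig3_sequence(), [], Thresholds.speech())
print(render_text(tree), end="")
```

`irprosody analyze` also reads Praat TextGrids (a tone/syllable interval
tier, a pitch tier in Hz or semitones, optional `topdown` break tiers) and
writes parses as JSON-lines, CSV, or TextGrids (`-o parse.jsonl`).

## Documentation

`docs/methods.md` describes the model, its thresholds and their defaults,
the break semantics, what the synthetic fixtures do and do not emulate,
and the package's design decisions.
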