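import pytest

from irprosody.fixtures import (
    case2_sequences,
    fig3_sequence,
    make_grouping_fixture,
    random_utterance,
)
from irprosody.model import (
    BreakAnnotation,
    BreakKind,
    GroupingStatus,
    InvalidAnnotationError,
    InvalidInputError,
    Thresholds,
    Tone,
)
from irprosody.parser import parse_level


class TestBasicParsing:
    def test_L_Rminus_grouping_closes_with_worked_tallies(self, speech, fig3a_tones):
        groupings, _ = parse_level(fig3a_tones, [], speech)
        assert len(groupings) == 1
        g = groupings[0]
        assert g.tone_indices == [0, 1, 2]
        assert [l.symbol for l in g.interval_labels] == ["L", "R-"]
        assert g.nets == [0, 2, -3]  # the worked per-tone expectancy tallies
        assert g.status is GroupingStatus.CLOSED

    def test_S_Ptilde_grouping_final_tone_reopens(self, speech):
        tones = fig3_sequence()
        groupings, _ = parse_level(tones, [], speech)
        first = groupings[0]
        assert [l.symbol for l in first.interval_labels] == ["S", "P~"]
        assert first.status is GroupingStatus.CLOSED
        # the closing tone also initiates the next grouping
        assert groupings[1].start == first.end

    def test_single_tone_level(self, speech):
        groupings, _ = parse_level([Tone("a", 0.0, 0.3, 10.0)], [], speech)
        assert len(groupings) == 1
        g = groupings[0]
        assert g.tone_indices == [0] and g.interval_labels == []
        assert g.status is GroupingStatus.OPEN_AT_END

    def test_empty_input_rejected(self, speech):
        with pytest.raises(InvalidInputError):
            parse_level([], [], speech)

    def test_every_grouping_starts_with_zero_implication(self, speech):
        groupings, _ = parse_level(fig3_sequence(), [], speech)
        for g in groupings:
            assert g.nets[0] == 0
            m = g.marks[0]
            assert (m.arrows, m.tails, m.commas, m.inverted_commas) == (0, 0, 0, 0)

    def test_determinism(self, speech):
        tones = random_utterance(40, seed=11)
        assert parse_level(tones, [], speech)[0] == parse_level(tones, [], speech)[0]


class TestStructuralProperties:
    @pytest.mark.parametrize("seed", range(40))
    def test_bracket_conservation_and_coverage(self, speech, seed):
        tones = random_utterance(3 + seed % 15, seed=seed)
        groupings, _ = parse_level(tones, [], speech)
        # every tone belongs to at least one grouping
        covered = sorted({i for g in groupings for i in g.tone_indices})
        assert covered == list(range(len(tones)))
        # interior boundaries are shared without separation breaks
        for a, b in zip(groupings, groupings[1:]):
            assert b.start == a.end
        assert groupings[0].start == 0 and groupings[-1].end == len(tones) - 1
        # each grouping closes legitimately
        for g in groupings[:-1]:
            assert g.status is GroupingStatus.CLOSED and g.nets[-1] <= 0

    @pytest.mark.parametrize("seed", range(40))
    def test_second_tone_closure_needs_commas(self, speech, seed):
        """A dyad can only close when its commas cover the initial arrows."""
        tones = random_utterance(3 + seed % 15, seed=1000 + seed)
        groupings, _ = parse_level(tones, [], speech)
        for g in groupings:
            if len(g.tone_indices) == 2 and g.status is GroupingStatus.CLOSED:
                m = g.marks[1]
                assert m.commas >= m.arrows + m.inverted_commas

    def test_duration_ratio_sweep_dyad_closure(self, speech):
        """Sweeping the second tone's duration, closure begins exactly when
        secondary closure covers the two initial arrows."""
        for ratio in (1.0, 1.2, 1.43, 1.44, 1.728, 2.5):
            tones = make_grouping_fixture([(+1.0, ratio), (+1.2, 1.0)])
            groupings, _ = parse_level(tones, [], speech)
            closed_on_second = groupings[0].tone_indices == [0, 1]
            assert closed_on_second == (ratio >= 1.44), ratio


def _gapped_tones():
    return [
        Tone("a", 0.0, 0.3, 10.0),
        Tone("b", 0.3, 0.3, 11.0),
        Tone("c", 1.0, 0.3, 12.0),  # 0.4 s silence after b
        Tone("d", 1.3, 0.3, 13.0),
    ]


class TestBreaks:
    def test_halt_stops_grouping_unclosed(self, speech):
        tones, breaks = case2_sequences()["halt"]
        groupings, _ = parse_level(tones, breaks, speech)
        halted = groupings[0]
        assert halted.status is GroupingStatus.HALTED
        assert halted.end == 4
        # the following tone opens a fresh grouping; no label spans the break
        assert groupings[1].start == 5
        assert len(halted.interval_labels) == 4

    def test_suspend_labels_straddling_interval_and_forces_closure(self, speech):
        tones, breaks = case2_sequences()["suspend"]
        groupings, _ = parse_level(tones, breaks, speech)
        g = groupings[0]
        # the grouping continues across the pause and is forced closed on
        # the following tone even though net implication is still positive
        assert g.tone_indices == [0, 1, 2, 3, 4, 5]
        assert g.status is GroupingStatus.CLOSED
        assert g.suspended_after == 4
        assert g.interval_labels[-1].symbol == "R+"  # labeled as if no break
        assert g.nets[-1] > 0

    def test_suspend_at_level_end_leaves_status_suspended(self, speech):
        tones = make_grouping_fixture([(+1.0, 1.0), (+1.2, 1.0)])
        groupings, _ = parse_level(
            tones, [BreakAnnotation(BreakKind.SUSPEND, 2)], speech
        )
        assert groupings[-1].status is GroupingStatus.SUSPENDED

    def test_separation_delays_next_grouping(self, speech):
        # force closure at tone 1, separation there: next grouping starts at 2
        tones = make_grouping_fixture([(+1.0, 1.0), (+1.2, 1.0), (+1.0, 1.0)])
        breaks = [
            BreakAnnotation(BreakKind.FORCE_CLOSURE, 1),
            BreakAnnotation(BreakKind.SEPARATION, 1),
        ]
        groupings, _ = parse_level(tones, breaks, speech)
        assert groupings[0].tone_indices == [0, 1]
        assert groupings[1].start == 2  # not shared

    def test_time_in_absorbs_silence(self, speech):
        tones = _gapped_tones()
        _, adjusted = parse_level(
            tones, [BreakAnnotation(BreakKind.TIME_IN, 1)], speech
        )
        assert adjusted[1].duration == pytest.approx(0.7)
        assert adjusted[2].onset == pytest.approx(1.0)  # later tones unmoved

    def test_time_out_removes_silence(self, speech):
        tones = _gapped_tones()
        _, adjusted = parse_level(
            tones, [BreakAnnotation(BreakKind.TIME_OUT, 1)], speech
        )
        assert adjusted[1].duration == pytest.approx(0.3)
        assert adjusted[2].onset == pytest.approx(0.6)  # timeline compacted
        assert adjusted[3].onset == pytest.approx(0.9)

    def test_time_break_requires_a_silence(self, speech):
        tones = make_grouping_fixture([(+1.0, 1.0), (+1.0, 1.0)])
        with pytest.raises(InvalidAnnotationError):
            parse_level(tones, [BreakAnnotation(BreakKind.TIME_IN, 0)], speech)

    def test_suppress_closure_keeps_grouping_open(self, speech):
        # three commas on the second tone would close the S dyad
        tones = make_grouping_fixture([(+1.0, 2.0), (+1.0, 1.0)])
        plain, _ = parse_level(tones, [], speech)
        assert plain[0].tone_indices == [0, 1]
        suppressed, _ = parse_level(
            tones, [BreakAnnotation(BreakKind.SUPPRESS_CLOSURE, 1)], speech
        )
        assert suppressed[0].tone_indices == [0, 1, 2]

    def test_force_closure_overrides_positive_net(self, speech):
        tones = make_grouping_fixture([(+1.0, 1.0), (+1.2, 1.0)])
        groupings, _ = parse_level(
            tones, [BreakAnnotation(BreakKind.FORCE_CLOSURE, 1)], speech
        )
        assert groupings[0].tone_indices == [0, 1]
        assert groupings[0].status is GroupingStatus.CLOSED
        assert groupings[0].nets[-1] > 0

    def test_invalid_position_rejected(self, speech):
        tones = make_grouping_fixture([(+1.0, 1.0)])
        with pytest.raises(InvalidAnnotationError):
            parse_level(tones, [BreakAnnotation(BreakKind.HALT, 7)], speech)
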