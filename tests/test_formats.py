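import math

import pytest

from irprosody import praat_textgrid as ptg
from irprosody.fixtures import fig3_sequence
from irprosody.formats import (
    FormatError,
    estimate_target_pitch,
    read_parse,
    read_textgrid,
    read_tone_csv,
    read_utterances_csv,
    write_parse,
    write_tone_csv,
)
from irprosody.hierarchy import build_hierarchy
from irprosody.model import BreakKind, InvalidInputError, ParseTree


class TestToneCsv:
    def test_basic_read(self, tmp_path):
        p = tmp_path / "tones.csv"
        p.write_text(
            "label,start,end,pitch\n"
            "ma,0.0,0.2,100\n"
            "ri,0.2,0.5,10.5\n"
            "an,0.5,1.1,12.0\n"
        )
        tones, breaks = read_tone_csv(p)
        assert [t.duration for t in tones] == pytest.approx([0.2, 0.3, 0.6])
        # 100 is above the auto threshold: Hz, i.e. 0 st
        assert tones[0].pitch_st == pytest.approx(0.0)
        assert tones[1].pitch_st == pytest.approx(10.5)  # <= 45: semitones
        assert breaks == []

    def test_out_of_order_rows_resorted_with_warning(self, tmp_path):
        p = tmp_path / "tones.csv"
        p.write_text(
            "label,start,end,pitch\nb,0.2,0.5,10\na,0.0,0.2,11\n"
        )
        with pytest.warns(UserWarning, match="re-sorting"):
            tones, _ = read_tone_csv(p)
        assert [t.label for t in tones] == ["a", "b"]

    def test_overlap_error_lists_rows(self, tmp_path):
        p = tmp_path / "tones.csv"
        p.write_text(
            "label,start,end,pitch\na,0.0,0.3,10\nb,0.2,0.5,11\n"
        )
        with pytest.raises(FormatError, match="overlapping"):
            read_tone_csv(p)

    def test_unit_column_forces_interpretation(self, tmp_path):
        p = tmp_path / "tones.csv"
        p.write_text(
            "label,start,end,pitch,unit\na,0.0,0.3,100,st\n"
        )
        tones, _ = read_tone_csv(p)
        assert tones[0].pitch_st == pytest.approx(100.0)

    def test_break_glyph_column(self, tmp_path):
        p = tmp_path / "tones.csv"
        p.write_text(
            'label,start,end,pitch,break\n'
            'a,0.0,0.3,10,\n'
            'b,0.3,0.6,11,"#;..."\n'
            'c,1.0,1.3,12,\n'
        )
        tones, breaks = read_tone_csv(p)
        kinds = {(b.kind, b.position) for b in breaks}
        assert kinds == {(BreakKind.SUSPEND, 1), (BreakKind.TIME_OUT, 1)}

    def test_multi_utterance_requires_selection(self, tmp_path):
        p = tmp_path / "tones.csv"
        p.write_text(
            "utterance,label,start,end,pitch\nu1,a,0,0.3,10\nu2,b,0,0.3,11\n"
        )
        with pytest.raises(FormatError, match="pass utterance="):
            read_tone_csv(p)
        tones, _ = read_tone_csv(p, utterance="u2")
        assert tones[0].label == "b"
        assert set(read_utterances_csv(p)) == {"u1", "u2"}

    def test_missing_columns(self, tmp_path):
        p = tmp_path / "tones.csv"
        p.write_text("label,start\nx,0\n")
        with pytest.raises(FormatError, match="missing columns"):
            read_tone_csv(p)

    def test_write_read_roundtrip(self, tmp_path):
        table = {"u": (fig3_sequence(), [])}
        p = tmp_path / "out.csv"
        write_tone_csv(table, p)
        tones, _ = read_tone_csv(p)
        ref = table["u"][0]
        assert len(tones) == len(ref)
        for a, b in zip(tones, ref):
            assert a.label == b.label
            assert a.onset == pytest.approx(b.onset, abs=1e-9)
            assert a.pitch_st == pytest.approx(b.pitch_st, abs=1e-9)


LONG_GRID = """File type = "ooTextFile"
Object class = "TextGrid"

xmin = 0
xmax = 1.0
tiers? <exists>
size = 3
item []:
    item [1]:
        class = "IntervalTier"
        name = "tones"
        xmin = 0
        xmax = 1.0
        intervals: size = 4
        intervals [1]:
            xmin = 0.00
            xmax = 0.20
            text = "ma"
        intervals [2]:
            xmin = 0.20
            xmax = 0.35
            text = "ri"
        intervals [3]:
            xmin = 0.35
            xmax = 0.55
            text = ""
        intervals [4]:
            xmin = 0.55
            xmax = 1.0
            text = "an"
    item [2]:
        class = "IntervalTier"
        name = "pitch"
        xmin = 0
        xmax = 1.0
        intervals: size = 4
        intervals [1]:
            xmin = 0.00
            xmax = 0.20
            text = "180"
        intervals [2]:
            xmin = 0.20
            xmax = 0.35
            text = "210"
        intervals [3]:
            xmin = 0.35
            xmax = 0.55
            text = ""
        intervals [4]:
            xmin = 0.55
            xmax = 1.0
            text = "150"
    item [3]:
        class = "IntervalTier"
        name = "topdown"
        xmin = 0
        xmax = 1.0
        intervals: size = 3
        intervals [1]:
            xmin = 0
            xmax = 0.35
            text = ""
        intervals [2]:
            xmin = 0.35
            xmax = 0.55
            text = "#"
        intervals [3]:
            xmin = 0.55
            xmax = 1.0
            text = ""
"""

SHORT_GRID = """File type = "ooTextFile"
Object class = "TextGrid"

0
0.5
<exists>
2
"IntervalTier"
"syllables"
0
0.5
2
0
0.25
"da"
0.25
0.5
"dum"
"IntervalTier"
"pitch"
0
0.5
2
0
0.25
"100"
0.25
0.5
"12"
"""


class TestTextGrid:
    def test_long_dialect(self, tmp_path):
        p = tmp_path / "g.TextGrid"
        p.write_text(LONG_GRID)
        tones, breaks = read_textgrid(p)
        assert [t.label for t in tones] == ["ma", "ri", "an"]
        # independent conversion: 12*log2(f/100)
        assert tones[0].pitch_st == pytest.approx(12 * math.log2(1.8), abs=1e-6)
        assert tones[1].pitch_st == pytest.approx(12 * math.log2(2.1), abs=1e-6)
        # the empty interval is a silence, not a tone
        assert tones[1].end == pytest.approx(0.35)
        assert tones[2].onset == pytest.approx(0.55)
        # '#' over the pause: suspend attached to the preceding tone
        assert [(b.kind, b.position) for b in breaks] == [(BreakKind.SUSPEND, 1)]

    def test_short_dialect_and_mixed_units(self, tmp_path):
        p = tmp_path / "g.TextGrid"
        p.write_text(SHORT_GRID)
        tones, _ = read_textgrid(p)
        assert [t.label for t in tones] == ["da", "dum"]
        assert tones[0].pitch_st == pytest.approx(0.0)  # 100 -> Hz
        assert tones[1].pitch_st == pytest.approx(12.0)  # 12 -> st

    def test_missing_tier_named_in_error(self, tmp_path):
        p = tmp_path / "g.TextGrid"
        p.write_text(SHORT_GRID.replace('"pitch"', '"other"'))
        with pytest.raises(FormatError, match="pitch"):
            read_textgrid(p)

    def test_unparseable_pitch_names_interval(self, tmp_path):
        p = tmp_path / "g.TextGrid"
        p.write_text(LONG_GRID.replace('"210"', '"hi"'))
        with pytest.raises(FormatError, match="interval 1"):
            read_textgrid(p)

    def test_not_a_textgrid(self, tmp_path):
        p = tmp_path / "g.TextGrid"
        p.write_text("just some text\n")
        with pytest.raises(FormatError):
            read_textgrid(p)

    def test_write_read_roundtrip_precision(self, tmp_path):
        grid = ptg.loads(LONG_GRID)
        p = tmp_path / "out.TextGrid"
        ptg.dump(grid, p)
        back = ptg.load(p)
        for t1, t2 in zip(grid.tiers, back.tiers):
            assert t1.name == t2.name
            for a, b in zip(t1.intervals, t2.intervals):
                assert abs(a.xmin - b.xmin) < 1e-6
                assert abs(a.xmax - b.xmax) < 1e-6
                assert a.text == b.text


class TestTargetPitch:
    def test_constant_signal(self):
        assert estimate_target_pitch(
            [(0.0, 150.0, 1.0), (0.01, 150.0, 9.0)]
        ) == pytest.approx(150.0)

    def test_intensity_weighting(self):
        # (1*100 + 3*200) / 4 = 175
        assert estimate_target_pitch(
            [(0.0, 100.0, 1.0), (0.02, 200.0, 3.0)]
        ) == pytest.approx(175.0)

    def test_single_sample(self):
        assert estimate_target_pitch([(0.0, 120.0, 2.0)]) == pytest.approx(120.0)

    def test_unvoiced_samples_excluded(self):
        est = estimate_target_pitch(
            [(0.0, 0.0, 99.0), (0.01, 140.0, 1.0), (0.02, float("nan"), 5.0)]
        )
        assert est == pytest.approx(140.0)

    def test_no_voiced_samples(self):
        with pytest.raises(InvalidInputError):
            estimate_target_pitch([(0.0, 0.0, 1.0)])

    @pytest.mark.parametrize("seed", range(10))
    def test_estimate_within_voiced_range(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        t = np.arange(0, 0.08, 0.005)
        f0 = rng.uniform(80, 300, len(t))
        w = rng.uniform(0, 5, len(t))
        est = estimate_target_pitch(np.c_[t, f0, w])
        assert f0.min() - 1e-9 <= est <= f0.max() + 1e-9


class TestParseExport:
    @pytest.mark.parametrize("ext", ["jsonl", "csv"])
    def test_lossless_roundtrip(self, tmp_path, fig3_tree, ext):
        p = tmp_path / f"parse.{ext}"
        write_parse(fig3_tree, p)
        assert read_parse(p) == fig3_tree

    def test_empty_parse_header_only(self, tmp_path):
        p = tmp_path / "empty.jsonl"
        write_parse(ParseTree(), p)
        tree = read_parse(p)
        assert tree.levels == [] and tree.n_levels == 0

    def test_textgrid_export_labels_in_order(self, tmp_path, fig3_tree):
        p = tmp_path / "parse.TextGrid"
        write_parse(fig3_tree, p)
        grid = ptg.load(p)
        tier = grid.tier("level1")
        texts = [iv.text for iv in tier.intervals if iv.text]
        joined = " ".join(texts)
        # the level-1 interval labels appear in parse order
        assert joined.index(":S") < joined.index(":P~")
        assert joined.index(":P~") < joined.index(":*L")
        assert joined.index(":*L") < joined.index(":R-")
        assert len(grid.tiers) == fig3_tree.n_levels

    def test_unknown_extension(self, tmp_path, fig3_tree):
        with pytest.raises(FormatError):
            write_parse(fig3_tree, tmp_path / "parse.xyz")
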