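"""Score containers, the note-table dialect, preprocessing, and MIDI I/O."""

from fractions import Fraction

import pytest

import songrhythm as sr
from songrhythm import _smf
from songrhythm.score_io import effective_ms_per_quarter, transposition_to_c
from tests.helpers import build_song, make_table


class TestNoteTable:
    def test_four_row_table_builds_one_song(self, quarter_song_table):
        corpus = sr.parse_note_table(quarter_song_table)
        assert len(corpus) == 1
        song = corpus.get("tune")
        assert len(song.phrases) == 1
        assert len(song.phrases[0].events) == 4
        assert all(ev.duration == 1 for ev in song.phrases[0].events)

    def test_rational_durations_parse_exactly(self):
        table = make_table(["t,English,folk,3/4,G,,0,0,60,1,3,0,0",
                            "t,English,folk,3/4,G,,0,1,62,2,3,0,0"])
        song = sr.parse_note_table(table).get("t")
        assert song.phrases[0].events[0].duration == Fraction(1, 3)
        assert song.phrases[0].events[1].onset == Fraction(1, 3)

    def test_round_trip_is_identity(self):
        corpus = sr.generate_corpus(sr.SynthConfig(cells={
            ("English", "children"): sr.CellConfig(3, 40.0, 5.0),
            ("French", "folk"): sr.CellConfig(2, 35.0, 5.0),
        }), seed=3)
        text = sr.serialize_note_table(corpus)
        reparsed = sr.parse_note_table(text)
        assert sr.serialize_note_table(reparsed) == text
        assert reparsed.songs == corpus.songs

    def test_phrase_index_jump_is_rejected(self):
        table = make_table(["t,English,folk,4/4,C,,0,0,60,1,1,0,0",
                            "t,English,folk,4/4,C,,2,0,60,1,1,0,0"])
        with pytest.raises(sr.ValidationError, match="jump"):
            sr.parse_note_table(table)

    def test_nonpositive_duration_is_rejected(self):
        table = make_table(["t,English,folk,4/4,C,,0,0,60,0,1,0,0"])
        with pytest.raises((sr.ParseError, sr.ValidationError)):
            sr.parse_note_table(table)

    def test_unknown_labels_are_rejected(self):
        bad_type = make_table(["t,English,opera,4/4,C,,0,0,60,1,1,0,0"])
        with pytest.raises(sr.ValidationError):
            sr.parse_note_table(bad_type)
        bad_lang = make_table(["t,Klingon,folk,4/4,C,,0,0,60,1,1,0,0"])
        with pytest.raises(sr.ValidationError):
            sr.parse_note_table(bad_lang)

    def test_malformed_row_names_line(self):
        table = make_table(["t,English,folk,4/4,C,,0,0,60,one,1,0,0"])
        with pytest.raises(sr.ParseError, match="line 2"):
            sr.parse_note_table(table)


class TestPreprocess:
    def test_tied_notes_merge_into_one_element(self):
        events = [
            sr.NoteEvent(Fraction(0), Fraction(1), 60, tie_to_next=True),
            sr.NoteEvent(Fraction(1), Fraction(1), 60),
        ]
        song = sr.Song(id="t", language="English", song_type="folk",
                       phrases=[sr.Phrase(0, events)])
        (series,) = sr.preprocess(song)
        assert series.durations == (Fraction(2),)

    @pytest.mark.parametrize(
        "rest_mode,expected",
        [("drop", (1, 1)), ("inter_onset", (2, 1))],
    )
    def test_rest_policies(self, rest_mode, expected):
        events = [
            sr.NoteEvent(Fraction(0), Fraction(1), 60),
            sr.NoteEvent(Fraction(1), Fraction(1), sr.REST),
            sr.NoteEvent(Fraction(2), Fraction(1), 60),
        ]
        song = sr.Song(id="t", language="English", song_type="folk",
                       phrases=[sr.Phrase(0, events)])
        (series,) = sr.preprocess(song, sr.PreprocessPolicy(rest_mode=rest_mode))
        assert tuple(int(d) for d in series.durations) == expected

    def test_grace_notes_are_dropped(self):
        events = [
            sr.NoteEvent(Fraction(0), Fraction(1, 8), 62, grace=True),
            sr.NoteEvent(Fraction(1, 8), Fraction(1), 60),
        ]
        song = sr.Song(id="t", language="English", song_type="folk",
                       phrases=[sr.Phrase(0, events)])
        (series,) = sr.preprocess(song)
        assert series.durations == (Fraction(1),)

    def test_all_rest_phrase_is_dropped_with_warning(self, caplog):
        events = [sr.NoteEvent(Fraction(0), Fraction(1), sr.REST)]
        note = [sr.NoteEvent(Fraction(1), Fraction(1), 60)]
        song = sr.Song(id="t", language="English", song_type="folk",
                       phrases=[sr.Phrase(0, events), sr.Phrase(1, note)])
        with caplog.at_level("WARNING"):
            series = sr.preprocess(song)
        assert len(series) == 1
        assert any("dropped" in r.message for r in caplog.records)

    def test_element_count_never_exceeds_note_count(self):
        corpus = sr.generate_corpus(sr.SynthConfig(cells={
            ("English", "folk"): sr.CellConfig(5, 45.0, 10.0),
        }), seed=9)
        for song in corpus:
            n_notes = sum(1 for ev in song.events)
            n_elements = sum(len(s) for s in sr.preprocess(song))
            assert n_elements <= n_notes
            # generator emits no ties, graces, or rests, so equality holds
            assert n_elements == n_notes


class TestMidi:
    def test_default_tempo_meta_is_600000_us(self):
        song = build_song([[1, 1, 1, 1]])
        _, _, tracks = _smf.read_smf(sr.render_midi(song))
        tempos = [e for e in tracks[0] if e.kind == "tempo"]
        assert tempos[0].data["us_per_quarter"] == 600000

    def test_notated_tempo_wins(self):
        song = build_song([[1, 1]], tempo=500.0)  # 120 bpm
        _, _, tracks = _smf.read_smf(sr.render_midi(song))
        tempos = [e for e in tracks[0] if e.kind == "tempo"]
        assert tempos[0].data["us_per_quarter"] == 500000

    @pytest.mark.parametrize("direction,shift", [("down", -7), ("up", 5)])
    def test_transposition_from_g_major(self, direction, shift):
        assert transposition_to_c("G", direction) == shift
        song = build_song([[1, 1]], key="G")
        _, _, tracks = _smf.read_smf(
            sr.render_midi(song, transpose_to_c=True, transpose_direction=direction)
        )
        ons = [e for e in tracks[0] if e.kind == "note_on"]
        assert all(e.data["pitch"] == 60 + shift for e in ons)

    def test_unknown_key_with_transpose_errors(self):
        song = build_song([[1, 1]], key="H")
        with pytest.raises(sr.ValidationError, match="key"):
            sr.render_midi(song, transpose_to_c=True)

    def test_render_parse_round_trip_preserves_durations(self, tmp_path):
        # triplets do not land on exact ticks at 480/quarter: 1/3 beat = 160 ticks
        song = build_song(
            [[Fraction(1, 3), Fraction(1, 3), Fraction(1, 3), 1], [1, Fraction(1, 2)]]
        )
        path = tmp_path / "song.mid"
        path.write_bytes(sr.render_midi(song))
        parsed = sr.parse_midi(path, phrase_policy="marker")
        tick = Fraction(1, 480)
        original = [ev.duration for ev in song.events]
        parsed_durations = [ev.duration for ev in parsed.events]
        assert len(parsed_durations) == len(original)
        assert all(abs(a - b) <= tick for a, b in zip(original, parsed_durations))
        assert len(parsed.phrases) == 2
        assert parsed.meter == (4, 4)

    def test_rest_gap_policy_splits_phrases(self):
        events1 = [sr.NoteEvent(Fraction(0), Fraction(1), 60),
                   sr.NoteEvent(Fraction(1), Fraction(1), 62)]
        events2 = [sr.NoteEvent(Fraction(4), Fraction(1), 64),
                   sr.NoteEvent(Fraction(5), Fraction(1), 65)]
        song = sr.Song(id="gap", language="English", song_type="folk",
                       phrases=[sr.Phrase(0, events1 + events2)])
        data = sr.render_midi(song)
        parsed = sr.parse_midi(data, phrase_policy="rest_gap", rest_gap_beats=2.0)
        assert len(parsed.phrases) == 2

    def test_polyphony_is_rejected(self):
        events = [
            _smf.Event(0, "note_on", {"pitch": 60, "velocity": 64}),
            _smf.Event(0, "note_on", {"pitch": 64, "velocity": 64}),
            _smf.Event(480, "note_off", {"pitch": 60}),
            _smf.Event(480, "note_off", {"pitch": 64}),
        ]
        data = _smf.write_smf([events])
        with pytest.raises(sr.PolyphonyError):
            sr.parse_midi(data)

    def test_no_notes_is_rejected(self):
        data = _smf.write_smf([[_smf.Event(0, "tempo", {"us_per_quarter": 600000})]])
        with pytest.raises(sr.ValidationError, match="no notes"):
            sr.parse_midi(data)


class TestContainers:
    def test_duplicate_song_ids_rejected(self, two_phrase_song):
        with pytest.raises(sr.ValidationError, match="duplicate"):
            sr.Corpus(songs=[two_phrase_song, two_phrase_song])

    def test_effective_tempo_rule(self):
        assert effective_ms_per_quarter(build_song([[1]])) == 600.0
        assert effective_ms_per_quarter(build_song([[1]], tempo=484.0)) == 484.0

    def test_overlapping_events_rejected(self):
        with pytest.raises(sr.ValidationError, match="overlap"):
            sr.Phrase(0, [
                sr.NoteEvent(Fraction(0), Fraction(2), 60),
                sr.NoteEvent(Fraction(1), Fraction(1), 62),
            ])

    def test_meter_denominator_restricted(self):
        with pytest.raises(sr.ValidationError, match="meter"):
            build_song([[1, 1]], meter=(4, 16))
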