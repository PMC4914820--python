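"""Shared test utilities: score builders and a naive nPVI reference."""

from fractions import Fraction

import songrhythm as sr

NOTE_TABLE_HEADER = (
    "song_id,language,song_type,meter,key,tempo_ms_per_quarter,"
    "phrase_index,note_index,pitch,duration_num,duration_den,tie_to_next,grace"
)


def make_table(rows):
    return NOTE_TABLE_HEADER + "\n" + "\n".join(rows) + "\n"


def build_song(phrase_durations, song_id="s", language="English",
               song_type="children", meter=(4, 4), key="C", tempo=None):
    """Song from nested duration lists (one inner list per phrase)."""
    phrases = []
    clock = Fraction(0)
    for index, durations in enumerate(phrase_durations):
        events = []
        for d in durations:
            d = Fraction(d)
            events.append(sr.NoteEvent(onset=clock, duration=d, pitch=60))
            clock += d
        phrases.append(sr.Phrase(index=index, events=events))
    return sr.Song(id=song_id, language=language, song_type=song_type,
                   meter=meter, key=key, tempo_ms_per_quarter=tempo,
                   phrases=phrases)


def naive_npvi(durations):
    """Reference double-loop evaluation of the defining formula."""
    total = 0.0
    m = len(durations)
    for k in range(m - 1):
        d1, d2 = durations[k], durations[k + 1]
        total += abs(d1 - d2) / ((d1 + d2) / 2.0)
    return 100.0 * total / (m - 1)
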