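"""Symbolic score containers and I/O.

The in-memory model is a :class:`Corpus` of :class:`Song` objects, each a
list of :class:`Phrase` objects holding :class:`NoteEvent` records. Durations
and onsets are exact rationals in beats (quarter note = 1), so tuplets and
dotted values survive round trips without floating-point damage; they are
converted to floats only inside the rhythm statistics.

Two serializations are supported: a tabular note-event CSV dialect (one row
per note or rest) and standard MIDI files, where phrase boundaries travel as
marker meta events named ``phrase``.
"""

from __future__ import annotations

import csv
import io
import logging
import os
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator, Literal

from . import _smf
from .errors import ParseError, PolyphonyError, ValidationError

logger = logging.getLogger(__name__)

#: Sentinel pitch value for rests.
REST = -1

LANGUAGES = ("English", "French")
SONG_TYPES = ("children", "folk")

NOTE_TABLE_COLUMNS = [
    "song_id",
    "language",
    "song_type",
    "meter",
    "key",
    "tempo_ms_per_quarter",
    "phrase_index",
    "note_index",
    "pitch",
    "duration_num",
    "duration_den",
    "tie_to_next",
    "grace",
]

# pitch class of the tonic for each supported key label; a trailing "m"
# (minor) is stripped before lookup
_KEY_PITCH_CLASS = {
    "C": 0, "B#": 0, "C#": 1, "Db": 1, "D": 2, "D#": 3, "Eb": 3, "E": 4,
    "Fb": 4, "F": 5, "E#": 5, "F#": 6, "Gb": 6, "G": 7, "G#": 8, "Ab": 8,
    "A": 9, "A#": 10, "Bb": 10, "B": 11, "Cb": 11,
}


def _validate_language(language: str) -> str:
    if language in LANGUAGES or language.startswith("synthetic:"):
        return language
    raise ValidationError(
        f"unknown language {language!r}; expected one of {LANGUAGES} or 'synthetic:<tag>'"
    )


@dataclass(frozen=True)
class NoteEvent:
    """A single note or rest with exact rational timing in beats."""

    onset: Fraction
    duration: Fraction
    pitch: int  # 0..127, or REST
    tie_to_next: bool = False
    grace: bool = False

    def __post_init__(self):
        if self.duration <= 0:
            raise ValidationError(f"duration must be positive, got {self.duration}")
        if self.onset < 0:
            raise ValidationError(f"onset must be non-negative, got {self.onset}")
        if self.pitch != REST and not 0 <= self.pitch <= 127:
            raise ValidationError(f"pitch must be 0..127 or REST, got {self.pitch}")

    @property
    def is_rest(self) -> bool:
        return self.pitch == REST


@dataclass(frozen=True)
class Phrase:
    """A contiguous sub-phrase; adjacent duration pairs inside one phrase
    enter the nPVI, pairs straddling phrase boundaries do not."""

    index: int
    events: tuple[NoteEvent, ...]

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))
        if not self.events:
            raise ValidationError(f"phrase {self.index} is empty")
        clock = None
        for ev in self.events:
            if clock is not None and ev.onset < clock:
                raise ValidationError(
                    f"phrase {self.index}: events overlap or are unsorted at onset {ev.onset}"
                )
            clock = ev.onset + ev.duration

    @property
    def end(self) -> Fraction:
        return max(ev.onset + ev.duration for ev in self.events)


@dataclass(frozen=True)
class Song:
    id: str
    language: str
    song_type: str
    meter: tuple[int, int] = (4, 4)
    key: str = "C"
    tempo_ms_per_quarter: float | None = None
    phrases: tuple[Phrase, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "phrases", tuple(self.phrases))
        _validate_language(self.language)
        if self.song_type not in SONG_TYPES:
            raise ValidationError(f"unknown song_type {self.song_type!r}")
        num, den = self.meter
        if num < 1 or den not in (2, 4, 8):
            raise ValidationError(f"unsupported meter {num}/{den}")
        if not self.phrases:
            raise ValidationError(f"song {self.id!r} has no phrases")
        if [p.index for p in self.phrases] != list(range(len(self.phrases))):
            raise ValidationError(
                f"song {self.id!r}: phrase indices must be consecutive from 0"
            )
        if self.tempo_ms_per_quarter is not None and self.tempo_ms_per_quarter <= 0:
            raise ValidationError("tempo_ms_per_quarter must be positive")

    @property
    def events(self) -> Iterator[NoteEvent]:
        for phrase in self.phrases:
            yield from phrase.events


@dataclass
class Corpus:
    songs: list[Song] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        ids = [s.id for s in self.songs]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate song ids: {dupes}")

    def __iter__(self) -> Iterator[Song]:
        return iter(self.songs)

    def __len__(self) -> int:
        return len(self.songs)

    def get(self, song_id: str) -> Song:
        for song in self.songs:
            if song.id == song_id:
                return song
        raise KeyError(song_id)


# ---------------------------------------------------------------------------
# note-table CSV dialect


def _parse_row(row: dict, lineno: int):
    try:
        num = int(row["duration_num"])
        den = int(row["duration_den"])
        if den <= 0:
            raise ValueError("duration_den must be positive")
        duration = Fraction(num, den)
        pitch = REST if row["pitch"].strip().lower() == "rest" else int(row["pitch"])
        meter_num, meter_den = (int(x) for x in row["meter"].split("/"))
        tempo_raw = row["tempo_ms_per_quarter"].strip()
        tempo = float(tempo_raw) if tempo_raw else None
        return {
            "song_id": row["song_id"],
            "language": row["language"],
            "song_type": row["song_type"],
            "meter": (meter_num, meter_den),
            "key": row["key"],
            "tempo": tempo,
            "phrase_index": int(row["phrase_index"]),
            "note_index": int(row["note_index"]),
            "pitch": pitch,
            "duration": duration,
            "tie_to_next": bool(int(row["tie_to_next"])),
            "grace": bool(int(row["grace"])),
        }
    except (KeyError, ValueError) as exc:
        raise ParseError(f"malformed note-table row ({exc})", line=lineno) from None


def parse_note_table(source) -> Corpus:
    """Read the note-event CSV dialect into a :class:`Corpus`.

    ``source`` may be a path, a text stream, or the CSV text itself.
    Durations are read as exact ``duration_num/duration_den`` rationals.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, (str, os.PathLike)) and (
        isinstance(source, os.PathLike) or ("\n" not in source and os.path.exists(source))
    ):
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = source

    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        raise ParseError("empty note table", line=1)
    missing = set(NOTE_TABLE_COLUMNS) - set(reader.fieldnames)
    if missing:
        raise ParseError(f"missing columns: {sorted(missing)}", line=1)

    rows_by_song: dict[str, list[dict]] = {}
    for lineno, row in enumerate(reader, start=2):
        parsed = _parse_row(row, lineno)
        rows_by_song.setdefault(parsed["song_id"], []).append(parsed)

    songs = []
    for song_id, rows in rows_by_song.items():
        rows.sort(key=lambda r: (r["phrase_index"], r["note_index"]))
        head = rows[0]
        phrases = []
        clock = Fraction(0)
        phrase_events: list[NoteEvent] = []
        current_phrase = 0
        if head["phrase_index"] != 0:
            raise ValidationError(f"song {song_id!r}: first phrase index must be 0")

        def flush():
            nonlocal phrase_events
            phrases.append(Phrase(index=current_phrase, events=phrase_events))
            phrase_events = []

        for row in rows:
            if row["phrase_index"] != current_phrase:
                if row["phrase_index"] != current_phrase + 1:
                    raise ValidationError(
                        f"song {song_id!r}: phrase index jumps "
                        f"{current_phrase} -> {row['phrase_index']}"
                    )
                flush()
                current_phrase = row["phrase_index"]
            if row["note_index"] != len(phrase_events):
                raise ValidationError(
                    f"song {song_id!r} phrase {current_phrase}: note_index "
                    f"{row['note_index']} out of order"
                )
            phrase_events.append(
                NoteEvent(
                    onset=clock,
                    duration=row["duration"],
                    pitch=row["pitch"],
                    tie_to_next=row["tie_to_next"],
                    grace=row["grace"],
                )
            )
            clock += row["duration"]
        flush()
        songs.append(
            Song(
                id=song_id,
                language=head["language"],
                song_type=head["song_type"],
                meter=head["meter"],
                key=head["key"],
                tempo_ms_per_quarter=head["tempo"],
                phrases=phrases,
            )
        )
    return Corpus(songs=songs, provenance="note-table")


def serialize_note_table(corpus: Corpus) -> str:
    """Inverse of :func:`parse_note_table`; emits the CSV dialect."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(NOTE_TABLE_COLUMNS)
    for song in corpus:
        tempo = "" if song.tempo_ms_per_quarter is None else repr(song.tempo_ms_per_quarter)
        for phrase in song.phrases:
            for i, ev in enumerate(phrase.events):
                writer.writerow(
                    [
                        song.id,
                        song.language,
                        song.song_type,
                        f"{song.meter[0]}/{song.meter[1]}",
                        song.key,
                        tempo,
                        phrase.index,
                        i,
                        "rest" if ev.is_rest else ev.pitch,
                        ev.duration.numerator,
                        ev.duration.denominator,
                        int(ev.tie_to_next),
                        int(ev.grace),
                    ]
                )
    return buf.getvalue()


def write_note_table(corpus: Corpus, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(serialize_note_table(corpus))


# ---------------------------------------------------------------------------
# preprocessing: song -> per-phrase duration sequences


@dataclass(frozen=True)
class PreprocessPolicy:
    """How notated events become rhythm elements.

    ``rest_mode='drop'`` (default): elements are notated note durations and
    rests vanish. ``rest_mode='inter_onset'``: element duration is the
    inter-onset interval to the next element, so rest (and dropped grace)
    time accrues to the preceding note; the final element of a phrase keeps
    its span to the phrase end.
    """

    rest_mode: Literal["drop", "inter_onset"] = "drop"


DEFAULT_POLICY = PreprocessPolicy()


def _merged_elements(phrase: Phrase) -> list[tuple[Fraction, Fraction]]:
    """(onset, duration) per element after grace removal and tie merging."""
    elements: list[tuple[Fraction, Fraction]] = []
    open_tie = False
    for ev in phrase.events:
        if ev.grace:
            continue
        if ev.is_rest:
            open_tie = False  # a rest breaks a tie chain
            continue
        if open_tie and elements:
            onset, dur = elements[-1]
            elements[-1] = (onset, dur + ev.duration)
        else:
            elements.append((ev.onset, ev.duration))
        open_tie = ev.tie_to_next
    return elements


def preprocess(song: Song, policy: PreprocessPolicy = DEFAULT_POLICY):
    """Reduce a song to per-phrase duration sequences.

    Returns a list of :class:`~songrhythm.rhythm_metrics.DurationSeries`,
    one per phrase that still has at least one element; emptied phrases are
    dropped with a logged warning.
    """
    from .rhythm_metrics import DurationSeries

    out = []
    for phrase in song.phrases:
        elements = _merged_elements(phrase)
        if not elements:
            logger.warning(
                "song %r phrase %d reduced to zero elements; dropped",
                song.id,
                phrase.index,
            )
            continue
        if policy.rest_mode == "inter_onset":
            onsets = [onset for onset, _ in elements]
            durations = [b - a for a, b in zip(onsets[:-1], onsets[1:])]
            durations.append(phrase.end - onsets[-1])
        elif policy.rest_mode == "drop":
            durations = [dur for _, dur in elements]
        else:
            raise ValidationError(f"unknown rest_mode {policy.rest_mode!r}")
        out.append(
            DurationSeries(song_id=song.id, phrase_index=phrase.index, durations=durations)
        )
    return out


# ---------------------------------------------------------------------------
# MIDI rendering and parsing

DEFAULT_BPM = 100.0
MIDI_DIVISION = 480


def effective_ms_per_quarter(song: Song, default_bpm: float = DEFAULT_BPM) -> float:
    """Notated tempo if present, otherwise the default-bpm rule
    (100 bpm = 600 ms per quarter note)."""
    if song.tempo_ms_per_quarter is not None:
        return float(song.tempo_ms_per_quarter)
    return 60000.0 / default_bpm


def transposition_to_c(key: str, direction: Literal["down", "up"] = "down") -> int:
    """Semitone shift taking the tonic of ``key`` to C (e.g. G -> -7 or +5)."""
    label = key.strip()
    if label.endswith("m") and label[:-1] in _KEY_PITCH_CLASS:
        label = label[:-1]
    if label not in _KEY_PITCH_CLASS:
        raise ValidationError(f"unknown key label {key!r}")
    pc = _KEY_PITCH_CLASS[label]
    if pc == 0:
        return 0
    return -pc if direction == "down" else 12 - pc


def render_midi(
    song: Song,
    default_bpm: float = DEFAULT_BPM,
    transpose_to_c: bool = False,
    transpose_direction: Literal["down", "up"] = "down",
    division: int = MIDI_DIVISION,
) -> bytes:
    """Render a song as a single-track standard MIDI file.

    The tempo meta event encodes the notated tempo when present, otherwise
    the default of 600 ms per quarter note. Phrase starts are written as
    marker meta events named ``phrase``.
    """
    shift = transposition_to_c(song.key, transpose_direction) if transpose_to_c else 0
    us_per_quarter = int(round(effective_ms_per_quarter(song, default_bpm) * 1000))
    events = [
        _smf.Event(0, "track_name", {"text": song.id}),
        _smf.Event(0, "time_signature", {"numerator": song.meter[0], "denominator": song.meter[1]}),
        _smf.Event(0, "tempo", {"us_per_quarter": us_per_quarter}),
    ]
    for phrase in song.phrases:
        start_tick = int(round(phrase.events[0].onset * division))
        events.append(_smf.Event(start_tick, "marker", {"text": "phrase"}))
        for ev in phrase.events:
            if ev.is_rest:
                continue
            pitch = ev.pitch + shift
            while pitch < 0:
                pitch += 12
            while pitch > 127:
                pitch -= 12
            on = int(round(ev.onset * division))
            off = max(on + 1, int(round((ev.onset + ev.duration) * division)))
            events.append(_smf.Event(on, "note_on", {"pitch": pitch, "velocity": 80}))
            events.append(_smf.Event(off, "note_off", {"pitch": pitch, "velocity": 0}))
    return _smf.write_smf([events], division=division)


def parse_midi(
    source,
    phrase_policy: Literal["marker", "rest_gap"] = "marker",
    rest_gap_beats: float = 2.0,
    song_id: str | None = None,
    language: str = "synthetic:midi",
    song_type: str = "folk",
) -> Song:
    """Parse a monophonic standard MIDI file into a :class:`Song`.

    ``source`` is a path or raw bytes. Phrase boundaries come from marker
    meta events named ``phrase`` (``marker`` policy) or from silences of at
    least ``rest_gap_beats`` between consecutive notes (``rest_gap`` policy).
    Raises :class:`PolyphonyError` when two notes overlap in time.
    """
    if isinstance(source, (bytes, bytearray)):
        data = bytes(source)
    else:
        with open(source, "rb") as fh:
            data = fh.read()
        if song_id is None:
            song_id = os.path.splitext(os.path.basename(os.fspath(source)))[0]

    _, division, tracks = _smf.read_smf(data)
    # note_off before note_on at the same tick, so back-to-back notes are
    # not misread as overlapping
    merged: list[_smf.Event] = sorted(
        (ev for track in tracks for ev in track),
        key=lambda e: (e.tick, 0 if e.kind == "note_off" else 1),
    )

    meter = (4, 4)
    tempo_ms = None
    name = None
    markers: list[Fraction] = []
    notes: list[tuple[Fraction, Fraction, int]] = []  # (onset, duration, pitch)
    active: dict[int, int] = {}  # pitch -> on tick

    for ev in merged:
        beat = Fraction(ev.tick, division)
        if ev.kind == "time_signature":
            meter = (ev.data["numerator"], ev.data["denominator"])
        elif ev.kind == "tempo" and tempo_ms is None:
            tempo_ms = ev.data["us_per_quarter"] / 1000.0
        elif ev.kind == "track_name" and name is None:
            name = ev.data["text"]
        elif ev.kind == "marker" and ev.data["text"].strip().lower() == "phrase":
            markers.append(beat)
        elif ev.kind == "note_on":
            if active:
                raise PolyphonyError(
                    [Fraction(t, division) for t in active.values()] + [beat]
                )
            active[ev.data["pitch"]] = ev.tick
        elif ev.kind == "note_off":
            on_tick = active.pop(ev.data["pitch"], None)
            if on_tick is None:
                continue
            duration = Fraction(ev.tick - on_tick, division)
            if duration > 0:
                notes.append((Fraction(on_tick, division), duration, ev.data["pitch"]))
    if not notes:
        raise ValidationError("MIDI file contains no notes")
    notes.sort()

    if phrase_policy == "marker" and markers:
        boundaries = sorted(set(markers))
    elif phrase_policy == "rest_gap" or not markers:
        boundaries = [notes[0][0]]
        for (on_a, dur_a, _), (on_b, _, _) in zip(notes[:-1], notes[1:]):
            if on_b - (on_a + dur_a) >= rest_gap_beats:
                boundaries.append(on_b)
    else:  # pragma: no cover
        raise ValidationError(f"unknown phrase policy {phrase_policy!r}")

    groups: list[list[NoteEvent]] = [[] for _ in boundaries]
    for onset, duration, pitch in notes:
        idx = 0
        for i, b in enumerate(boundaries):
            if onset >= b:
                idx = i
        groups[idx].append(NoteEvent(onset=onset, duration=duration, pitch=pitch))
    phrases = [
        Phrase(index=i, events=g) for i, g in enumerate(g for g in groups if g)
    ]
    return Song(
        id=song_id or name or "midi",
        language=language,
        song_type=song_type,
        meter=meter,
        key="C",
        tempo_ms_per_quarter=tempo_ms,
        phrases=phrases,
    )
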