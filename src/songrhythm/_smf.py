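"""Minimal standard MIDI file (SMF) reader/writer.

Supports exactly what monophonic melody stimuli need: format 0/1 files,
note on/off, set-tempo, time-signature and marker/track-name meta events,
running status on read, and variable-length delta times. Events are plain
``Event`` records with absolute tick times; delta encoding is handled here.
SMPTE (negative) divisions are not supported.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

from .errors import ParseError

__all__ = ["Event", "read_smf", "write_smf"]

DEFAULT_DIVISION = 480


@dataclass
class Event:
    """One MIDI event at an absolute tick.

    ``kind`` is one of ``note_on``, ``note_off``, ``tempo``,
    ``time_signature``, ``marker``, ``track_name``, ``end_of_track``.
    ``data`` holds kind-specific fields (``pitch``/``velocity``/``channel``,
    ``us_per_quarter``, ``numerator``/``denominator``, or ``text``).
    """

    tick: int
    kind: str
    data: dict = field(default_factory=dict)


def _encode_vlq(value: int) -> bytes:
    if value < 0:
        raise ValueError("VLQ values must be non-negative")
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


class _Cursor:
    def __init__(self, data: bytes, pos: int = 0):
        self.data = data
        self.pos = pos

    def read(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise ParseError("truncated MIDI data")
        chunk = self.data[self.pos : self.pos + n]
        self.pos += n
        return chunk

    def read_vlq(self) -> int:
        value = 0
        for _ in range(4):
            byte = self.read(1)[0]
            value = (value << 7) | (byte & 0x7F)
            if not byte & 0x80:
                return value
        raise ParseError("variable-length quantity longer than 4 bytes")


def _event_bytes(ev: Event) -> bytes:
    d = ev.data
    if ev.kind == "note_on":
        return bytes([0x90 | d.get("channel", 0), d["pitch"], d.get("velocity", 64)])
    if ev.kind == "note_off":
        return bytes([0x80 | d.get("channel", 0), d["pitch"], d.get("velocity", 0)])
    if ev.kind == "tempo":
        return b"\xff\x51\x03" + struct.pack(">I", d["us_per_quarter"])[1:]
    if ev.kind == "time_signature":
        dd = d["denominator"].bit_length() - 1
        if 1 << dd != d["denominator"]:
            raise ValueError(f"non power-of-two meter denominator {d['denominator']}")
        return bytes([0xFF, 0x58, 0x04, d["numerator"], dd, 24, 8])
    if ev.kind in ("marker", "track_name"):
        text = d["text"].encode("utf-8")
        meta_type = 0x06 if ev.kind == "marker" else 0x03
        return bytes([0xFF, meta_type]) + _encode_vlq(len(text)) + text
    if ev.kind == "end_of_track":
        return b"\xff\x2f\x00"
    raise ValueError(f"unknown event kind {ev.kind!r}")


def write_smf(tracks: list[list[Event]], division: int = DEFAULT_DIVISION) -> bytes:
    """Serialize tracks of absolute-tick events to SMF bytes (format 0 or 1)."""
    fmt = 0 if len(tracks) == 1 else 1
    out = bytearray(b"MThd" + struct.pack(">IHHH", 6, fmt, len(tracks), division))
    for track in tracks:
        events = sorted(track, key=lambda e: e.tick)
        if not events or events[-1].kind != "end_of_track":
            last = events[-1].tick if events else 0
            events = events + [Event(last, "end_of_track")]
        body = bytearray()
        prev_tick = 0
        for ev in events:
            if ev.tick < 0:
                raise ValueError("negative tick")
            body += _encode_vlq(ev.tick - prev_tick)
            body += _event_bytes(ev)
            prev_tick = ev.tick
        out += b"MTrk" + struct.pack(">I", len(body)) + bytes(body)
    return bytes(out)


# data-byte counts for channel messages, by upper nibble
_CHANNEL_DATA_LEN = {0x80: 2, 0x90: 2, 0xA0: 2, 0xB0: 2, 0xC0: 1, 0xD0: 1, 0xE0: 2}

_META_KINDS = {0x51: "tempo", 0x58: "time_signature", 0x06: "marker", 0x03: "track_name"}


def _read_track(cur: _Cursor, length: int) -> list[Event]:
    end = cur.pos + length
    events: list[Event] = []
    tick = 0
    running_status: int | None = None
    while cur.pos < end:
        tick += cur.read_vlq()
        status = cur.read(1)[0]
        if status < 0x80:
            if running_status is None:
                raise ParseError("data byte with no running status")
            cur.pos -= 1
            status = running_status
        if status == 0xFF:
            running_status = None
            meta_type = cur.read(1)[0]
            data = cur.read(cur.read_vlq())
            if meta_type == 0x2F:
                events.append(Event(tick, "end_of_track"))
                break
            kind = _META_KINDS.get(meta_type)
            if kind == "tempo":
                events.append(Event(tick, "tempo", {"us_per_quarter": int.from_bytes(data, "big")}))
            elif kind == "time_signature":
                events.append(
                    Event(tick, "time_signature", {"numerator": data[0], "denominator": 1 << data[1]})
                )
            elif kind in ("marker", "track_name"):
                events.append(Event(tick, kind, {"text": data.decode("utf-8", "replace")}))
            # other meta events are skipped
        elif status in (0xF0, 0xF7):
            running_status = None
            cur.read(cur.read_vlq())  # sysex payload, ignored
        else:
            running_status = status
            upper = status & 0xF0
            n = _CHANNEL_DATA_LEN.get(upper)
            if n is None:
                raise ParseError(f"unexpected status byte 0x{status:02x}")
            data = cur.read(n)
            channel = status & 0x0F
            if upper == 0x90 and data[1] > 0:
                events.append(
                    Event(tick, "note_on", {"pitch": data[0], "velocity": data[1], "channel": channel})
                )
            elif upper == 0x80 or (upper == 0x90 and data[1] == 0):
                events.append(
                    Event(tick, "note_off", {"pitch": data[0], "velocity": 0, "channel": channel})
                )
            # other channel messages are skipped
    cur.pos = end
    return events


def read_smf(data: bytes) -> tuple[int, int, list[list[Event]]]:
    """Parse SMF bytes; returns ``(format, division, tracks)``.

    Tracks carry absolute tick times. Raises :class:`ParseError` on
    structural problems, including SMPTE time division.
    """
    cur = _Cursor(data)
    if cur.read(4) != b"MThd":
        raise ParseError("not a standard MIDI file (missing MThd)")
    header_len, fmt, n_tracks, division = struct.unpack(">IHHH", cur.read(10))
    if header_len != 6:
        cur.read(header_len - 6)
    if division & 0x8000:
        raise ParseError("SMPTE time division is not supported")
    if fmt not in (0, 1):
        raise ParseError(f"unsupported SMF format {fmt}")
    tracks = []
    for _ in range(n_tracks):
        while True:
            chunk_type = cur.read(4)
            (length,) = struct.unpack(">I", cur.read(4))
            if chunk_type == b"MTrk":
                break
            cur.read(length)  # alien chunk, skip
        tracks.append(_read_track(cur, length))
    return fmt, division, tracks
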