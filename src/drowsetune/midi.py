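"""Minimal standard-MIDI (SMF format 0/1) note I/O.

This is a purpose-built codec covering exactly what the music-feature
extractor needs: note-on/note-off pairing on the melody track and the
tempo map needed to convert ticks to seconds.  It does not model
controllers, program changes, SMPTE time division or multi-song (format 2)
files.

Melody selection follows a simple convention: among non-percussion tracks
(channel 10 excluded) the track with the highest mean pitch is taken as
the main melody; an explicit track index can override this.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

__all__ = ["Note", "NoteSequence", "read_midi", "write_midi"]

_PERCUSSION_CHANNEL = 9  # MIDI channel 10 (0-based 9) is drums by convention


@dataclass(frozen=True)
class Note:
    """A single melody note: MIDI pitch plus onset/offset in seconds."""

    pitch: int
    start: float
    end: float

    def __post_init__(self) -> None:
        if not 0 <= self.pitch <= 127:
            raise ValueError("pitch must lie in 0..127")
        if self.end <= self.start:
            raise ValueError("note must have positive duration")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class NoteSequence:
    """Notes of one melody, ordered by onset time."""

    notes: list[Note]

    def __post_init__(self) -> None:
        if len(self.notes) == 0:
            raise ValueError("a note sequence must contain at least one note")
        self.notes = sorted(self.notes, key=lambda n: (n.start, n.pitch))

    def __len__(self) -> int:
        return len(self.notes)

    @property
    def pitches(self) -> list[int]:
        return [n.pitch for n in self.notes]

    @property
    def durations(self) -> list[float]:
        return [n.duration for n in self.notes]


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def _write_varlen(value: int) -> bytes:
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(chunks))


def _parse_track(data: bytes):
    """Yield (abs_tick, kind, payload) events of one MTrk chunk body."""
    pos = 0
    tick = 0
    status = None
    while pos < len(data):
        delta, pos = _read_varlen(data, pos)
        tick += delta
        byte = data[pos]
        if byte == 0xFF:  # meta
            meta_type = data[pos + 1]
            length, npos = _read_varlen(data, pos + 2)
            payload = data[npos : npos + length]
            pos = npos + length
            yield tick, "meta", (meta_type, payload)
            if meta_type == 0x2F:
                return
        elif byte in (0xF0, 0xF7):  # sysex: skip
            length, npos = _read_varlen(data, pos + 1)
            pos = npos + length
            status = None
        else:
            if byte & 0x80:
                status = byte
                pos += 1
            elif status is None:
                raise ValueError("running status without a prior status byte")
            kind = status & 0xF0
            channel = status & 0x0F
            n_data = 1 if kind in (0xC0, 0xD0) else 2
            args = data[pos : pos + n_data]
            pos += n_data
            if kind in (0x80, 0x90):
                yield tick, "note", (kind, channel, args[0], args[1])


class _TempoMap:
    """Piecewise-constant tempo: converts absolute ticks to seconds."""

    def __init__(self, ticks_per_beat: int, changes: list[tuple[int, int]]):
        self.tpb = ticks_per_beat
        changes = sorted(changes)
        if not changes or changes[0][0] > 0:
            changes.insert(0, (0, 500000))  # MIDI default: 120 bpm
        self._ticks = [t for t, _ in changes]
        self._secs = [0.0]
        for (t0, tempo), (t1, _) in zip(changes, changes[1:]):
            self._secs.append(self._secs[-1] + (t1 - t0) * tempo / (self.tpb * 1e6))
        self._tempi = [tempo for _, tempo in changes]

    def to_seconds(self, tick: int) -> float:
        i = 0
        for j, t in enumerate(self._ticks):
            if t <= tick:
                i = j
            else:
                break
        return self._secs[i] + (tick - self._ticks[i]) * self._tempi[i] / (self.tpb * 1e6)


def _track_notes(events, tempo_map: _TempoMap) -> tuple[list[Note], list[int]]:
    """Pair note-on/note-off events (FIFO per channel+pitch) into Notes."""
    open_notes: dict[tuple[int, int], list[int]] = {}
    notes: list[Note] = []
    channels: set[int] = set()
    for tick, kind, payload in events:
        if kind != "note":
            continue
        status_kind, channel, pitch, velocity = payload
        channels.add(channel)
        key = (channel, pitch)
        is_off = status_kind == 0x80 or velocity == 0
        if not is_off:
            open_notes.setdefault(key, []).append(tick)
        elif open_notes.get(key):
            start_tick = open_notes[key].pop(0)
            start = tempo_map.to_seconds(start_tick)
            end = tempo_map.to_seconds(tick)
            if end > start:
                notes.append(Note(pitch=pitch, start=start, end=end))
    return notes, sorted(channels)


def read_midi(path, track: int | None = None) -> NoteSequence:
    """Read the melody track of a standard MIDI file into a NoteSequence.

    Parameters
    ----------
    path : str or Path
        Format 0 or 1 file with ticks-per-beat time division.
    track : int, optional
        Explicit track index; by default the non-percussion track with the
        highest mean pitch is chosen.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != b"MThd":
        raise ValueError(f"{path}: not a standard MIDI file (missing MThd)")
    hlen, fmt, ntrks, division = struct.unpack(">IHHH", data[4:14])
    if division & 0x8000:
        raise ValueError("SMPTE time division is not supported")
    if fmt not in (0, 1):
        raise ValueError(f"unsupported MIDI format {fmt}")

    pos = 8 + hlen
    track_events = []
    while pos < len(data) and len(track_events) < ntrks:
        if data[pos : pos + 4] != b"MTrk":
            raise ValueError("malformed MIDI file: expected MTrk chunk")
        (length,) = struct.unpack(">I", data[pos + 4 : pos + 8])
        body = data[pos + 8 : pos + 8 + length]
        track_events.append(list(_parse_track(body)))
        pos += 8 + length

    tempo_changes = [
        (tick, int.from_bytes(payload[1], "big"))
        for events in track_events
        for tick, kind, payload in events
        if kind == "meta" and payload[0] == 0x51
    ]
    tempo_map = _TempoMap(division, tempo_changes)

    parsed = [_track_notes(ev, tempo_map) for ev in track_events]
    if track is not None:
        if not 0 <= track < len(parsed):
            raise ValueError(f"track index {track} out of range (file has {len(parsed)})")
        notes, _ = parsed[track]
        if not notes:
            raise ValueError(f"track {track} contains no notes")
        return NoteSequence(notes)

    candidates = [
        notes
        for notes, channels in parsed
        if notes and any(c != _PERCUSSION_CHANNEL for c in channels)
    ]
    if not candidates:
        raise ValueError(f"{path}: no non-percussion track with notes found")
    melody = max(candidates, key=lambda ns: sum(n.pitch for n in ns) / len(ns))
    return NoteSequence(melody)


def write_midi(seq: NoteSequence, path, ticks_per_beat: int = 480,
               tempo_bpm: float = 120.0) -> None:
    """Write a NoteSequence as a single-track format-0 MIDI file."""
    tempo = round(60e6 / tempo_bpm)  # microseconds per beat

    def to_tick(seconds: float) -> int:
        return round(seconds * ticks_per_beat * 1e6 / tempo)

    events: list[tuple[int, int, bytes]] = []  # (tick, order, message)
    for note in seq.notes:
        events.append((to_tick(note.start), 1, bytes([0x90, note.pitch, 64])))
        events.append((to_tick(note.end), 0, bytes([0x80, note.pitch, 0])))
    events.sort(key=lambda e: (e[0], e[1]))

    body = bytearray()
    body += _write_varlen(0) + bytes([0xFF, 0x51, 0x03]) + tempo.to_bytes(3, "big")
    last_tick = 0
    for tick, _, msg in events:
        body += _write_varlen(tick - last_tick) + msg
        last_tick = tick
    body += _write_varlen(0) + bytes([0xFF, 0x2F, 0x00])

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, ticks_per_beat))
        fh.write(b"MTrk" + struct.pack(">I", len(body)) + bytes(body))
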