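"""Minimal Standard MIDI File codec for monophonic performance capture.

Reads and writes SMF format 0/1 well enough for the pipeline's needs: note-on
events with onsets in seconds (derived from the file's tempo map and PPQ
division), deterministic event ordering, and a writer whose output round-trips
through the reader to within one tick of quantization.  Running status, meta
events and sysex are handled; SMPTE divisions are not (the study recordings
are PPQ-based).
"""

from __future__ import annotations

from pathlib import Path

from .performance_model import NoteEvent, Performance, sort_events

__all__ = ["MidiFormatError", "read_performance_midi", "write_performance_midi"]

DEFAULT_PPQ = 480
DEFAULT_TEMPO_US = 500_000  # microseconds per quarter note (120 bpm)


class MidiFormatError(ValueError):
    """Malformed SMF; the message names the offending byte offset."""


def _read_vlq(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    for _ in range(4):
        if pos >= len(data):
            raise MidiFormatError(f"truncated variable-length quantity at byte {pos}")
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos
    raise MidiFormatError(f"variable-length quantity longer than 4 bytes at byte {pos}")


def _write_vlq(value: int) -> bytes:
    if value < 0:
        raise ValueError("negative delta time")
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(chunks))


def _parse_track(data: bytes, start: int, end: int, track_no: int):
    """Yield (abs_tick, kind, payload) for one MTrk chunk body."""
    pos = start
    tick = 0
    status = None
    while pos < end:
        delta, pos = _read_vlq(data, pos)
        tick += delta
        if pos >= end:
            raise MidiFormatError(f"track {track_no}: event truncated at byte {pos}")
        byte = data[pos]
        if byte >= 0x80:
            pos += 1
            if byte == 0xFF:  # meta
                if pos + 1 > end:
                    raise MidiFormatError(f"track {track_no}: meta truncated at byte {pos}")
                mtype = data[pos]
                length, pos = _read_vlq(data, pos + 1)
                if pos + length > end:
                    raise MidiFormatError(f"track {track_no}: meta overruns at byte {pos}")
                yield tick, "meta", (mtype, data[pos : pos + length])
                pos += length
                status = None
                continue
            if byte in (0xF0, 0xF7):  # sysex
                length, pos = _read_vlq(data, pos)
                pos += length
                status = None
                continue
            status = byte
        elif status is None:
            raise MidiFormatError(
                f"track {track_no}: data byte 0x{byte:02x} with no running status at byte {pos}"
            )
        kind = status & 0xF0
        n_data = 1 if kind in (0xC0, 0xD0) else 2
        if pos + n_data > end:
            raise MidiFormatError(f"track {track_no}: channel event truncated at byte {pos}")
        args = data[pos : pos + n_data]
        pos += n_data
        if kind == 0x90 and args[1] > 0:
            yield tick, "note_on", (args[0], args[1])
        elif kind == 0x80 or (kind == 0x90 and args[1] == 0):
            yield tick, "note_off", (args[0],)


def _ticks_to_seconds(ticks, tempo_changes, ppq):
    """Convert absolute ticks to seconds under a tempo map [(tick, us_per_beat)]."""
    out = []
    for t in ticks:
        seconds = 0.0
        prev_tick, tempo = 0, DEFAULT_TEMPO_US
        for change_tick, new_tempo in tempo_changes:
            if change_tick >= t:
                break
            seconds += (change_tick - prev_tick) * tempo / (1e6 * ppq)
            prev_tick, tempo = change_tick, new_tempo
        seconds += (t - prev_tick) * tempo / (1e6 * ppq)
        out.append(seconds)
    return out


def read_performance_midi(
    path: str | Path,
    *,
    count_in: bool = False,
    count_in_beats: float = 4.0,
    **metadata,
) -> Performance:
    """Read an SMF and return a :class:`Performance` (one event per note-on).

    With ``count_in=True`` the four-beat metronome count-in is subtracted:
    onsets are shifted earlier by ``count_in_beats`` quarter notes at the
    file's initial tempo, and events before the resulting time zero are
    clamped to zero.  Trial metadata (participant, group, session, ...) is
    passed through as keyword arguments.
    """
    data = Path(path).read_bytes()
    if len(data) < 14 or data[:4] != b"MThd":
        raise MidiFormatError("missing MThd header at byte 0")
    header_len = int.from_bytes(data[4:8], "big")
    fmt = int.from_bytes(data[8:10], "big")
    n_tracks = int.from_bytes(data[10:12], "big")
    division = int.from_bytes(data[12:14], "big")
    if fmt not in (0, 1):
        raise MidiFormatError(f"unsupported SMF format {fmt} at byte 8")
    if division & 0x8000:
        raise MidiFormatError("SMPTE time division not supported (byte 12)")
    ppq = division
    if ppq == 0:
        raise MidiFormatError("zero PPQ division at byte 12")

    pos = 8 + header_len
    events: list[tuple[int, str, tuple]] = []
    tempo_changes: list[tuple[int, int]] = []
    for track_no in range(n_tracks):
        if pos + 8 > len(data) or data[pos : pos + 4] != b"MTrk":
            raise MidiFormatError(f"missing MTrk chunk for track {track_no} at byte {pos}")
        length = int.from_bytes(data[pos + 4 : pos + 8], "big")
        body_start, body_end = pos + 8, pos + 8 + length
        if body_end > len(data):
            raise MidiFormatError(f"track {track_no} overruns file at byte {pos + 4}")
        for tick, kind, payload in _parse_track(data, body_start, body_end, track_no):
            if kind == "meta" and payload[0] == 0x51 and len(payload[1]) == 3:
                tempo_changes.append((tick, int.from_bytes(payload[1], "big")))
            elif kind in ("note_on", "note_off"):
                events.append((tick, kind, payload))
        pos = body_end

    tempo_changes.sort()
    initial_tempo = tempo_changes[0][1] if tempo_changes and tempo_changes[0][0] == 0 else (
        tempo_changes[0][1] if tempo_changes else DEFAULT_TEMPO_US
    )

    ons = [(t, p[0]) for t, k, p in events if k == "note_on"]
    offs = [(t, p[0]) for t, k, p in events if k == "note_off"]
    on_secs = _ticks_to_seconds([t for t, _ in ons], tempo_changes, ppq)
    off_secs = _ticks_to_seconds([t for t, _ in offs], tempo_changes, ppq)

    offset = count_in_beats * initial_tempo / 1e6 if count_in else 0.0

    # pair note-offs FIFO per pitch for durations
    pending: dict[int, list[float]] = {}
    for sec, pitch in sorted(zip(on_secs, (p for _, p in ons))):
        pending.setdefault(pitch, []).append(sec)
    durations: dict[tuple[int, float], float] = {}
    for sec, pitch in sorted(zip(off_secs, (p for _, p in offs))):
        queue = pending.get(pitch, [])
        if queue and queue[0] <= sec:
            start = queue.pop(0)
            durations[(pitch, start)] = sec - start

    note_events = []
    for sec, pitch in zip(on_secs, (p for _, p in ons)):
        onset = max(0.0, sec - offset)
        note_events.append(NoteEvent(pitch=pitch, onset=onset, duration=durations.get((pitch, sec))))
    return Performance(events=sort_events(note_events), **metadata)


def write_performance_midi(
    performance: Performance,
    path: str | Path,
    *,
    ppq: int = DEFAULT_PPQ,
    tempo_us: int = DEFAULT_TEMPO_US,
    default_duration: float = 0.25,
) -> None:
    """Write a format-0 SMF whose note-on times, read back, reproduce the
    performance onsets to within one tick at the written PPQ."""
    ticks_per_second = ppq * 1e6 / tempo_us
    items: list[tuple[int, int, int, int]] = []  # (tick, order, status, pitch)
    for ev in performance.events:
        on_tick = round(ev.onset * ticks_per_second)
        dur = ev.duration if ev.duration is not None else default_duration
        off_tick = max(on_tick + 1, round((ev.onset + dur) * ticks_per_second))
        items.append((on_tick, 1, 0x90, ev.pitch))
        items.append((off_tick, 0, 0x80, ev.pitch))
    items.sort()

    body = bytearray()
    body += _write_vlq(0) + bytes([0xFF, 0x51, 0x03]) + tempo_us.to_bytes(3, "big")
    prev_tick = 0
    for tick, _, status, pitch in items:
        body += _write_vlq(tick - prev_tick)
        body += bytes([status, pitch, 64 if status == 0x90 else 0])
        prev_tick = tick
    body += _write_vlq(0) + bytes([0xFF, 0x2F, 0x00])  # end of track

    out = bytearray()
    out += b"MThd" + (6).to_bytes(4, "big")
    out += (0).to_bytes(2, "big") + (1).to_bytes(2, "big") + ppq.to_bytes(2, "big")
    out += b"MTrk" + len(body).to_bytes(4, "big") + body
    Path(path).write_bytes(bytes(out))
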