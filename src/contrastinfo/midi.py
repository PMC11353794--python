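"""Minimal read-only Standard MIDI File parser for monophonic melodies.

Parses format 0/1 files, extracts note_on/note_off pairs, and converts
delta ticks to beats using the header division.  Overlapping notes
(polyphony) are rejected: the information profiles here are defined for
melodies, one pitch sounding at a time.
"""

from __future__ import annotations

import struct

__all__ = ["read_monophonic_midi"]


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def _track_events(data: bytes):
    """Yield (abs_ticks, status, payload) from one track chunk body."""
    pos = 0
    ticks = 0
    running = None
    while pos < len(data):
        delta, pos = _read_varlen(data, pos)
        ticks += delta
        status = data[pos]
        if status & 0x80:
            pos += 1
            if status < 0xF0:
                running = status
        else:
            if running is None:
                raise ValueError("running status without prior status byte")
            status = running
        if status == 0xFF:  # meta event
            pos += 1  # meta type
            length, pos = _read_varlen(data, pos)
            pos += length
            yield ticks, status, b""
        elif status in (0xF0, 0xF7):  # sysex
            length, pos = _read_varlen(data, pos)
            pos += length
        else:
            nbytes = 1 if (status & 0xF0) in (0xC0, 0xD0) else 2
            payload = data[pos : pos + nbytes]
            pos += nbytes
            yield ticks, status, payload


def read_monophonic_midi(path) -> list[tuple[int, float, float]]:
    """Read a monophonic SMF; returns (note, onset_beats, duration_beats) triples."""
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != b"MThd":
        raise ValueError(f"{path}: not a Standard MIDI File")
    hlen, fmt, _ntracks, division = struct.unpack(">IHHH", data[4:14])
    if fmt not in (0, 1):
        raise ValueError(f"{path}: unsupported SMF format {fmt}")
    if division & 0x8000:
        raise ValueError(f"{path}: SMPTE time division not supported")
    pos = 8 + hlen
    notes: list[tuple[int, float, float]] = []
    while pos < len(data):
        if data[pos : pos + 4] != b"MTrk":
            raise ValueError(f"{path}: bad track chunk at offset {pos}")
        (length,) = struct.unpack(">I", data[pos + 4 : pos + 8])
        body = data[pos + 8 : pos + 8 + length]
        pos += 8 + length
        active: tuple[int, int] | None = None  # (note, onset_ticks)
        for ticks, status, payload in _track_events(body):
            kind = status & 0xF0
            if kind == 0x90 and payload[1] > 0:  # note on
                if active is not None:
                    raise ValueError(
                        f"{path}: polyphony at tick {ticks}; only melodies are supported"
                    )
                active = (payload[0], ticks)
            elif kind == 0x80 or (kind == 0x90 and payload[1] == 0):  # note off
                if active is None or active[0] != payload[0]:
                    continue
                note, onset = active
                notes.append((note, onset / division, (ticks - onset) / division))
                active = None
    notes.sort(key=lambda t: t[1])
    for (_, t0, d0), (_, t1, _) in zip(notes, notes[1:]):
        if t1 < t0 + d0 - 1e-9:
            raise ValueError(f"{path}: overlapping notes; only melodies are supported")
    return notes
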