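"""Event sequences and file I/O (CSV/JSON/MIDI in, TSV profiles out)."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

__all__ = ["EventSequence", "read_events", "write_events", "write_profile", "midi_to_hz"]


def midi_to_hz(note: float) -> float:
    """Equal-temperament fundamental frequency of a MIDI note (A4 = 69 = 440 Hz)."""
    return 440.0 * 2.0 ** ((note - 69) / 12.0)


@dataclass(frozen=True)
class EventSequence:
    """A realised sequence of events, symbolic or real-valued, timed or not.

    ``values`` holds one symbol (or real) per event; ``onsets`` and
    ``durations`` are present only in continuous time mode, with onsets
    strictly increasing and durations positive.
    """

    values: tuple
    onsets: tuple | None = None
    durations: tuple | None = None
    kind: str = "symbolic"  # symbolic | real
    time_mode: str = "discrete"  # discrete | continuous

    def __init__(self, values, onsets=None, durations=None, kind="symbolic",
                 time_mode=None):
        values = tuple(values)
        if kind not in ("symbolic", "real"):
            raise ValueError(f"kind must be 'symbolic' or 'real', got {kind!r}")
        if time_mode is None:
            time_mode = "continuous" if onsets is not None else "discrete"
        if time_mode == "continuous":
            if onsets is None or durations is None:
                raise ValueError("continuous sequences need onsets and durations")
            onsets = tuple(float(t) for t in onsets)
            durations = tuple(float(d) for d in durations)
            if not (len(values) == len(onsets) == len(durations)):
                raise ValueError("values/onsets/durations length mismatch")
            for i in range(1, len(onsets)):
                if onsets[i] <= onsets[i - 1]:
                    raise ValueError(f"onsets not strictly increasing at index {i}")
            for i, d in enumerate(durations):
                if d <= 0:
                    raise ValueError(f"non-positive duration at index {i}")
        else:
            if onsets is not None:
                raise ValueError("discrete sequences carry no onsets")
            durations = None
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "time_mode", time_mode)

    def __len__(self) -> int:
        return len(self.values)

    def timed_events(self) -> list[tuple]:
        """(value, onset, duration) triples; continuous mode only."""
        if self.time_mode != "continuous":
            raise ValueError("sequence has no timing information")
        return list(zip(self.values, self.onsets, self.durations))


def _parse_value(raw: str, kind: str):
    return float(raw) if kind == "real" else raw


def read_events(path, format: str | None = None, kind: str = "symbolic") -> EventSequence:
    """Read an event sequence from CSV, JSON, or a monophonic MIDI file.

    CSV must carry the header ``onset,duration,value``; empty onset and
    duration columns give a discrete-time sequence.  MIDI notes map to
    their note number in symbolic mode or to Hz in real mode.
    """
    path = str(path)
    if format is None:
        ext = path.rsplit(".", 1)[-1].lower()
        format = {"csv": "csv", "json": "json", "mid": "midi", "midi": "midi"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer format from {path!r}")
    if format == "csv":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip() for h in header] != ["onset", "duration", "value"]:
                raise ValueError(f"{path}: expected header 'onset,duration,value'")
            values, onsets, durations = [], [], []
            timed = None
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
                onset, duration, value = (c.strip() for c in row)
                row_timed = bool(onset or duration)
                if timed is None:
                    timed = row_timed
                elif timed != row_timed:
                    raise ValueError(f"{path}:{lineno}: mixed timed and untimed rows")
                values.append(_parse_value(value, kind))
                if row_timed:
                    try:
                        onsets.append(float(onset))
                        durations.append(float(duration))
                    except ValueError:
                        raise ValueError(f"{path}:{lineno}: bad onset/duration") from None
        if timed:
            return EventSequence(values, onsets, durations, kind=kind)
        return EventSequence(values, kind=kind)
    if format == "json":
        with open(path) as fh:
            d = json.load(fh)
        events = d["events"]
        values = [_parse_value(str(e["value"]), kind) if kind == "real" else e["value"]
                  for e in events]
        if events and events[0].get("onset") is not None:
            return EventSequence(
                values,
                [e["onset"] for e in events],
                [e["duration"] for e in events],
                kind=kind,
            )
        return EventSequence(values, kind=kind)
    if format == "midi":
        from .midi import read_monophonic_midi

        notes = read_monophonic_midi(path)
        values = [midi_to_hz(n) if kind == "real" else n for n, _, _ in notes]
        return EventSequence(
            values, [t for _, t, _ in notes], [d for _, _, d in notes], kind=kind
        )
    raise ValueError(f"unknown format {format!r}")


def write_events(seq: EventSequence, path) -> None:
    """Write a sequence as CSV with header onset,duration,value (round-trips)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["onset", "duration", "value"])
        if seq.time_mode == "continuous":
            for v, t, d in seq.timed_events():
                writer.writerow([repr(t), repr(d), v])
        else:
            for v in seq.values:
                writer.writerow(["", "", v])


def write_profile(profile: pd.DataFrame, path) -> None:
    """Write an information profile as a TSV file."""
    profile.to_csv(path, sep="\t", index=False)
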