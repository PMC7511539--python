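"""Domain types for target melodies and recorded keypress performances.

The study task is monophonic: a learner reproduces a 12-note melody (five
unique pitches A4-E5, quarter and eighth notes, 75 bpm) on a MIDI keyboard.
A *performance* is the ordered list of timed note-on events recorded during
one test trial; a *melody* is the target pitch/value sequence together with
the inter-onset intervals (IOIs) it implies at its notated tempo.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "NoteEvent",
    "Melody",
    "Performance",
    "MatchResult",
    "AccuracyScore",
    "note_name_to_midi",
    "midi_to_note_name",
    "melody_from_spec",
    "melody_to_spec",
    "read_melody_json",
    "write_melody_json",
    "read_melody_csv",
    "write_melody_csv",
    "sort_events",
]

_NOTE_OFFSETS = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}
_NAME_RE = re.compile(r"^([A-Ga-g])([#b]?)(-?\d+)$")

# Study-melody invariants (strict mode)
STUDY_LENGTH = 12
STUDY_PITCH_SET = frozenset({69, 71, 72, 74, 76})  # A4 B4 C5 D5 E5
STUDY_TEMPO_BPM = 75.0
STUDY_NOTE_VALUES = frozenset({1.0, 0.5})


def note_name_to_midi(name: str) -> int:
    """Convert scientific pitch notation (e.g. ``'A4'``, ``'C#5'``) to a MIDI number."""
    m = _NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"unknown pitch name: {name!r}")
    letter, accidental, octave = m.groups()
    semitone = _NOTE_OFFSETS[letter.upper()]
    if accidental == "#":
        semitone += 1
    elif accidental == "b":
        semitone -= 1
    midi = 12 * (int(octave) + 1) + semitone
    if not 0 <= midi <= 127:
        raise ValueError(f"pitch {name!r} outside MIDI range 0-127")
    return midi


def midi_to_note_name(midi: int) -> str:
    names = ["C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B"]
    return f"{names[midi % 12]}{midi // 12 - 1}"


@dataclass(frozen=True)
class NoteEvent:
    """One keypress: MIDI pitch and onset time in seconds from trial start
    (trial start = end of the four-beat metronome count-in)."""

    pitch: int
    onset: float
    duration: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.pitch <= 127:
            raise ValueError(f"pitch {self.pitch} outside 0-127")
        if self.onset < 0:
            raise ValueError(f"negative onset {self.onset}")


@dataclass(frozen=True)
class Melody:
    """Target note sequence with derived expected inter-onset intervals.

    ``expected_iois[i]`` is the expected time between the onsets of notes
    ``i`` and ``i+1``: ``note_values[i] * 60 / tempo_bpm`` seconds.  The final
    note's value contributes no IOI, so there are ``len(pitches) - 1`` of them.
    """

    pitches: tuple[int, ...]
    note_values: tuple[float, ...]
    tempo_bpm: float
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.pitches) != len(self.note_values):
            raise ValueError("pitches and note_values must have equal length")
        if self.tempo_bpm <= 0:
            raise ValueError("tempo must be positive")

    @property
    def beat_seconds(self) -> float:
        return 60.0 / self.tempo_bpm

    @property
    def expected_iois(self) -> tuple[float, ...]:
        b = self.beat_seconds
        return tuple(v * b for v in self.note_values[:-1])

    @property
    def grid_onsets(self) -> tuple[float, ...]:
        """Expected onset of each note on the tempo grid, from trial-start zero."""
        out, t = [], 0.0
        for ioi in (0.0,) + self.expected_iois:
            t += ioi
            out.append(t)
        return tuple(out)

    def __len__(self) -> int:
        return len(self.pitches)

    def validate_study_melody(self) -> None:
        """Raise if this melody violates the study-stimulus structure
        (12 notes, pitches within A4-E5 set, quarter/eighth values, 75 bpm)."""
        if len(self) != STUDY_LENGTH:
            raise ValueError(f"study melody must have {STUDY_LENGTH} notes, got {len(self)}")
        if not set(self.pitches) <= STUDY_PITCH_SET:
            bad = sorted(set(self.pitches) - STUDY_PITCH_SET)
            raise ValueError(f"pitches outside study set: {[midi_to_note_name(p) for p in bad]}")
        if not set(self.note_values) <= STUDY_NOTE_VALUES:
            raise ValueError("study melodies use only quarter (1.0) and eighth (0.5) values")
        if self.tempo_bpm != STUDY_TEMPO_BPM:
            raise ValueError(f"study tempo is {STUDY_TEMPO_BPM} bpm, got {self.tempo_bpm}")


GROUPS = ("HIIT", "LIIT")
PHASES = ("familiarization", "acquisition", "retention", "transfer")
SESSIONS = ("Acq", "R1h", "R24h", "R7d", "Tran")
TRIAL_TYPES = ("listen", "train", "test")


@dataclass(frozen=True)
class Performance:
    """Ordered timed keypresses for one trial plus its metadata.

    Events are kept sorted by onset, ties broken by ascending pitch, so that
    scoring is deterministic.  Only test trials carry dependent measures.
    """

    events: tuple[NoteEvent, ...]
    participant_id: str = ""
    group: str | None = None
    phase: str | None = None
    session: str | None = None
    block: int | None = None
    trial_type: str = "test"
    trial_index: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", sort_events(self.events))
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")

    @property
    def pitches(self) -> tuple[int, ...]:
        return tuple(e.pitch for e in self.events)

    @property
    def onsets(self) -> tuple[float, ...]:
        return tuple(e.onset for e in self.events)

    def __len__(self) -> int:
        return len(self.events)


def sort_events(events: Iterable[NoteEvent]) -> tuple[NoteEvent, ...]:
    """Total deterministic order: onset, then ascending pitch (simultaneous
    presses in a monophonic task are participant error; serializing them by
    pitch keeps scoring reproducible)."""
    return tuple(sorted(events, key=lambda e: (e.onset, e.pitch)))


@dataclass(frozen=True)
class MatchResult:
    """Order-preserving alignment: (performance_index, target_index) pairs,
    both index sequences strictly increasing."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for (p0, t0), (p1, t1) in zip(self.pairs, self.pairs[1:]):
            if p1 <= p0 or t1 <= t0:
                raise ValueError("alignment indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class AccuracyScore:
    """Pitch and rhythm accuracy for one test trial, with the counts and the
    alignment they were computed from."""

    pitch_accuracy: float
    rhythm_accuracy: float
    n_correct_notes: int
    n_performed: int
    n_target: int
    n_correct_iois: int
    n_performed_iois: int
    alignment: MatchResult

    def __post_init__(self) -> None:
        if not 0 <= self.pitch_accuracy <= 100 or not 0 <= self.rhythm_accuracy <= 100:
            raise ValueError("accuracies must lie in [0, 100]")
        if self.n_correct_notes > min(self.n_performed, self.n_target):
            raise ValueError("matched notes exceed sequence lengths")


# ---------------------------------------------------------------------------
# Melody construction and serialization
# ---------------------------------------------------------------------------

_VALUE_NAMES = {"quarter": 1.0, "eighth": 0.5, "half": 2.0, "sixteenth": 0.25}


def _coerce_pitch(p: int | str) -> int:
    if isinstance(p, str):
        return note_name_to_midi(p)
    p = int(p)
    if not 0 <= p <= 127:
        raise ValueError(f"pitch {p} outside 0-127")
    return p


def _coerce_value(v: float | str) -> float:
    if isinstance(v, str):
        try:
            return _VALUE_NAMES[v.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown note value {v!r}") from None
    v = float(v)
    if v <= 0:
        raise ValueError("note values must be positive")
    return v


def melody_from_spec(
    pitches: Sequence[int | str],
    note_values: Sequence[float | str],
    tempo_bpm: float,
    name: str = "",
    strict: bool = False,
) -> Melody:
    """Build a :class:`Melody` from named or numeric pitches and note values.

    With ``strict=True`` the study-stimulus invariants are enforced
    (12 notes over A4-E5, quarter/eighth values, 75 bpm).
    """
    if tempo_bpm <= 0:
        raise ValueError("tempo must be positive")
    mel = Melody(
        pitches=tuple(_coerce_pitch(p) for p in pitches),
        note_values=tuple(_coerce_value(v) for v in note_values),
        tempo_bpm=float(tempo_bpm),
        name=name,
    )
    if strict:
        mel.validate_study_melody()
    return mel


def melody_to_spec(melody: Melody) -> dict:
    """Inverse of :func:`melody_from_spec` (named pitches, numeric values)."""
    return {
        "name": melody.name,
        "tempo_bpm": melody.tempo_bpm,
        "notes": [
            {"pitch": midi_to_note_name(p), "note_value": v}
            for p, v in zip(melody.pitches, melody.note_values)
        ],
    }


def write_melody_json(melody: Melody, path: str | Path) -> None:
    Path(path).write_text(json.dumps(melody_to_spec(melody), indent=2))


def read_melody_json(path: str | Path, strict: bool = False) -> Melody:
    spec = json.loads(Path(path).read_text())
    notes = spec["notes"]
    return melody_from_spec(
        [n["pitch"] for n in notes],
        [n["note_value"] for n in notes],
        spec["tempo_bpm"],
        name=spec.get("name", ""),
        strict=strict,
    )


def write_melody_csv(melody: Melody, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pitch", "note_value", "tempo_bpm"])
        for p, v in zip(melody.pitches, melody.note_values):
            w.writerow([midi_to_note_name(p), v, melody.tempo_bpm])


def read_melody_csv(path: str | Path, strict: bool = False) -> Melody:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ValueError(f"empty melody file: {path}")
    tempo = float(rows[0]["tempo_bpm"])
    return melody_from_spec(
        [r["pitch"] for r in rows],
        [float(r["note_value"]) for r in rows],
        tempo,
        strict=strict,
    )
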