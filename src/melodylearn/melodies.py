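"""Packaged placeholder melodies with the study-stimulus structure.

The original two target melodies and three familiarization melodies are
published only as engraved notation images, not as note text, so the package
ships *synthetic placeholders* that satisfy every stated structural
constraint: 12 notes drawn from the five pitches A4, B4, C5, D5, E5; only
quarter and eighth note values; tempo 75 bpm.  Familiarization melodies are
short all-quarter sequences over the same five keys.  Analyses that depend
only on this structure (scoring arithmetic, tolerance ranges, simulation)
are unaffected by the substitution.
"""

from __future__ import annotations

from .performance_model import Melody, melody_from_spec

__all__ = [
    "acquisition_melody",
    "transfer_melody",
    "familiarization_melodies",
    "study_melodies",
]

_Q, _E = 1.0, 0.5


def acquisition_melody() -> Melody:
    """Synthetic placeholder for study melody 1 (7 quarters + 5 eighths)."""
    return melody_from_spec(
        ["C5", "D5", "E5", "D5", "C5", "B4", "C5", "A4", "B4", "C5", "D5", "C5"],
        [_Q, _Q, _E, _E, _Q, _E, _E, _Q, _Q, _Q, _Q, _E],
        75,
        name="study-melody-1 (synthetic placeholder)",
        strict=True,
    )


def transfer_melody() -> Melody:
    """Synthetic placeholder for study melody 2, difficulty-matched in
    structure (12 notes, same pitch set, quarters and eighths, 75 bpm)."""
    return melody_from_spec(
        ["E5", "D5", "C5", "D5", "E5", "E5", "C5", "B4", "A4", "B4", "C5", "C5"],
        [_Q, _E, _E, _Q, _Q, _E, _E, _Q, _Q, _E, _E, _Q],
        75,
        name="study-melody-2 (synthetic placeholder)",
        strict=True,
    )


def familiarization_melodies() -> tuple[Melody, Melody, Melody]:
    """Three simple synthetic placeholder melodies used to teach the trial types."""
    specs = [
        (["C5", "D5", "E5", "D5", "C5"], "familiarization-1"),
        (["A4", "B4", "C5", "B4", "A4"], "familiarization-2"),
        (["C5", "E5", "C5", "A4", "C5"], "familiarization-3"),
    ]
    return tuple(
        melody_from_spec(p, [_Q] * len(p), 75, name=f"{n} (synthetic placeholder)")
        for p, n in specs
    )


def study_melodies() -> tuple[Melody, Melody]:
    return acquisition_melody(), transfer_melody()
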