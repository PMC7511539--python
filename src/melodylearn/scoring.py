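"""Pitch and rhythm accuracy for piano-melody test trials.

Pitch accuracy: sub-sequences of the target pitch sequence are identified in
the performed sequence via a maximum-cardinality order-preserving match
(longest common subsequence).  The matched-note count is divided by the
longer of the target length and the number of performed notes, so extra
notes are penalized.

Rhythm accuracy: the percentage of inter-onset intervals (IOIs) within a
tolerance (default +/-10%) of the expected IOI.  Each matched note with a
preceding matched (i.e. correct) note is referenced to that note; the
expected interval is the sum of the melody's expected IOIs spanning the two
matched target positions, which absorbs natural timing drift earlier in the
trial.  A first matched note with no preceding correct note is referenced to
the melody's tempo grid.  The denominator is the longer of the target IOI
count and the performed IOI count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

from .performance_model import AccuracyScore, MatchResult, Melody, Performance

__all__ = [
    "RhythmTolerance",
    "match_pitches",
    "pitch_accuracy",
    "rhythm_accuracy",
    "acceptable_tempo_range",
    "score_trial",
]

FirstNoteRule = Literal["grid", "lenient"]


@dataclass(frozen=True)
class RhythmTolerance:
    """Relative IOI tolerance.  ``fraction`` is the study criterion (10%);
    ``legacy_fraction`` is the more lenient prior-literature criterion (30%)."""

    fraction: float = 0.10
    legacy_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not 0 <= self.fraction < 1:
            raise ValueError("tolerance fraction must lie in [0, 1)")


def match_pitches(
    performed_pitches: Sequence[int], target_pitches: Sequence[int]
) -> MatchResult:
    """Maximum-cardinality order-preserving pitch match (LCS), leftmost.

    Among all maximum matchings, each pair greedily takes the earliest
    feasible performance index and then the earliest feasible target index,
    which makes the downstream rhythm scoring deterministic.
    """
    a, b = list(performed_pitches), list(target_pitches)
    n, m = len(a), len(b)
    # L[i][j] = LCS length of a[i:], b[j:]
    L = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row, nxt = L[i], L[i + 1]
        ai = a[i]
        for j in range(m - 1, -1, -1):
            if ai == b[j]:
                row[j] = nxt[j + 1] + 1
            else:
                row[j] = nxt[j] if nxt[j] >= row[j + 1] else row[j + 1]
    pairs = []
    i = j = 0
    while i < n and j < m and L[i][j] > 0:
        # match performance index i at the earliest target position that still
        # permits a maximum matching; if none exists, i is skippable for free
        for jj in range(j, m):
            if a[i] == b[jj] and 1 + L[i + 1][jj + 1] == L[i][j]:
                pairs.append((i, jj))
                j = jj + 1
                break
        i += 1
    return MatchResult(pairs=tuple(pairs))


def pitch_accuracy(match: MatchResult, n_target: int, n_performed: int) -> float:
    """100 x matched notes / max(target length, performed length)."""
    if n_target < 1:
        raise ValueError("target melody must contain at least one note")
    return 100.0 * len(match) / max(n_target, n_performed)


def rhythm_accuracy(
    performance: Performance,
    melody: Melody,
    match: MatchResult,
    tol: RhythmTolerance | float = RhythmTolerance(),
    first_note: FirstNoteRule = "grid",
) -> float:
    """Percentage of correct IOIs under the preceding-correct-note rule.

    For each matched note with a preceding matched note the observed interval
    (onset difference of the two performance events) is compared with the
    expected interval (sum of melody IOIs between the two target positions);
    it is correct when the relative deviation is at most the tolerance
    (boundary inclusive).  A first matched note aligned past the start of the
    target is referenced to its expected onset on the tempo grid; when it is
    aligned to the very first target note the grid-expected onset is zero and
    no interval is countable for it.  ``first_note="lenient"`` counts the
    grid-referenced first note as correct unconditionally.

    Returns ``100 x n_correct / max(n_target - 1, n_performed - 1)``; a
    performance with fewer than two events scores 0 against a multi-note
    target.
    """
    frac = tol.fraction if isinstance(tol, RhythmTolerance) else float(tol)
    n_target = len(melody)
    n_performed = len(performance)
    if n_target < 2:
        raise ValueError("rhythm scoring needs a target with at least two notes")
    denom = max(n_target - 1, n_performed - 1)
    if n_performed < 2 and not match.pairs:
        return 0.0

    onsets = performance.onsets
    for p_idx, t_idx in match.pairs:
        if p_idx >= n_performed or t_idx >= n_target:
            raise ValueError("alignment indices inconsistent with this trial")
        if performance.pitches[p_idx] != melody.pitches[t_idx]:
            raise ValueError("alignment does not match this performance/melody pair")

    iois = melody.expected_iois
    grid = melody.grid_onsets
    # inclusive boundary with a hair of numerical slack so an exactly-10%
    # deviation is not rejected by floating-point rounding
    limit = frac * (1 + 1e-9) + 1e-12
    n_correct = 0
    prev: tuple[int, int] | None = None
    for p_idx, t_idx in match.pairs:
        if prev is None:
            expected = grid[t_idx]
            if expected > 0:
                observed = onsets[p_idx]
                if first_note == "lenient" or abs(observed - expected) / expected <= limit:
                    n_correct += 1
            # t_idx == 0: expected onset is zero; no countable interval
        else:
            p_prev, t_prev = prev
            expected = math.fsum(iois[t_prev:t_idx])
            observed = onsets[p_idx] - onsets[p_prev]
            if abs(observed - expected) / expected <= limit:
                n_correct += 1
        prev = (p_idx, t_idx)
    return 100.0 * n_correct / denom


def acceptable_tempo_range(tempo_bpm: float, tol_fraction: float) -> tuple[int, int]:
    """Integer bpm range whose uniform IOIs fall within the relative tolerance.

    A rendition at tempo T of a melody notated at ``tempo_bpm`` has every IOI
    scaled by ``tempo_bpm / T``, so the slowest acceptable tempo is
    ``tempo_bpm / (1 + tol)`` and the fastest ``tempo_bpm / (1 - tol)``,
    rounded half away from zero to the nearest integer.
    """
    if tempo_bpm <= 0:
        raise ValueError("tempo must be positive")
    if not 0 <= tol_fraction < 1:
        raise ValueError("tolerance fraction must lie in [0, 1)")

    def _round_half_away(x: float) -> int:
        return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))

    low = _round_half_away(tempo_bpm / (1 + tol_fraction))
    high = _round_half_away(tempo_bpm / (1 - tol_fraction))
    return low, high


def score_trial(
    performance: Performance,
    melody: Melody,
    tol: RhythmTolerance | float = RhythmTolerance(),
    first_note: FirstNoteRule = "grid",
) -> AccuracyScore:
    """Score one test trial: pitch match, pitch accuracy, rhythm accuracy."""
    match = match_pitches(performance.pitches, melody.pitches)
    pa = pitch_accuracy(match, len(melody), len(performance))
    ra = rhythm_accuracy(performance, melody, match, tol, first_note=first_note)
    frac = tol.fraction if isinstance(tol, RhythmTolerance) else float(tol)
    denom = max(len(melody) - 1, len(performance) - 1)
    return AccuracyScore(
        pitch_accuracy=pa,
        rhythm_accuracy=ra,
        n_correct_notes=len(match),
        n_performed=len(performance),
        n_target=len(melody),
        n_correct_iois=round(ra * denom / 100.0),
        n_performed_iois=max(len(performance) - 1, 0),
        alignment=match,
    )
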