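import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from melodylearn.performance_model import MatchResult, NoteEvent, Performance
from melodylearn.scoring import (
    RhythmTolerance,
    acceptable_tempo_range,
    match_pitches,
    pitch_accuracy,
    rhythm_accuracy,
    score_trial,
)

from conftest import render

PITCHES = [69, 71, 72, 74, 76]


def lcs_by_enumeration(a, b):
    """Independent oracle: longest common subsequence by exhaustive
    enumeration of all subsequences of ``a`` (feasible for len <= 8)."""
    best = 0
    for r in range(len(a), 0, -1):
        for idxs in itertools.combinations(range(len(a)), r):
            sub = [a[i] for i in idxs]
            it = iter(b)
            if all(any(x == y for y in it) for x in sub):
                return r
    return best


class TestMatchPitches:
    def test_identity_alignment(self, melody):
        m = match_pitches(melody.pitches, melody.pitches)
        assert m.pairs == tuple((i, i) for i in range(12))

    def test_empty_performance(self, melody):
        assert len(match_pitches([], melody.pitches)) == 0
        assert len(match_pitches(melody.pitches, melody.pitches[:0])) == 0

    def test_substitutions_and_insertion_match_oracle(self):
        target = [69, 71, 72, 74, 76, 72, 71, 69]
        performed = [69, 76, 72, 74, 74, 76, 72, 71]  # 2 substitutions + 1 inserted 74
        m = match_pitches(performed, target)
        assert len(m) == lcs_by_enumeration(performed, target)

    @given(
        st.lists(st.sampled_from(PITCHES), max_size=8),
        st.lists(st.sampled_from(PITCHES), max_size=8),
    )
    def test_cardinality_equals_enumeration_oracle(self, performed, target):
        assert len(match_pitches(performed, target)) == lcs_by_enumeration(performed, target)

    @given(
        st.lists(st.sampled_from(PITCHES), max_size=10),
        st.lists(st.sampled_from(PITCHES), max_size=10),
    )
    def test_alignment_is_valid_and_leftmost_deterministic(self, performed, target):
        m = match_pitches(performed, target)
        for p, t in m.pairs:
            assert performed[p] == target[t]
        assert m == match_pitches(performed, target)


class TestPitchAccuracy:
    def test_perfect_rendition_scores_100(self, melody, perfect_performance):
        assert score_trial(perfect_performance, melody).pitch_accuracy == 100.0

    def test_extra_notes_penalized_by_longer_denominator(self, melody):
        m = match_pitches(list(melody.pitches) + [69] * 12, melody.pitches)
        assert pitch_accuracy(m, 12, 24) == 50.0

    def test_ten_of_twelve_with_eleven_performed(self):
        # drop two target notes, append one stray: 10 matched of 12, 11 played
        target = [69, 71, 72, 74, 76, 72, 71, 69, 71, 72, 74, 76]
        performed = [t for i, t in enumerate(target) if i not in (2, 5)] + [69]
        m = match_pitches(performed, target)
        assert len(m) == 10 == lcs_by_enumeration(performed, target)
        assert pitch_accuracy(m, 12, 11) == pytest.approx(100 * 10 / 12)

    def test_zero_length_target_rejected(self):
        with pytest.raises(ValueError):
            pitch_accuracy(MatchResult(pairs=()), 0, 5)

    def test_non_increasing_in_performed_count(self):
        m = MatchResult(pairs=((0, 0), (1, 1), (2, 2)))
        values = [pitch_accuracy(m, 12, n) for n in range(3, 30)]
        assert values == sorted(values, reverse=True)

    def test_100_only_for_exact_length_match(self, melody):
        m = match_pitches(melody.pitches, melody.pitches)
        assert pitch_accuracy(m, 12, 12) == 100.0
        assert pitch_accuracy(m, 12, 13) < 100.0


class TestRhythmAccuracy:
    def test_perfect_rendition_scores_100(self, melody, perfect_performance):
        assert score_trial(perfect_performance, melody).rhythm_accuracy == 100.0

    def test_uniform_15pct_stretch_scores_0(self, melody):
        perf = render(melody, onsets=[1.15 * t for t in melody.grid_onsets])
        assert score_trial(perf, melody).rhythm_accuracy == 0.0

    def test_single_stretched_ioi_gives_10_of_11(self, melody):
        shift = 0.15 * melody.expected_iois[4]
        onsets = [t if i < 5 else t + shift for i, t in enumerate(melody.grid_onsets)]
        perf = render(melody, onsets=onsets)
        assert score_trial(perf, melody).rhythm_accuracy == pytest.approx(100 * 10 / 11)

    def test_boundary_deviation_is_inclusive(self, melody):
        onsets = list(melody.grid_onsets)
        onsets = [t if i < 1 else t + 0.10 * melody.expected_iois[0] for i, t in enumerate(onsets)]
        perf = render(melody, onsets=onsets)
        # first IOI deviates by exactly 10%: still correct
        assert score_trial(perf, melody).rhythm_accuracy == 100.0

    def test_monotone_in_tolerance(self, melody, rng):
        onsets = np.asarray(melody.grid_onsets)
        noisy = np.maximum.accumulate(np.clip(onsets + rng.normal(0, 0.05, size=12), 0, None))
        perf = render(melody, onsets=noisy)
        m = match_pitches(perf.pitches, melody.pitches)
        accs = [rhythm_accuracy(perf, melody, m, tol) for tol in (0.02, 0.05, 0.10, 0.30)]
        assert accs == sorted(accs)

    def test_translation_invariance_with_lenient_first_note(self, melody, rng):
        onsets = np.maximum.accumulate(
            np.clip(np.asarray(melody.grid_onsets) + rng.normal(0, 0.03, size=12), 0, None)
        )
        base = render(melody, onsets=onsets)
        shifted = render(melody, onsets=onsets + 0.7)
        m = match_pitches(base.pitches, melody.pitches)
        for perf_pair in [(base, shifted)]:
            a = rhythm_accuracy(perf_pair[0], melody, m, first_note="lenient")
            b = rhythm_accuracy(perf_pair[1], melody, m, first_note="lenient")
            assert a == pytest.approx(b)

    def test_grid_rule_scores_first_matched_note_when_target_start_missed(self, melody):
        # first target note omitted: the first matched note is referenced to
        # its expected onset on the tempo grid
        onsets = melody.grid_onsets[1:]
        pitches = melody.pitches[1:]
        on_grid = render(melody, onsets=onsets, pitches=pitches)
        assert score_trial(on_grid, melody).rhythm_accuracy == pytest.approx(100 * 11 / 11)
        late = render(melody, onsets=[o + 0.3 for o in onsets], pitches=pitches)
        m = match_pitches(late.pitches, melody.pitches)
        assert rhythm_accuracy(late, melody, m) == pytest.approx(100 * 10 / 11)
        assert rhythm_accuracy(late, melody, m, first_note="lenient") == pytest.approx(100.0)

    def test_empty_and_single_event_score_zero(self, melody):
        assert score_trial(Performance(events=()), melody).rhythm_accuracy == 0.0
        assert score_trial(Performance(events=(NoteEvent(72, 0.0),)), melody).rhythm_accuracy == 0.0

    @pytest.mark.parametrize("tempo", [60, 66, 68, 70, 75, 80, 83, 86, 95])
    def test_uniform_tempo_within_range_iff_100(self, melody, tempo):
        scale = 75.0 / tempo
        perf = render(melody, onsets=[scale * t for t in melody.grid_onsets])
        acc = score_trial(perf, melody).rhythm_accuracy
        in_band = abs(scale - 1.0) <= 0.10  # pre-rounding tolerance band
        assert (acc == 100.0) == in_band
        if not in_band:
            assert acc == 0.0

    def test_inconsistent_alignment_rejected(self, melody, perfect_performance):
        bad = MatchResult(pairs=((0, 1),))
        with pytest.raises(ValueError):
            rhythm_accuracy(perfect_performance, melody, bad)


class TestAcceptableTempoRange:
    @pytest.mark.parametrize(
        "tempo,tol,expected",
        [(75, 0.10, (68, 83)), (75, 0.30, (58, 107)), (75, 0.0, (75, 75)), (120, 0.10, (109, 133))],
    )
    def test_ranges(self, tempo, tol, expected):
        assert acceptable_tempo_range(tempo, tol) == expected

    def test_bounds_bracket_the_tempo(self):
        for tol in (0.05, 0.1, 0.2, 0.3):
            low, high = acceptable_tempo_range(75, tol)
            assert low <= 75 <= high

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            acceptable_tempo_range(75, 1.0)
        with pytest.raises(ValueError):
            acceptable_tempo_range(0, 0.1)


class TestScoreTrial:
    def test_perfect(self, melody, perfect_performance):
        s = score_trial(perfect_performance, melody)
        assert (s.pitch_accuracy, s.rhythm_accuracy) == (100.0, 100.0)
        assert s.n_correct_notes == s.n_performed == s.n_target == 12

    def test_empty(self, melody):
        s = score_trial(Performance(events=()), melody)
        assert (s.pitch_accuracy, s.rhythm_accuracy) == (0.0, 0.0)

    def test_eight_note_toy_with_one_substitution(self):
        from melodylearn.performance_model import melody_from_spec

        mel = melody_from_spec([69, 71, 72, 74, 76, 74, 72, 71], [1.0] * 8, 75)
        pitches = list(mel.pitches)
        pitches[3] = 69  # substitution
        perf = render(mel, pitches=pitches)
        s = score_trial(perf, mel)
        assert s.pitch_accuracy == pytest.approx(100 * 7 / 8)
        # 7 matched notes yield 6 countable intervals (the substituted note
        # forfeits one); all spanned intervals sit exactly on the grid
        assert s.rhythm_accuracy == pytest.approx(100 * 6 / 7)
        assert s.n_correct_iois == 6

    def test_deterministic(self, melody, perfect_performance):
        assert score_trial(perfect_performance, melody) == score_trial(perfect_performance, melody)
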