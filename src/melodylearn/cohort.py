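"""Synthetic learner cohorts with the statistical structure of the study.

The generator emulates the long-format trial data the analysis layer
consumes: 25 participants (13 HIIT / 12 LIIT), an acquisition phase run to a
three-consecutive-correct criterion, retention tests at 1 h / 24 h / 7 days,
and a six-block transfer phase on a second melody.  Each learner follows an
exponential learning curve in per-note correctness probability, with
multiplicative lognormal timing jitter whose coefficient of variation decays
with practice.  Group effects enter as additive shifts on the accuracy
scale: a consolidation offset at the delayed retention tests (both groups),
a HIIT-specific retention offset, and a HIIT-specific per-block gain in
transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence
import math
import warnings

import numpy as np
import pandas as pd

from .performance_model import Melody, NoteEvent, Performance
from .melodies import acquisition_melody, transfer_melody
from .scoring import RhythmTolerance, score_trial

__all__ = [
    "LearnerParams",
    "GroupEffects",
    "CohortConfig",
    "simulate_trial",
    "criterion_check",
    "simulate_acquisition",
    "simulate_study",
    "last10_average",
]

STUDY_PITCHES = (69, 71, 72, 74, 76)


@dataclass(frozen=True)
class LearnerParams:
    """Learning-curve and error-model parameters for one simulated learner.

    Per-note correctness probability at practice trial t is
    ``asymptote - (asymptote - p0) * exp(-rate * t)``.  An incorrect note is
    omitted with probability ``deletion_rate`` (a multiplier on the error
    probability) and otherwise substituted uniformly by one of the other four
    study pitches.  ``insertion_rate`` is the expected number of extra notes
    per trial (Poisson), placed uniformly between adjacent produced notes.
    Timing jitter is multiplicative lognormal on each IOI with coefficient of
    variation ``timing_cv_floor + (timing_cv0 - timing_cv_floor) *
    exp(-timing_rate * t)``.
    """

    p0: float = 0.25
    asymptote: float = 0.70
    rate: float = 0.08
    insertion_rate: float = 0.3
    deletion_rate: float = 0.3
    timing_cv0: float = 0.12
    timing_cv_floor: float = 0.05
    timing_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p0", "asymptote", "deletion_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("rate", "insertion_rate", "timing_cv0", "timing_cv_floor", "timing_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.asymptote < self.p0:
            raise ValueError("asymptote must be at least p0")

    def p_correct(self, trial_number: int) -> float:
        return self.asymptote - (self.asymptote - self.p0) * math.exp(-self.rate * trial_number)

    def timing_cv(self, trial_number: int) -> float:
        return self.timing_cv_floor + (self.timing_cv0 - self.timing_cv_floor) * math.exp(
            -self.timing_rate * trial_number
        )


@dataclass(frozen=True)
class GroupEffects:
    """Additive accuracy-scale effects, in percentage points.

    ``consolidation_offset`` applies to both groups at the delayed retention
    tests (R24, R7), emulating off-line consolidation; ``retention_offset``
    applies to the HIIT group only at R24/R7; ``transfer_slope_boost`` adds
    ``boost x (block - 1)`` to HIIT transfer trials.
    """

    retention_offset: float = 0.0
    transfer_slope_boost: float = 0.0
    consolidation_offset: float = 0.0


# trial counts per phase: (listen, train, test) per block
SESSION_PLAN = {
    "blocks_1_3": (5, 5, 5),
    "blocks_4_6": (5, 0, 5),
    "retention": (2, 0, 10),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-level configuration for one simulated cohort."""

    n_hiit: int = 13
    n_liit: int = 12
    group_effects: GroupEffects = GroupEffects()
    learner: LearnerParams = LearnerParams()
    between_subject_sd: dict = field(
        default_factory=lambda: {"p0": 0.08, "asymptote": 0.07, "rate": 0.03}
    )
    melody: Melody | None = None
    transfer_melody: Melody | None = None
    tolerance: RhythmTolerance = RhythmTolerance()
    seed: int = 0
    mtrain_median: float = 10.0
    mtrain_sigma: float = 1.2
    mtrain_max: float = 60.0

    def __post_init__(self) -> None:
        if self.n_hiit < 2 or self.n_liit < 2:
            raise ValueError("need at least two participants per group")


def simulate_trial(
    params: LearnerParams,
    trial_number: int,
    melody: Melody,
    rng: np.random.Generator,
) -> Performance:
    """Simulate one test-trial performance of ``melody``.

    Deterministic for a fixed generator state.  Returns a bare
    :class:`Performance` (metadata is attached by the cohort driver).
    """
    p = params.p_correct(trial_number)
    cv = params.timing_cv(trial_number)

    n = len(melody)
    grid = melody.grid_onsets
    slots: list[tuple[float, int]] = []  # (nominal grid time, pitch)
    u = rng.random(n)
    for i in range(n):
        if u[i] < p:
            slots.append((grid[i], melody.pitches[i]))
        elif rng.random() < params.deletion_rate:
            continue  # omitted note
        else:
            others = [q for q in STUDY_PITCHES if q != melody.pitches[i]]
            slots.append((grid[i], others[rng.integers(len(others))]))

    n_ins = rng.poisson(params.insertion_rate)
    for _ in range(n_ins):
        pitch = STUDY_PITCHES[rng.integers(len(STUDY_PITCHES))]
        if slots:
            k = int(rng.integers(len(slots) + 1))
            if k == 0:
                t_new = max(0.0, slots[0][0] - 0.5 * melody.beat_seconds)
            elif k == len(slots):
                t_new = slots[-1][0] + 0.5 * melody.beat_seconds
            else:
                t_new = 0.5 * (slots[k - 1][0] + slots[k][0])
            slots.insert(k, (t_new, pitch))
        else:
            slots.append((0.0, pitch))

    # multiplicative lognormal jitter on nominal IOIs, mean 1, CV = cv
    if cv > 0:
        sigma2 = math.log(1.0 + cv * cv)
        mu = -0.5 * sigma2
        factors = np.exp(rng.normal(mu, math.sqrt(sigma2), size=len(slots)))
    else:
        factors = np.ones(len(slots))

    events = []
    t_acc = 0.0
    prev_nominal = 0.0
    for k, (nominal, pitch) in enumerate(slots):
        ioi = nominal - prev_nominal
        t_acc += ioi * factors[k]
        t_acc = max(t_acc, 0.0)
        events.append(NoteEvent(pitch=pitch, onset=t_acc))
        prev_nominal = nominal
    return Performance(events=tuple(events))


def criterion_check(recent_flags: Sequence[bool]) -> bool:
    """Stop rule: the last three test trials were exact pitch-sequence matches
    (rhythm is not considered)."""
    return len(recent_flags) >= 3 and all(recent_flags[-3:])


def _pitch_perfect(score) -> bool:
    return score.pitch_accuracy == 100.0 and score.n_performed == score.n_target


def simulate_acquisition(
    params: LearnerParams,
    melody: Melody,
    rng: np.random.Generator,
    tolerance: RhythmTolerance = RhythmTolerance(),
    stop_at_criterion: bool = True,
    start_trial_number: int = 0,
):
    """Run one learner through the six acquisition blocks.

    Blocks 1-3 each hold 5 listen + 5 train + 5 test trials, blocks 4-6 hold
    5 listen + 5 test.  The practice clock advances with train and test
    trials.  The stop criterion — three consecutive pitch-perfect test
    trials — can be reached within blocks 1-3 but takes effect only once the
    mandatory block 3 completes; from block 4 on it is checked after every
    test trial.  Returns ``(rows, final_trial_number)`` where each row is
    ``(block, trial_index_in_block, AccuracyScore)``.
    """
    rows = []
    flags: list[bool] = []
    t = start_trial_number
    reached = False
    for block in range(1, 7):
        _, n_train, n_test = SESSION_PLAN["blocks_1_3" if block <= 3 else "blocks_4_6"]
        t += n_train  # training trials advance the practice clock, unscored
        for trial_idx in range(1, n_test + 1):
            perf = simulate_trial(params, t, melody, rng)
            t += 1
            score = score_trial(perf, melody, tolerance)
            rows.append((block, trial_idx, score))
            flags.append(_pitch_perfect(score))
            if criterion_check(flags):
                reached = True
            if stop_at_criterion and reached and block > 3:
                return rows, t
        if stop_at_criterion and reached and block >= 3:
            return rows, t
    return rows, t


def _draw_learner(base: LearnerParams, sds: dict, rng: np.random.Generator) -> LearnerParams:
    # asymptote draws are capped below ceiling so additive group effects on
    # the percent scale stay identifiable (see docs/methods.md)
    p0 = float(np.clip(rng.normal(base.p0, sds.get("p0", 0.0)), 0.01, 0.85))
    asym = float(np.clip(rng.normal(base.asymptote, sds.get("asymptote", 0.0)), p0, 0.88))
    rate = float(max(rng.normal(base.rate, sds.get("rate", 0.0)), 0.005))
    return replace(base, p0=p0, asymptote=asym, rate=rate)


def _shift(acc: float, delta: float) -> float:
    return float(np.clip(acc + delta, 0.0, 100.0))


def simulate_study(config: CohortConfig) -> pd.DataFrame:
    """Simulate the full study and return the long-format trial-score table.

    Columns: participant, group, phase, session (Acq/R1/R24/R7/Tran), block,
    trial, pitch_accuracy, rhythm_accuracy, musical_training.  Byte-identical
    across runs for a fixed config (including seed).
    """
    mel_acq = config.melody or acquisition_melody()
    mel_tran = config.transfer_melody or transfer_melody()
    eff = config.group_effects
    root = np.random.SeedSequence(config.seed)
    records = []

    groups = ["HIIT"] * config.n_hiit + ["LIIT"] * config.n_liit
    streams = root.spawn(len(groups))
    for idx, (group, stream) in enumerate(zip(groups, streams), start=1):
        rng = np.random.default_rng(stream)
        pid = f"P{idx:02d}"
        learner = _draw_learner(config.learner, config.between_subject_sd, rng)
        mtrain = min(
            float(rng.lognormal(math.log(config.mtrain_median), config.mtrain_sigma)),
            config.mtrain_max,
        )

        def add(phase, session, block, trial, score, delta=0.0):
            records.append(
                {
                    "participant": pid,
                    "group": group,
                    "phase": phase,
                    "session": session,
                    "block": block,
                    "trial": trial,
                    "pitch_accuracy": _shift(score.pitch_accuracy, delta),
                    "rhythm_accuracy": _shift(score.rhythm_accuracy, delta),
                    "musical_training": mtrain,
                }
            )

        acq_rows, t_end = simulate_acquisition(
            learner, mel_acq, rng, config.tolerance, stop_at_criterion=True
        )
        for block, trial, score in acq_rows:
            add("acquisition", "Acq", block, trial, score)

        # retention: measurement at the frozen end-of-acquisition clock
        for session in ("R1", "R24", "R7"):
            delta = 0.0
            if session in ("R24", "R7"):
                delta += eff.consolidation_offset
                if group == "HIIT":
                    delta += eff.retention_offset
            for trial in range(1, SESSION_PLAN["retention"][2] + 1):
                perf = simulate_trial(learner, t_end, mel_acq, rng)
                add("retention", session, None, trial, score_trial(perf, mel_acq, config.tolerance), delta)

        # transfer: new melody, fresh practice clock, no early stop
        tran_rows, _ = simulate_acquisition(
            learner, mel_tran, rng, config.tolerance, stop_at_criterion=False
        )
        for block, trial, score in tran_rows:
            delta = eff.transfer_slope_boost * (block - 1) if group == "HIIT" else 0.0
            add("transfer", "Tran", block, trial, score, delta)

    df = pd.DataFrame.from_records(records)
    df["block"] = df["block"].astype("Int64")
    return df


def last10_average(scores: Sequence[float]) -> float:
    """End-of-acquisition summary: mean of the final 10 test-trial scores
    (participants stopping at criterion have varying trial counts).  With
    fewer than 10 trials all are averaged, with a warning."""
    if len(scores) == 0:
        raise ValueError("no acquisition scores")
    if len(scores) < 10:
        warnings.warn(
            f"only {len(scores)} acquisition trials; averaging all", stacklevel=2
        )
    return float(np.mean(np.asarray(scores, dtype=float)[-10:]))
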