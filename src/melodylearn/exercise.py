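"""Graded exercise test (GXT) bookkeeping and interval-exercise prescription.

The GXT is an incremental cycling test: men start at 100 W, women at 50 W,
and the power rises by 30 W every 2 min until volitional exhaustion.  W_max
is the power of the final fully completed stage and anchors the personalized
19-min interval protocol: a 2-min warm-up and cool-down at 5% W_max framing
three repetitions of a 2-min low-intensity and a 3-min high-intensity
interval.  The HIIT group cycles at 60%/90% W_max, the active-control LIIT
group at 8%/12% W_max — both a 2:3 low:high ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "GxtStage",
    "GxtResult",
    "IntervalSegment",
    "IntervalProtocol",
    "build_gxt_schedule",
    "wmax_from_stages",
    "vo2peak_attained",
    "build_interval_protocol",
    "hiit_dose_completed",
    "format_dose",
    "parse_dose",
]

STAGE_SECONDS = 120
STAGE_INCREMENT_W = 30
START_W = {"M": 100, "F": 50}

INTERVAL_FRACTIONS = {"HIIT": (0.60, 0.90), "LIIT": (0.08, 0.12)}
WARMUP_FRACTION = 0.05
PROTOCOL_SECONDS = 1140  # 19 min

ATTAINMENT_FLAGS = ("vo2_or_hr_plateau", "rer_gt_1.1", "cadence_failure", "volitional_exhaustion")


@dataclass(frozen=True)
class GxtStage:
    """One 2-min GXT stage with its physiological samples."""

    power: float
    completed: bool
    planned_duration: float = STAGE_SECONDS
    hr_samples: tuple[float, ...] = ()
    vo2_samples: tuple[float, ...] = ()
    rer_samples: tuple[float, ...] = ()
    rpe: float | None = None
    cadence_ok: bool = True

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("stage power must be positive")
        if self.rpe is not None and not 6 <= self.rpe <= 20:
            raise ValueError("RPE must lie on the Borg 6-20 scale")


@dataclass(frozen=True)
class GxtResult:
    stages: tuple[GxtStage, ...]
    wmax: float
    vo2peak: float | None = None
    hrmax: float | None = None
    rermax: float | None = None
    rpemax: float | None = None
    attainment_flags: frozenset[str] = frozenset()
    volitional_exhaustion: bool = False


@dataclass(frozen=True)
class IntervalSegment:
    phase: str  # warmup | low | high | cooldown
    intensity_fraction: float
    power: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")


@dataclass(frozen=True)
class IntervalProtocol:
    group: str
    wmax: float
    segments: tuple[IntervalSegment, ...]

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)


def build_gxt_schedule(sex: str, n_stages: int) -> list[float]:
    """Stage powers: 100 W start for men, 50 W for women, +30 W per stage."""
    if sex not in START_W:
        raise ValueError(f"unknown sex code {sex!r}; expected 'M' or 'F'")
    if n_stages < 1:
        raise ValueError("need at least one stage")
    start = START_W[sex]
    return [float(start + STAGE_INCREMENT_W * k) for k in range(n_stages)]


def wmax_from_stages(stages: Sequence[GxtStage]) -> float:
    """Power of the final fully completed stage."""
    completed = [s for s in stages if s.completed]
    if not completed:
        raise ValueError("no fully completed stage: test is un-scorable")
    return completed[-1].power


def vo2peak_attained(
    result: GxtResult,
    *,
    vo2_plateau_epsilon: float = 1.5,
    hr_plateau_epsilon: float = 4.0,
) -> tuple[bool, frozenset[str]]:
    """Check the VO2peak attainment criteria; true when at least one holds.

    Criteria: a plateau in VO2 (< ``vo2_plateau_epsilon`` ml/kg/min rise) or
    HR (< ``hr_plateau_epsilon`` bpm rise) across the final two stages despite
    the workload increase; RER strictly above 1.1; inability to hold the
    70-90 RPM cadence band; or volitional exhaustion.  Channels without data
    skip their criterion with a warning.
    """
    flags: set[str] = set()

    def _stage_peak(samples_name: str) -> list[float]:
        return [max(getattr(s, samples_name)) for s in result.stages if getattr(s, samples_name)]

    vo2 = _stage_peak("vo2_samples")
    hr = _stage_peak("hr_samples")
    if len(vo2) >= 2 and vo2[-1] - vo2[-2] < vo2_plateau_epsilon:
        flags.add("vo2_or_hr_plateau")
    if len(hr) >= 2 and hr[-1] - hr[-2] < hr_plateau_epsilon:
        flags.add("vo2_or_hr_plateau")
    if not vo2 and not hr:
        warnings.warn("no VO2 or HR samples: plateau criterion skipped", stacklevel=2)

    rers = [max(s.rer_samples) for s in result.stages if s.rer_samples]
    rermax = result.rermax if result.rermax is not None else (max(rers) if rers else None)
    if rermax is None:
        warnings.warn("no RER data: RER criterion skipped", stacklevel=2)
    elif rermax > 1.1:
        flags.add("rer_gt_1.1")

    if any(not s.cadence_ok for s in result.stages):
        flags.add("cadence_failure")
    if result.volitional_exhaustion:
        flags.add("volitional_exhaustion")
    return bool(flags), frozenset(flags)


def build_interval_protocol(wmax: float, group: str) -> IntervalProtocol:
    """The 19-min personalized interval schedule for one participant."""
    if wmax <= 0:
        raise ValueError("W_max must be positive")
    if group not in INTERVAL_FRACTIONS:
        raise ValueError(f"unknown group {group!r}; expected 'HIIT' or 'LIIT'")
    low_f, high_f = INTERVAL_FRACTIONS[group]

    def seg(phase: str, fraction: float, duration: float) -> IntervalSegment:
        return IntervalSegment(phase, fraction, fraction * wmax, duration)

    segments = [seg("warmup", WARMUP_FRACTION, 120)]
    for _ in range(3):
        segments.append(seg("low", low_f, 120))
        segments.append(seg("high", high_f, 180))
    segments.append(seg("cooldown", WARMUP_FRACTION, 120))
    protocol = IntervalProtocol(group=group, wmax=wmax, segments=tuple(segments))
    assert protocol.total_duration == PROTOCOL_SECONDS
    return protocol


def hiit_dose_completed(segment_log: Sequence[tuple[IntervalSegment, float]]) -> float:
    """Completed high-intensity work, in seconds, from a per-segment elapsed log.

    The log is a sequence of (segment, elapsed_seconds) pairs.  Logs may
    contain more high-intensity time than the printed 3 x 3-min schedule
    (repeated or extended intervals); only elapsed > planned for a single
    segment is rejected as inconsistent.
    """
    total = 0.0
    for segment, elapsed in segment_log:
        if elapsed < 0 or elapsed > segment.duration + 1e-9:
            raise ValueError(
                f"elapsed {elapsed} s inconsistent with planned {segment.duration} s"
            )
        if segment.phase == "high":
            total += elapsed
    return total


def format_dose(seconds: float) -> str:
    """Render a dose in the study's m:s notation, e.g. ``'10 m 30 s'`` or ``'4 m'``."""
    minutes = int(seconds // 60)
    rem = round(seconds - 60 * minutes)
    return f"{minutes} m" if rem == 0 else f"{minutes} m {rem} s"


def parse_dose(text: str) -> float:
    """Parse ``'10 m 30 s'`` / ``'4 m'`` into seconds."""
    parts = text.replace("m", " m ").replace("s", " s ").split()
    seconds = 0.0
    for value, unit in zip(parts[::2], parts[1::2]):
        seconds += float(value) * (60 if unit == "m" else 1)
    return seconds
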