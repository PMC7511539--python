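"""Rhythm-tolerance arithmetic and worked scoring examples.

Derives the integer tempo bands a uniform rendition of a 75-bpm melody may
occupy under the study's 10% inter-onset-interval criterion (68-83 bpm) and
the prior literature's 30% criterion (58-107 bpm), then scores a handful of
constructed performances of the packaged melody to illustrate the pitch
(subsequence / max-length) and rhythm (preceding-correct-note) rules.
"""

import json
from pathlib import Path

from melodylearn.melodies import acquisition_melody
from melodylearn.performance_model import NoteEvent, Performance
from melodylearn.scoring import acceptable_tempo_range, score_trial

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

bands = {
    "study_10pct": acceptable_tempo_range(75, 0.10),
    "legacy_30pct": acceptable_tempo_range(75, 0.30),
}
print("Acceptable uniform tempi for a 75-bpm melody:")
for name, (lo, hi) in bands.items():
    print(f"  {name}: {lo}-{hi} bpm")

mel = acquisition_melody()


def rendition(scale=1.0, drop=(), onset_shift=0.0):
    events = [
        NoteEvent(p, scale * t + onset_shift)
        for i, (p, t) in enumerate(zip(mel.pitches, mel.grid_onsets))
        if i not in drop
    ]
    return Performance(events=tuple(events))


examples = {}
for label, perf in {
    "perfect": rendition(),
    "uniform_8pct_slow": rendition(scale=1.08),
    "uniform_15pct_slow": rendition(scale=1.15),
    "two_notes_dropped": rendition(drop=(3, 7)),
}.items():
    s = score_trial(perf, mel)
    examples[label] = {
        "pitch_accuracy": round(s.pitch_accuracy, 1),
        "rhythm_accuracy": round(s.rhythm_accuracy, 1),
        "n_correct_notes": s.n_correct_notes,
    }
    print(f"  {label:>20s}: pitch {examples[label]['pitch_accuracy']:5.1f}%  "
          f"rhythm {examples[label]['rhythm_accuracy']:5.1f}%")

(OUT / "tolerance_ranges.json").write_text(
    json.dumps({"bands_bpm": {k: list(v) for k, v in bands.items()},
                "worked_examples": examples}, indent=2)
)
print(f"\nWrote {OUT / 'tolerance_ranges.json'}")
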