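"""Rank-based longitudinal models on the simulated cohort.

Fits the three designs of the analysis plan to the trial table written by
04_simulate_cohort.py, for both dependent measures: (1) retention — group x
session (Acq, R1, R24, R7) with musical training and a participant random
intercept; (2) transfer — group x block (1-6); (3) acquisition vs transfer —
blocks 1-3 of both phases.  Also reports normality checks (which motivate
the rank transform), the end-of-acquisition Wilcoxon group comparison, and
per-group transfer slopes in percentage points per block.
"""

import json
from pathlib import Path

import pandas as pd

from melodylearn.pipeline import analyze_trials, summarize_retention
from melodylearn.statistics import ks_normality, wilcoxon_rank_sum

OUT = Path(__file__).resolve().parents[1] / "results"
trials = pd.read_csv(OUT / "trials.csv")

results = {}
ret = summarize_retention(trials)
for resp in ("pitch_accuracy", "rhythm_accuracy"):
    ks = ks_normality(ret[resp])
    hi = ret[(ret.session == "Acq") & (ret.group == "HIIT")][resp]
    lo = ret[(ret.session == "Acq") & (ret.group == "LIIT")][resp]
    w = wilcoxon_rank_sum(hi, lo)
    results[resp] = {
        "normality": {"D": round(ks.statistic, 3), "p": round(ks.p_value, 4)},
        "end_of_acquisition": {"W": w.statistic, "p": round(w.p_value, 3)},
    }
    print(f"{resp}: Lilliefors D = {ks.statistic:.3f} (p = {ks.p_value:.3f}); "
          f"end-of-acquisition W = {w.statistic:.0f} (p = {w.p_value:.3f})")

for design in ("retention", "transfer", "acq-vs-transfer"):
    for resp in ("pitch_accuracy", "rhythm_accuracy"):
        model = analyze_trials(trials, design, resp)
        results[f"{design}:{resp}"] = model
        print(f"\n== {design} / {resp} ==")
        if model["interaction"]:
            it = model["interaction"]
            kept = "removed (ns)" if model["interaction_removed"] else "retained"
            print(f"  interaction F({it['df_num']},{it['df_den']}) = {it['F']:.2f}, "
                  f"p = {it['p_value']:.3f} -> {kept}")
        for e in model["effects"]:
            print(f"  {e['name']}: F({e['df_num']},{e['df_den']}) = {e['F']:.2f}, "
                  f"p = {e['p_value']:.3f}")
        if "slopes" in model and design == "transfer":
            s = model["slopes"]
            print(f"  slopes: HIIT {s['HIIT']:.1f} vs LIIT {s['LIIT']:.1f} %/block "
                  f"(difference {s['difference']:.1f})")

(OUT / "models.json").write_text(json.dumps(results, indent=2))
print(f"\nWrote {OUT / 'models.json'}")
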