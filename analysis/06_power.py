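"""Two-group power and sample-size calculations.

Uses the noncentral-t machinery to tabulate the per-group n a two-sided
pooled t-test needs at 80% power across standardized effect sizes, and
inverts the published whole-study requirements (396/group for pitch,
156/group for rhythm) into the standardized differences they imply — a
direct way to see how small the between-group retention effects were.
"""

import json
from pathlib import Path

from melodylearn.statistics import sample_size_two_groups

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

table = {d: sample_size_two_groups(d, 1.0, power=0.80, alpha=0.05)
         for d in (1.0, 0.8, 0.5, 0.35, 0.3, 0.2845, 0.2, 0.1)}
print("n per group for 80% power (two-sided alpha 0.05):")
for d, n in table.items():
    print(f"  d = {d:5.3f} -> n = {n}")


def implied_d(n_target, lo=0.01, hi=2.0):
    # n per group is decreasing in d: find the smallest d whose n fits
    while hi - lo > 1e-6:
        mid = (lo + hi) / 2
        if sample_size_two_groups(mid, 1.0) <= n_target:
            hi = mid
        else:
            lo = mid
    return round(hi, 4)


implied = {"pitch_396_per_group": implied_d(396), "rhythm_156_per_group": implied_d(156)}
print("\nStandardized differences implied by the published requirements:")
for k, v in implied.items():
    print(f"  {k}: d ~= {v}")

(OUT / "power.json").write_text(json.dumps(
    {"n_per_group_at_80pct_power": {str(k): v for k, v in table.items()},
     "implied_standardized_differences": implied}, indent=2))
print(f"\nWrote {OUT / 'power.json'}")
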