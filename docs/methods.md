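# Methods

`melodylearn` implements the complete analytic pipeline of a two-group
(HIIT vs LIIT) piano-melody learning design: performance scoring, exercise
prescription bookkeeping, a synthetic learner simulator, and the rank-based
longitudinal statistics. This note documents the models, the parameters
that matter, the numerical choices, and the limits of what the synthetic
data can show.

## Performance scoring

A test trial is an ordered list of timed keypresses (MIDI pitch + onset in
seconds from trial start, trial start being the end of the four-beat
count-in). The target is a 12-note melody over the five pitches A4–E5 with
quarter/eighth values at 75 bpm, so the expected inter-onset interval (IOI)
of note *i* is `note_value[i] × 60 / tempo` (0.8 s or 0.4 s).

**Pitch accuracy.** Correctly performed notes are identified as an
order-preserving match of maximum cardinality between the performed and
target pitch sequences — a longest common subsequence (LCS). Among
equal-cardinality matchings the leftmost one is taken: each pair greedily
uses the earliest feasible performance index, then the earliest feasible
target index. Determinism here matters because rhythm scoring depends on
*which* occurrences were matched. Pitch accuracy is
`100 × |match| / max(n_target, n_performed)`: extra keypresses inflate the
denominator and are thereby penalized. Pitch equality is exact MIDI-number
equality; with five labelled keys, octave confusions cannot occur.

Note a consequence of subsequence matching worth knowing when interpreting
scores: two *random* length-12 sequences over a 5-symbol alphabet share a
common subsequence of about 6 notes, so chance-level performance scores
near 50%, not 0%.

**Rhythm accuracy.** The percentage of IOIs within a relative tolerance
(default 10%, boundary inclusive; the prior literature's 30% criterion is
available) of the expected IOI. Each matched note with a preceding matched
note is referenced to that note: the observed interval is the onset
difference of the two keypresses, the expected interval the sum of melody
IOIs spanning the two matched target positions. Referencing the *preceding
correct note* (rather than the absolute grid) absorbs timing drift
accumulated earlier in the trial; a pitch error costs at most the one
interval it interrupts. The denominator is
`max(n_target − 1, n_performed − 1)`.

The first matched note has no preceding correct note and is referenced to
the tempo grid: its onset is compared with its expected grid onset. When
the first matched note is aligned to the very first target note, its
grid-expected onset is zero and no relative deviation exists; it then
contributes no countable interval (this is the only reading under which a
metronomically perfect rendition scores exactly 100 with 11 countable
intervals, and a single stretched IOI scores 10/11). A `first_note="lenient"`
option counts the grid-referenced first note as correct unconditionally,
which makes both accuracies invariant to a uniform time translation of the
whole performance.

Numerical choices: the tolerance comparison uses
`deviation ≤ tol × (1 + 1e-9) + 1e-12` so an exactly-boundary deviation is
not rejected by floating-point rounding; simultaneous keypresses are
serialized by ascending pitch; empty or single-event performances score 0
against a multi-note target.

**Tempo bands.** A uniform rendition at tempo T scales every IOI by
`75 / T`, so the acceptable band is `[75/(1+tol), 75/(1−tol)]`, rounded
half-away-from-zero to integers: 68–83 bpm at 10%, 58–107 bpm at 30%. This
rounding is the only scheme consistent with both published bands.

## Exercise protocol

The graded exercise test (GXT) is an arithmetic grid: 100 W start for men,
50 W for women, +30 W per 2-min stage; W_max is the power of the last fully
completed stage. Every W_max in the packaged participant table lies on the
corresponding sex grid. VO2peak attainment requires at least one of: a
plateau in VO2 or HR across the final two stages (defaults: rise < 1.5
ml/kg/min or < 4 bpm — the criterion names no threshold, so these are
package choices, configurable), respiratory exchange ratio strictly above
1.1, cadence failure (70–90 RPM band), or volitional exhaustion. Channels
without data skip their criterion with a warning.

The 19-min interval protocol is fixed in shape — 2-min warm-up at 5%
W_max, three repetitions of (2-min low + 3-min high), 2-min cool-down at
5% — with group-specific fractions: 60%/90% W_max for HIIT, 8%/12% for
LIIT (the same 2:3 low:high ratio). Total duration is always 1140 s
regardless of W_max. The completed high-intensity dose is summed from a
per-segment elapsed-time log; logs may contain more high-intensity time
than the printed 3 × 3-min schedule (the packaged dose table itself lists
up to 15 m 45 s), so the dose operation does not cap at 9 min.

## Synthetic learner cohorts

The generator emulates the long-format data the statistics consume; it is
first-class, tested code, not a fixture. Each learner has an exponential
learning curve in per-note correctness probability
`p(t) = a − (a − p0)·exp(−r·t)` where *t* counts motor-practice trials
(train + test; listen trials do not advance the clock). An incorrect note
is omitted with probability `deletion_rate` and otherwise substituted
uniformly among the other four pitches; extra notes arrive as a Poisson
count (`insertion_rate` per trial) placed uniformly between produced notes.
Onsets follow the target grid with multiplicative lognormal IOI jitter of
mean 1 and a coefficient of variation that decays with practice from
`timing_cv0` to `timing_cv_floor`. With CV = 0.05 and the 10% tolerance,
per-interval correctness has the closed form
`Φ((ln 1.1 − μ)/σ) − Φ((ln 0.9 − μ)/σ) ≈ 0.954`, which the tests use as an
independent oracle for the jitter model.

The acquisition session plan is 3 blocks of 5 listen + 5 train + 5 test,
then 3 blocks of 5 listen + 5 test. The stop criterion — three consecutive
pitch-perfect test trials (rhythm ignored) — can be *reached* anywhere but
takes effect only once the mandatory blocks 1–3 are complete; from block 4
it is checked after every test trial. Retention sessions (R1, R24, R7) are
10 test trials each at the frozen end-of-acquisition practice clock:
retention is treated as measurement, not practice, which keeps configured
retention effects cleanly recoverable. Transfer restarts the clock on a
second melody and runs all six blocks with no early stop.

Group effects are additive shifts on the percent scale, truncated to
[0, 100]: a consolidation offset at R24/R7 for both groups, a
HIIT-specific retention offset at R24/R7, and a HIIT-specific
`boost × (block − 1)` gain in transfer. Defaults (per-group n = 13/12,
p0 = 0.25, asymptote = 0.70 with between-subject SDs 0.08/0.07/0.03 on
p0/asymptote/rate, asymptote draws capped at 0.88, timing CV 0.12 → 0.05,
musical training lognormal with median 10 months capped at 60) place
trajectories in the mid-range of the accuracy scale. That is a deliberate
design constraint: additive effects are only identifiable away from the
100% ceiling, and the generator's contract includes unbiased recovery
(|bias| < 10% of the configured effect). The cost is a known divergence
from real cohorts of this kind, which show strong ceiling effects and
frequent criterion stops; under the defaults criterion stops are rare.
Ceiling-regime behaviour remains reachable by configuration (raise the
asymptote), and the criterion logic is tested with deterministic perfect
and late-blooming learners. Passing recovery tests therefore demonstrate
the estimation machinery, not robustness to ceiling truncation.

Determinism: every participant draws from a `SeedSequence(seed).spawn`
substream, so a fixed `CohortConfig` reproduces the trial table exactly.

## Statistics

**Two-group tests.** Pooled-variance Student t (df = n1 + n2 − 2, matching
the published df = 23 for 13 vs 12) with a Welch option; Wilcoxon rank sum
reporting the mid-rank sum W, exact p for combined n ≤ 20 without ties and
a continuity-corrected normal approximation otherwise; Lilliefors-corrected
Kolmogorov–Smirnov normality check that flags when rank-based modelling is
advisable.

**Rank-based longitudinal model.** The response is replaced by mid-ranks
over all observations, then a mixed model with fixed effects of group,
session-or-block, optionally their interaction and a between-subject
covariate (musical training), and a participant random intercept is
evaluated. Type III F tests use containment-style denominator degrees of
freedom, computed by stratified least squares: between-subject effects are
tested on subject means (denominator df = n_subjects − 1 − #between
parameters), within-subject effects against the residual with subject
intercepts absorbed (df = n_obs − n_subjects − #within parameters). For a
random-intercept design this reproduces the classical mixed-model ANOVA
exactly, is deterministic and fast, and yields the df shapes the design
implies — F(1,22) for group, F(3,69) for the session interaction model,
F(3,72) after reduction, F(5,115) for transfer blocks with 25 subjects. An
iterative REML route (statsmodels `MixedLM`) is exposed as `engine="reml"`
for sensitivity analysis and agrees with the stratified route on balanced
data; one test cross-checks the two. Sum-to-zero coding makes the
drop-term sums of squares Type III.

If the interaction p exceeds 0.05 the model is refitted with main effects
only (the analysis plan's reduction rule). Pairwise LS-mean contrasts of
the within factor are reported on the rank scale with the within-stratum
residual variance; because the original least-squares contrasts could have
been computed on either scale, a back-transformed estimate (rank → response
by interpolating the empirical rank–value relation) is reported alongside.
No multiplicity corrections are applied, and all tests are two-sided at
0.05. Empty design cells are reported by name rather than silently
dropped. Degenerate inputs (constant samples, zero pooled variance with
unequal means, zero effect size in the power solver) raise explicit
signals.

The acquisition-vs-transfer design (blocks 1–3 of both phases) is fitted
with a combined 6-level phase:block cell factor as the within effect, plus
per-phase per-group block slopes; this differs from a full three-way
factorization but tests the same questions with interpretable cells.

**Slopes and power.** Per-group block trends are least-squares slopes of
the *raw* accuracy over numeric block with subject intercepts absorbed,
in percentage points per block. The two-group sample-size solver finds the
smallest per-group n whose two-sided pooled t-test attains the requested
power via the noncentral t distribution (d = 1 → n = 17; d = 0.2 → n =
394), validated against Monte-Carlo power in the tests.

## Packaged fixtures and placeholder stimuli

The 25-row participant table and the 5-row incomplete-HIIT dose table are
transcribed into CSV fixtures, SHA-256-verified on load. One documented
oddity is retained as printed: the physical-activity t-test was published
with df = 21 while all other tests use df = 23; the fixture keeps all 25
rows and this package's recomputation gives df = 23 for that column.

The exact note sequences of the two target melodies and three
familiarization melodies are published only as notation images, so the
package ships *synthetic placeholder* melodies satisfying every stated
structural constraint (12 notes over A4–E5, quarters and eighths, 75 bpm;
short all-quarter familiarization tunes). All arithmetic that depends only
on this structure is unaffected; analyses of the original melodies'
specific contours are out of scope.

## Problem sizes used in checks

The Monte-Carlo operating-characteristic checks use 500 replicate cohorts
(25 participants each) for the interaction Type-I error, 200 replicates
for effect recovery, and 10,000 replicates for power validation — sizes at
which binomial noise is well below the tested margins while the whole
suite completes in a few minutes on one CPU.

## Known limitations

- The synthetic generator does not emulate ceiling truncation, fatigue,
  serial correlation of errors within a trial beyond timing drift, or any
  coupling between familiarization count and later learning; passing tests
  say nothing about those features of real data.
- The SMF codec covers PPQ-based format 0/1 files with note events, meta
  and sysex; SMPTE divisions and multi-channel semantics are not handled.
- The containment-df scheme is exact for random-intercept designs but is
  not a general substitute for Satterthwaite/Kenward–Roger approximations
  in more complex covariance structures.
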