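# Methods

## Coordinate and arena conventions

The arena floor is a 35 × 82.5 cm rectangle. The package's origin sits at
the shelter-side corner: x runs along the long axis away from the shelter
wall (0 → 82.5 cm; a virtual cricket travels this axis 0 → 83 cm), y along
the short axis (0 → 35 cm). The shelter is a triangle tucked into the
origin corner, represented by its corner points (default legs of 12 cm).

Derived zones (all half-open, `[lo, hi)` on each axis, so membership is
exhaustive and unambiguous on boundaries):

| zone | definition |
| --- | --- |
| threat zone | farthest third, x ≥ 2L/3 (stimulus trigger region) |
| danger zone | half opposite the shelter, x ≥ L/2 |
| center | central half on each axis, [L/4, 3L/4) × [W/4, 3W/4) |
| shelter zone | 23 cm square at the shelter corner |
| safe zone (near) | 20 cm band along the shelter-side short wall |
| safe zone (far) | 10 cm band along the far short wall |

Shelter *occupancy* uses the 23 cm shelter zone; shelter *entries* use the
distance rule (< 5 cm to the nearest shelter corner), which is robust to
small shelter movements. Both are reported.

## Kinematics

Positions (possibly with missing frames) become a scalar speed trace by:
per-frame-pair speed, linear interpolation onto a uniform 30 Hz grid, and
a 5-point centered moving average whose window shrinks at the edges.
Per-step speeds are assigned to frame-pair midpoints before interpolation.

Two speed definitions are exposed. The default, `euclidean`, is the true
path speed ‖Δ(x, y)‖/Δt, invariant under translation of the coordinate
frame. The alternative `paper_literal` differences the radial distance
√(x² + y²) from the arena origin; it is origin-dependent and vanishes on
circular paths around the origin, and exists only for replication of
analyses that used that formula. All thresholds in this package presuppose
a true speed, hence the default.

Baseline referencing: z-scores use the mean/SD of a pre-onset window —
10 s for heatmap-style normalisation, 5 s for per-trial speed-change
analysis; both are explicit parameters because both conventions are in
circulation. A frozen baseline (SD = 0) raises an error rather than
silently producing zeros. Pre-stimulus speed is the median over the 5 s
before onset; foraging speed the median over the preceding 2.5 min. All
windows are half-open `[onset − w, onset)`.

## Event extraction

All thresholds use strict inequalities:

- running bout: speed > 30 cm/s for ≥ 3 consecutive frames on the 30 Hz
  grid (the threshold corresponds to the 97.5th percentile of *Mus*
  baseline speeds; `baseline_threshold` recomputes such percentiles with
  the linear-interpolation definition);
- stopping time: longest run of frames < 5 cm/s in the stimulus window;
- shelter entry: distance < 5 cm to the nearest shelter corner; an animal
  already inside at the window start counts as one entry at zero latency;
- approach: animal–target distance < 10 cm for ≥ 10 frames (0.33 s at
  30 Hz — the frame count, not a rounded duration, is the criterion);
- ends-in-safety: any frame inside either safe band during the final 1 s
  of the stimulus train.

Latency fields are `None`, never 0, when the event does not occur.

One deliberate tolerance: the centered 5-point smoothing can advance a
measured bout onset by up to two frames, so trial-level extraction accepts
bouts starting up to 0.1 s *before* stimulus onset as stimulus-evoked
(`onset_tol_s`, configurable; latencies may then be marginally negative).
Without it, a response beginning exactly at onset would be attributed to
the pre-stimulus period.

## Rhythm analysis

Stimulus-window speed traces are first detrended (least-squares line
subtracted). The power spectrum then follows a fixed four-step single-
sided construction: `P2 = |fft(x)|/L`; keep bins `0..floor(L/2)`; double
the interior bins (for odd L there is no Nyquist bin, so all bins except
DC are doubled — the construction as usually quoted assumes even L);
square. For a pure sinusoid of amplitude A on an exact bin the interior
value is A², which the tests verify in closed form, and the whole
construction is checked against a brute-force O(L²) DFT oracle.

Cross-correlations are coefficient-normalised (`r[k] = Σ x[n+k]y[n] /
√(Σx²Σy²)`), so a signal's autocorrelation at lag 0 is exactly 1 and
reported values live in [−1, 1]. The stimulus is represented either as a
sinusoid at the cycle rate, `sin(2π f (t − train onset))` (phase fixed at
zero at train onset; the convention is arbitrary but documented), or as a
binary onset vector. Bout-train correlograms are computed per trial row
and averaged; a row with no bouts contributes a zero correlogram. Because
the convention for summarising a correlogram into a single r is not fixed,
the full correlogram is exported along with the peak within ±10 s.
`peak_frequency` breaks ties toward the lower frequency.

## Behavior classification

A deterministic rule cascade scores each trial from its stimulus-window
kinematics, with precedence dart > escape > stop > weak > none:

1. **dart / dart_safety** — ≥ 2 running bouts whose consecutive net-
   displacement headings differ by > 60°; `dart_safety` iff the trial ends
   in a safe band.
2. **escape** — bouts all within a single ≤ 1.5 s burst span, followed by
   stillness (post-bout median speed < 5 cm/s) or a shelter entry.
3. **stop** — no bout and ≥ 1 s of continuous stillness.
4. **weak** — a speed transient crossing 15 cm/s for < 3 frames.
5. **none** — nothing above fired.

Sprinting trials that fit neither the dart rule nor the strict escape rule
(e.g. repeated same-direction runs, or a sprint without subsequent
stillness) fall back to `escape` at confidence 0.5 — the cascade as
specified leaves those cases open, and a sprinting trial must not fall
through to `weak`/`none`. Every label carries the list of fired rules for
audit. The thresholds (1 s stillness, 1.5 s burst span, 60° heading
change, 15 cm/s transient) are package defaults chosen to reproduce the
separation of behavior types in the (maximal speed, stopping time) plane;
all are configurable.

The `weak` class captures only sub-threshold *speed* transients. Startles
expressed as rearing toward the stimulus are invisible to center-of-mass
kinematics; no recovery guarantee is made for `weak`.

## Statistics

- Permutation test: two-sided difference of means; labels shuffled without
  replacement; p = (1 + #{|Δperm| ≥ |Δobs|})/(n_perm + 1) (add-one, so
  p ≥ 1/(n_perm+1)); default 5000 permutations, seeded. The permutation
  null is drawn from the sorted pooled sample, making the seeded result
  invariant to input order and exactly symmetric under group swap at equal
  sizes. A bootstrap percentile 95% CI of the effect is attached.
- Rank-sum: Mann–Whitney U, exact null when both groups have n ≤ 10 and no
  ties, otherwise normal approximation with tie correction; Bonferroni
  adjustment p̃ = min(1, m·p).
- Correlation: Pearson r with the t-distribution p-value (n − 2 df);
  constant inputs are an error.
- Linear models: the "generalized linear model" of the assay's analyses is
  treated as Gaussian-identity, i.e. OLS, since the responses are
  continuous speeds and latencies; categorical terms are treatment-coded
  and per-term p-values come from type-II partial F-tests. Behavior type
  enters as a nominal factor. Rank-deficient designs raise an error naming
  the aliased columns (located by pivoted QR).

## The synthetic generator

The generator's defaults define the study conditions under which the
package is validated; they are fixed once, not fitted.

Stimulus schedules follow the assay exactly: black loom = 10 repetitions
of a 1 s cycle (0.5 s expansion + 0.5 s grey), white loom and dimming =
5 repetitions, sweep = one 21°/s pass (track in degrees; no screen
geometry is assumed, so no cm conversion is invented), cricket = one 3 cm/s
pass over 0 → 83 cm along the long wall.

Trajectories: the pre-stimulus phase is a bounded correlated random walk
(heading persistence ρ = 0.8, turning noise (1−ρ)·π·N(0,1), per-frame
lognormal speeds, reflecting walls). The speed regime switches from
foraging (lognormal median 5.0 cm/s bright / 3.5 dim) to threat-zone
approach (6.0 bright / 9.0 dim) in the last 8 s before onset — foraging
slows under dim light while pre-stimulus exploration speeds up, matching
the assay's observed directions; magnitudes are configuration, since the
original recordings are not available to fit them.

Behavior programs start at a lognormal latency after onset (median 0.6 s
dim / 1.2 s bright for escapes; darts lock to the first loom onset at or
after the drawn latency):

- *freeze*: near-complete immobility (≈0.3 cm/s positional jitter);
- *escape_shelter*: one sprint (lognormal peak, median 75 cm/s dim / 60
  bright) straight to a point < 5 cm from the shelter's wall corner, then
  sheltering;
- *dart / dart_safety*: 0.4 s sprints at full peak speed launched at every
  loom onset (± configurable Gaussian jitter; default 0), with fresh
  targets far enough (> 22 cm) that sprints run their full length, plus
  brief (0.2 s) intermediate sprints with probability 0.45 dim / 0.25
  bright at a uniformly random phase *between* looms — intermediate
  sprints are not phase-locked, which is what distinguishes them from the
  loom-locked ones. The final sprint steers into the nearer safe band
  (`dart_safety`) or mid-arena (`dart`) and runs until arrival.

Habituation cohorts emit one short trial per (animal, repetition) with
response probability p₀·decay^rep (decay attenuated under dim light) and
a small per-repetition probability of exclusion by the >10-min shelter
rule, carried as `tested` metadata.

What the generator does **not** emulate: posture (rearing, freezing
micro-movements), bodypart-level detail, tracking noise and identity
swaps, photometric properties of the stimuli, wall-following and
thigmotaxis, and any biomechanics (sprints are kinematic primitives).
Passing recovery tests therefore demonstrates that the pipeline's
thresholds, spectra and rules are internally consistent and correctly
implemented — not that they would achieve the same accuracy on real
videos.

## Numerical choices

- Half-open windows everywhere (`[start, stop)`), ties in `peak_frequency`
  to the lower frequency, strict threshold inequalities as printed.
- Gap handling in consensus tracking: frames with no bodypart at or above
  the likelihood cutoff (default 0.9) are missing; interior gaps of ≤ 20
  frames are bridged linearly, longer gaps stay missing — inventing
  trajectories across long occlusions is worse than reporting them.
- Session CSVs store floats at 12 significant digits (round-trip ≤ 1e-9);
  pipeline CSVs at 9 significant digits for bit-reproducible reruns.
- The run manifest records config hash, seed, package version and SHA-256
  of every output; its timestamp is the only field that differs between
  identical reruns, so bit-identity is defined over the stage outputs.

## Problem sizes used in validation

The test suite validates oracle equivalences on 200 random traces
(spectra) and 1000 random fixtures per scan-type extractor; statistical
calibration uses exhaustive enumeration at n = 3 + 3, 1000 null
simulations for the permutation type-I error, and 500 pure-noise fits for
linear-model p uniformity; classifier recovery uses a 600-trial labelled
cohort (3 species × 2 lights × 100). These sizes give stable Monte-Carlo
estimates while keeping the default suite fast.

## Known limitations

- The `paper_literal` speed mode is intentionally not origin-invariant;
  results under it depend on the coordinate convention above.
- The escape/dart boundary is inherently fuzzy for single-sprint darts;
  the rule trace and confidence expose borderline trials rather than
  hiding them.
- `cohort_summary` reports only conditions that contain trials; absent
  conditions are absent rows, not zeros.
- The classifier assumes 30 Hz input; frame-count thresholds scale with
  the trace rate but were chosen at 30 Hz.
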