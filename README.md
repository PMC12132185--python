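# loomkit

Trajectory-to-behavior analytics for looming-stimulus escape assays in
rodents.

When a mouse in an open arena sees an expanding overhead disk — a looming
stimulus mimicking an aerial predator — it freezes, escapes to a shelter,
or *darts*: a protean sequence of short high-speed sprints in varying
directions, often phase-locked to the repetition cycle of the stimulus.
`loomkit` turns center-of-mass tracking of such sessions into quantified
behavior:

- **kinematics** — speed traces from positions: resampling to 30 Hz,
  5-point smoothing, cm/s conversion, baseline z-scoring, pre-stimulus and
  foraging median speeds;
- **events** — threshold-based extraction: running bouts (speed > 30 cm/s
  for ≥ 3 consecutive frames), latency to running, maximal speed, stopping
  time (longest run < 5 cm/s), shelter entries (< 5 cm from a shelter
  corner), zone occupancy, approaches to a moving target (< 10 cm for
  ≥ 10 frames), safe-zone endings;
- **rhythm** — stimulus locking: linear detrend, a single-sided
  mean-squared-amplitude power spectrum (P = (2|FFT(x)|/L)² on interior
  bins), and coefficient-normalised cross-correlations of speed against a
  1 Hz stimulus sinusoid and of bout trains against onset trains;
- **classify** — a deterministic rule-cascade surrogate for manual
  five-category scoring: `stop`, `escape`, `dart_safety`, `dart`, `weak`,
  `none`, with a full rule trace per trial;
- **stats** — permutation mean-difference tests, Wilcoxon rank-sum with
  Bonferroni correction, Pearson correlation with p-values, and OLS linear
  models with per-term partial F-tests;
- **simulate** — a ground-truth generator: stimulus schedules (black loom
  10 × (0.5 s + 0.5 s), white loom / dimming 5×, 21°/s sweep, 3 cm/s
  virtual cricket) and arena trajectories from programmable behavior
  programs (correlated-random-walk foraging, freeze, shelter escape,
  loom-locked darting) with light-level modulation, so every stage of the
  pipeline is verifiable against known answers.

Sessions live in a 35 × 82.5 cm arena with the origin at the shelter-side
corner; readers are provided for pose-tracking CSV exports (the three-row
scorer/bodyparts/coords header dialect) and for a plain session CSV.

## Worked example

Simulate a small labelled cohort, classify every trial, and measure the
stimulus-locking of the darts-to-safety trials:

```python
import numpy as np
from loomkit import simulate_cohort, CohortConfig
from loomkit.arena import ArenaConfig, ZoneSet
from loomkit.kinematics import speed_from_positions
from loomkit.events import detect_bouts, extract_trial_features
from loomkit.classify import classify_trial
from loomkit.rhythm import detrend_linear, power_spectrum, mean_spectrum, peak_frequency

cfg = CohortConfig(n_per_condition=10, species=("Pp",), lights=("dim", "bright"), seed=42)
trials, truth = simulate_cohort(cfg)
zones = ZoneSet.from_arena(ArenaConfig())

labels, specs = [], []
for trial in trials:
    trace = speed_from_positions(trial.recording)
    bouts = detect_bouts(trace)                      # sprints > 30 cm/s, >= 3 frames
    feats = extract_trial_features(trial.recording, trace, trial.schedule, zones, bouts=bouts)
    label = classify_trial(feats, bouts, trial.recording, zones, trial.schedule, trace)
    labels.append(label.value)
    if label.value == "dart_safety":
        vals = trace.window_values(trial.schedule.onset_s, trial.schedule.end_s)[:300]
        specs.append(power_spectrum(detrend_linear(vals), trace.rate_hz))

print("labels:", {v: labels.count(v) for v in sorted(set(labels))})
print("truth :", truth["true_label"].value_counts().sort_index().to_dict())
print("dart-to-safety spectral peak: %.1f Hz"
      % peak_frequency(mean_spectrum(specs), (0.2, 5.0)))
```

which prints

```
labels: {'dart': 2, 'dart_safety': 4, 'escape': 6, 'none': 1, 'stop': 6, 'weak': 1}
truth : {'dart': 2, 'dart_safety': 4, 'escape': 6, 'none': 2, 'stop': 6}
dart-to-safety spectral peak: 1.0 Hz
```

The classifier recovers the programmed behaviors (one quiet foraging trial
brushes the `weak` transient rule — center-of-mass kinematics cannot tell
a brief speed flicker from a startle), and the darts, whose sprints launch
at the loom onsets, produce a mean power spectrum peaking at the 1 Hz
stimulus repetition rate.

The same analysis runs end to end from a shell:

```sh
loomkit run --seed 5 --out out/demo        # simulate -> extract -> classify -> rhythm -> stats
```

writing `ground_truth.csv`, `features.csv`, `labels.csv`,
`label_summary.csv`, `spectra.csv`, `xcorr.csv`, `stats.csv` and a
`manifest.json` with SHA-256 hashes of every output; a rerun with the same
seed reproduces the stage outputs bit-for-bit.

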