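# attnspot

Population decoding and rhythm analysis of a covertly exploring attentional
spotlight, exercised end to end on a synthetic-session generator with known
ground truth.

The package simulates trial-structured multi-unit activity (48 channels, 1 ms
bins, cued target-detection task with distractors) driven by a latent (x, y)
attention trajectory that hops between screen quadrants once per oscillation
cycle and is phase-reset at cue onset. On top of that it implements:

- **`attnspot.synth`** — the session generator: spatially tuned Poisson
  channels, rhythmic spotlight trajectories, phase-gated hit / false-alarm /
  reaction-time laws, four-position and two-position task variants.
- **`attnspot.decoding`** — regularized linear (ridge) decoding of windowed
  firing rates to continuous (x, y) attention estimates and four-class
  quadrant labels; cross-temporal accuracy matrices (70/30 splits, 10
  repeats, 50 ms windows), out-of-fold spotlight trajectories, and
  post-stimulus (50–100 ms) target/distractor decoding.
- **`attnspot.rhythm`** — analytic Morlet transform (12 voices per octave,
  4–20 Hz), attention-information time series, 7–12 Hz band peaks, cue-phase
  estimation, circular statistics, and permutation nulls built by circularly
  time-shifting each trial's spiking before decoding.
- **`attnspot.phase_behavior`** — sinusoidal session phase model, ten-bin
  phase assignment with a 5 ms optimal-lag sweep, upper/lower-third
  peak/trough summaries, and pooled per-millisecond hit-rate / geometric-mean
  reaction-time series with f-normalized wavelet spectra and permutation
  significance.
- **`attnspot.super_mua`** — per-trial population "super MUA", alpha-cycle
  detection, and per-channel spiking-probability modulation by oscillatory
  phase over 5–15 Hz.
- **`attnspot.exploration`** — quadrant collapse of trajectories, Markov
  transition estimation, pre-cue normalization with canonical
  [stay / same-hemifield / opposite-hemifield / diagonal] remapping,
  occupancy maps and displacement statistics with Kolmogorov–Smirnov
  comparisons.
- **`attnspot.cli`** — a `click` command-line front end.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end parameter-recovery criteria
(injected oscillation frequency and cue phase, phase-gated hit/false-alarm
laws, distractor-encoding modulation, Markov transition rows); the remaining
files are per-module unit and property tests.

## CLI

```sh
attnspot simulate --task four --n-trials 500 --seed 7 --out runs/sess7
attnspot decode   --session runs/sess7 --out runs/decode7
attnspot rhythm   --session runs/sess7 --n-perm 100 --out runs/rhythm7
attnspot phase    --session runs/sess7 --out runs/phase7
attnspot supermua --session runs/sess7 --out runs/supermua7
attnspot markov   --session runs/sess7 --trajectories runs/decode7 --out runs/markov7
attnspot all      --n-trials 300 --seed 7 --out runs/all7
```

Outputs are plain TSV/JSON with a `manifest.json` listing every file with a
SHA-256 content hash; identical seeds reproduce identical artifacts.

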