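# Methods

This note documents the models, conventions and design choices behind
gaitcsm, in the order the pipeline uses them. Index conventions are
0-based with half-open intervals everywhere.

## Synthetic ground contact forces

The generator (`gaitcsm.synth`) emulates steady treadmill walking for
one instrumented foot with ball and heel load cells, the regime the
detector is designed for.

- **Cycle timing.** Gait cycle duration maps linearly from 2000 ms at
  2 km/h to 1000 ms at 6 km/h (only the range and monotonicity are
  physiologically fixed; the linear interpolation is a modeling
  choice). Stance occupies `stance_fraction` (default 0.6) of each
  cycle; the heel contacts `heel_lead_ms` (default 100 ms) before the
  ball.
- **Stance profile.** Within stance the force follows a sum of two
  Gaussian bumps (loading and push-off peaks, centers 0.25/0.75 of
  stance, width 0.2, channel-specific peak ratio) under a flat-top
  window with half-cosine edge ramps, normalized to the stance peak
  force. The ramps make the loading/unloading transitions last ~60 ms
  at 2 km/h down to ~40 ms at 6 km/h — transition sharpness is the
  feature the detector keys on, and real force transitions are fast
  and only weakly speed-dependent, unlike the mid-stance shape. Swing
  samples are exactly zero before noise.
- **Amplitude.** The stance peak is `peak_force` (default 100,
  arbitrary units — all algorithms are scale-covariant) times a linear
  speed gain (`amp_gain_per_kmh` = 0.15, i.e. 1.6× from 2 to 6 km/h),
  times a per-subject weight factor (lognormal-ish N(1, 0.08), clipped)
  in dataset generation.
- **Noise and artifacts.** Additive zero-mean Gaussian noise
  (`noise_sd` = 2) on every sample; isolated single-sample spikes of
  ±`spike_magnitude` (150) placed by a Poisson process
  (`spike_rate_per_s` = 0.1) emulate the abnormal values load cells
  produce. Spike injection is a separate pure function so noiseless
  ground truth is available.
- **What it does not model.** Slopes, stairs, irregular terrain,
  pathological gait, inter-stride timing variability, drift, or sensor
  saturation. Tests passing on this generator show the pipeline's
  internal consistency and its robustness to amplitude diversity,
  noise and spikes — not performance on real recordings.

All generator randomness flows from integer seeds; identical
configuration gives bit-identical traces.

## Reference labeling

The global threshold is Thr = α(T_MAX − T_MIN) + T_MIN with α = 0.094,
where T_MAX/T_MIN are means of per-cycle force maxima/minima. Cycle
extrema are extracted from segments delimited by crossings of the
channel's mid-range level, keeping only segments of ≥ 300 ms. Two
robustness measures protect this offline estimator from spike
artifacts: a 3-sample median filter before segmentation, and extreme
quantiles (0.5%/99.5%) instead of min/max for the mid-range level.

Four-phase labeling (3 on-ground, 1 initial off-ground, 0 off-ground,
2 initial on-ground) brackets each threshold crossing with a t_W
window (default 50 ms):

- the **initial off-ground** window starts at the first sample below
  Thr and spans [i, i + w);
- the **initial on-ground** window ends at the first sample at or
  above Thr, spanning [j + 1 − w, j + 1) — the crossing sample itself
  is the window's newest point. This convention makes the last window
  of each run exactly the status-start curve the templates model:
  newest sample across the threshold, three older samples on the other
  side.

An off-ground period too short to hold both windows raises a labeling
error (abnormal tagging needs manual correction); the pipeline avoids
most such cases by debouncing the binarized signal first (status runs
shorter than `min_run_ms` = 150 ms are absorbed), the automated
analogue of fixing abnormal tags by hand. With t_W = 50 ms and cycles
of 1000–2000 ms the theoretical pointwise error floor of a
threshold-perfect detector is 2.5–5%.

## Curve similarity model

The 10-element curve, Gaussian transform and distance are given in the
README. Numerical conventions:

- public interfaces take windows in time order (oldest → newest) and
  map internally to the newest-first element order;
- δⱼ must be strictly positive; trained widths are clamped to ≥ 1e−6
  of the channel's dynamic range;
- d ∈ [0, 10) in exact arithmetic; in floats a very distant curve can
  reach exactly 10.0 through underflow of every transform element;
- ε outside the preferable band (0, 2] warns but does not fail — the
  bound is a recommendation, not a validity condition.

A trained parameter set for adult treadmill walking ships with the
package (`load_example_model()`); its centers are evolutionary search
results, not empirical window means, which is why individual elements
(e.g. a negative center for a nonnegative force element with a large
width) need not look physical.

## Detection

The streaming detector (batch and push-sample interfaces are exactly
equivalent) initializes on-ground — G(1)=G(2)=G(3)=1 — and for every
later sample tests the on-ground-start template first, then the
off-ground-start template; no match keeps the previous status. A
recording that begins mid-swing is therefore misclassified until the
first off-ground start is detected; this initialization is part of the
algorithm's contract and is preserved as-is.

A starting flag is recorded at the first window of each contiguous run
of satisfied tests: one flag per detected phase entry. Separate runs
within one cycle yield repeated same-type flags, which never toggle
the status and are scored as over-detections, not errors. The binary
status codes (1 on-ground, 0 off-ground) are deliberately a distinct
vocabulary from the four-phase label codes; `PhaseTrack.binary` maps
labels {3, 2} → 1 and {0, 1} → 0 (the initial windows are transition
buffers; this mapping assigns each to the status it is entering).

One trained model serves both channels and both feet; per-channel
models remain possible by training on different labeled subsets.

## Evaluation

Flags are matched per status against the reference track: a flag in
the matching initial window is correct (tn, first per window); in the
already-entered status or duplicated, an over-detection (sn); in the
opposite half of the cycle, false (fn); an unmatched window is a miss
(mn). Counts satisfy tn = cn − mn and dn = tn + fn + sn by
construction. F = (mn + fn)/2 per status is the training fitness; the
event rates are E1 = (mn₁+fn₁)/cn₁, E2 likewise for on-ground, E3
pooled, all ×100.

E4 is computed as the per-sample **disagreement** fraction between
detected and reference binary status. The formula as printed in its
source scores agreement yet is named an error rate and reported at a
few percent alongside zero event error; the disagreement reading is
the one consistent with both, and the literal agreement variant is
available behind `pointwise_error(..., literal=True)`. E4 has a
nonzero floor (t_W/cycle) even under perfect event detection because
the two protocols place the switch instant differently within each
transition window.

## Evolutionary training

Two independent searches (off-ground-start, then on-ground-start with
the next seed) evolve (μ, δ) pairs. Structure: 2·PopSize individuals;
each generation sorts all by fitness (stable, ties keep insertion
order), grades the best PopSize into quartiles (kind 1 = best), lets
parent j produce kind+1 mutated descendants (worse quartiles reproduce
more; `invert_kind` flips this), and stores the best descendant in
slot PopSize + j. Parents persist in [0, PopSize), so the best-so-far
fitness is non-increasing. Defaults PopSize = 20, MaxGen = 200.

Choices the algorithm's outline leaves open:

- **Initialization.** μ is sampled uniformly per element within the
  2%/98% quantile box of the *starting-flag curves* observed in the
  labeled training data (the window at each threshold crossing — the
  most distinctive window of each transition run); δ is sampled
  log-uniformly between 1/8 of that box width and the full width.
  Data-informed boxes keep the 20-dimensional search tractable.
- **Mutation.** Additive Gaussian steps for μ (sd = `mutation_scale`
  × box width) and multiplicative log-normal steps for δ, both
  annealed by `mutation_decay` = 0.95 per generation down to a floor
  of 0.05; each element is additionally resampled from its init box
  with probability 0.05, which lets the search escape basins that
  cover only part of the transition-curve family (e.g. one channel's
  amplitudes).
- **Early stop.** `target_fitness` optionally ends the run once
  reached (elitism makes further generations no-ops at fitness 0);
  the default is the full MaxGen budget.

On the bundled generator, training on both channels of six subjects at
2/4/6 km/h (20 s each) reaches held-out pooled event error E3 ≈ 4–5%
and pointwise error E4 ≈ 4%; on clean noiseless traces the search
recovers fitness-0 templates in essentially every seed.

## Problem sizes

The default experiment (`ExperimentConfig`) uses 10 subjects × 3
speeds × 20 s at 100 Hz, subjects 0–5 for training and 6–9 held out;
the test suite runs it at MaxGen = 50 and `scripts/acceptance.py` at
the full MaxGen = 200. These sizes are the package's reference
conditions; all are configurable.

## Known limitations

- The axis-aligned Gaussian template cannot model correlations between
  curve elements, so amplitude diversity across speeds and subjects is
  absorbed entirely by per-element widths; extreme diversity inflates
  either misses or false entries.
- The on-ground initialization mislabels recordings that start
  mid-swing until the first transition.
- The reference labeling, not biomechanical ground truth, defines
  "correct" during training and evaluation; systematic threshold bias
  propagates into the templates.
- The 2000 Hz acquisition path of real hardware is out of scope; the
  toolkit operates at an effective 100 Hz, with `decimate_mean`
  provided for block-averaging higher-rate recordings.
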