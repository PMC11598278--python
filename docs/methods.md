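# Methods

This note documents the models, the synthetic data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Problem setting

A gesture classifier is trained on surface-EMG sessions recorded on
different days. Two nuisance processes make sessions non-identically
distributed: *electrode displacement* (day-to-day changes in electrode
position relative to the muscle, which re-mixes how each gesture projects
onto the recording channels) and *slow time-varying characteristics*
(impedance and physiological drift, which scale and reshape the signal).
The package treats this as a continual-learning problem: sessions arrive
over time, and the model must learn new sessions without forgetting old
ones, under a fixed memory budget for stored exemplars.

## Preprocessing and segmentation

Filtering uses a 4th-order Butterworth band-pass (20–300 Hz, the band that
carries most sEMG power) applied forward–backward for zero phase, and a
2nd-order IIR notch at the 50 Hz line frequency with quality factor 30.
The filter family and order are package choices; only the bands are fixed
by the protocol.

Segmentation thresholds the blockwise average energy across the four
channels (blocks of N = 64 samples, non-overlapping hop 64). Rest
statistics (mean μ, standard deviation σ) are estimated from the first
1000 samples, which the protocol guarantees to be rest; an action onset is
declared when E_w(t) > μ + 3σ for at least 3 consecutive blocks, and the
offset symmetrically. The 3-block minimum (192 ms) rejects isolated
suprathreshold blocks produced by zero-phase filter smear at burst edges
while staying far below the shortest plausible action (600 ms). All of
N, hop, the threshold multipliers and the minimum run are configuration
knobs (`SegmenterParams`).

Detected actions of varying effective length are standardized to exactly
1000 samples by centering the window on the active interval's midpoint.
Shorter intervals are completed with flanking *raw signal* rather than
zero padding (zeros would be trivially separable from rest noise and leak
the boundary decision into the classifier); windows are clamped at
recording edges. Longer intervals are center-truncated by the same rule.

## The 1-D DenseNet

Input is a 4×1000 segment. The stem is conv(k7, stride 2, 4→48 channels) →
BN → ReLU → max-pool(3, stride 2). Four dense blocks of six layers follow;
each layer is the plain composite BN → ReLU → conv(k3, pad 1) producing
k = 24 new channels and consuming the concatenation of everything before
it in the block, so layer j's input width is entry + 24·j. Transitions
(BN → ReLU → conv k1 with compression 0.5 → average-pool 2) separate the
blocks; the last block feeds BN → ReLU → global average pooling → a linear
head. Convolutions carry no bias (batch norm absorbs it).

Two open architecture questions were pinned by the parameter budget: with
the plain (bottleneck-free) composite the model has 369 787 trainable
parameters (0.4 M at one decimal); a 1×1-bottleneck variant lands near
0.6 M. The optimizer is Adam at the protocol learning rate 0.001 — the
protocol fixes lr/batch/epochs but not the optimizer family.

The network is implemented as a small numpy layer stack with manual
backpropagation (`emgreplay.nn`): im2col + GEMM convolutions whose input
gradient is computed as a dilated correlation with the flipped kernel,
standard batch-norm backward, and Adam. Training is bit-reproducible for a
fixed (weights-seed, data, config) on a fixed BLAS; eval-mode batch norm
uses running statistics (momentum 0.1), which makes inference invariant to
batch partitioning.

A `DenseNetSpec.reduced()` variant (blocks 3-3, growth 12, stem 24,
stem stride 4) keeps the same architecture family at roughly 1/50 of the
compute; it is the default for the scaled-down experiments in the test
suite and for the desk-scale CLI runs. The full spec is always used for
the parameter-count checks.

## Replay training

The two-term loss `loss_T = (1 − λ)·loss_R + λ·loss_I` is applied at
minibatch granularity with paired batches — one from the replay buffer,
one from the incremental set — rather than by pre-mixing datasets. This
keeps loss_R and loss_I separately measurable and makes λ an exact convex
weight on the gradients. λ is static within one increment: in
time-incremental mode λ = max(N_Incl/N_Total, 0.2) with N_Total the total
sample count seen so far (the floor encodes that newer sessions are more
valid); in class-incremental mode λ is the class ratio (1/7 for one new
gesture among seven). Dynamic λ schedules are out of scope. With λ = 1 the
buffer is ignored and the increment reduces exactly to plain training on
the incremental set — this is the no-replay ablation.

After every increment the buffer is rebuilt from scratch over all seen
sessions. The total budget is divided equally over the (day, class) cells
present, remainder to the earliest days (the oldest data are the scarcest
signal about the past). Four per-class exemplar selectors are provided:

* **dbscan** — segments are featurized by per-channel RMS (4 values),
  z-scored, and clustered with DBSCAN (min_samples 5; eps defaults to the
  90th percentile of 4-nearest-neighbor distances, a per-cloud scale-free
  choice). Noise points are discarded and the rest ranked by distance to
  the centroid of the largest cluster's core points; the centroid
  reference makes the ranking total (every core point is at distance zero
  from *some* core point). Noise backfills only when non-noise runs out;
  an all-noise clustering falls back to distance-to-overall-centroid.
* **random** — uniform without replacement, seeded.
* **uniform** — rounded linear spacing over the repetition order,
  including both endpoints (captures slow within-session drift such as
  fatigue); a budget of 1 takes the first repetition by convention.
* **intermediate** — the contiguous central block of the repetition
  order (start/end executions are assumed transitional).

Whether to standardize RMS features before clustering is a knob;
standardization defaults on, since channel RMS scales differ by an order
of magnitude and unstandardized Euclidean distances would be dominated by
the loudest channel.

Class increments expand the linear head: old rows/bias are copied
bit-exactly and new rows are zero-initialized, so old-class logits are
unchanged until training resumes and new-class logits start at exactly 0.

## Increment schedules

For the canonical 12-day protocol the schedule table is embedded as
literal data: given a test day, the two sessions farthest from it in time
start the initial model and the rest arrive as increments in decreasing
span order. The table's tie-breaking flips direction between test days
1–7 (later day first) and 8–12 (earlier day first), and the row for test
day 7 orders its two initial days against the span sort; transcription
was therefore preferred over re-derivation. `generic_schedule` exposes the
span-sorted construction for any study length with both tie policies.

## The synthetic study generator

The generator emulates the acquisition protocol — daily sessions of
7 gesture classes × 100 repetitions, 4 channels at 1000 Hz, actions of
600–1400 samples separated by rest — with a three-part signal model:

1. **Carrier**: each action is band-limited Gaussian noise (white noise
   band-passed to 20–300 Hz), the standard surrogate for
   interference-pattern EMG, under a raised-cosine on/off envelope
   (100-sample ramps) and ±10 % lognormal per-repetition amplitude jitter.
   Rest is white noise at SD 0.05 versus burst SD 1.0.
2. **Electrode displacement**: each gesture class has a non-negative,
   max-normalized activation row over the 4 channels (one or two dominant
   channels, pairwise cosine similarity < 0.95). Each day this mixing
   matrix receives additive Gaussian perturbation (SD
   `displacement_scale` = 0.25) and is re-normalized; perturbations
   compound across days, so distribution distance from day 1 grows with
   the day index.
3. **Time-varying gain**: a multiplicative amplitude factor
   `daily_gain_drift` = 0.95 per elapsed day.

The displacement default was calibrated once so that the synthetic study
reproduces the qualitative cross-session phenomenology — near-ceiling
within-day accuracy with a clearly degraded, span-decreasing cross-day
accuracy — and was then frozen. A (config, seed) pair fully determines
every generated byte.

What the generator does *not* model: motor-unit recruitment and firing
statistics, muscle fatigue spectra (frequency compression over a session),
inter-subject variability, amputee signal characteristics, or
class-dependent drift. Consequently, passing tests demonstrate that the
pipeline behaves correctly under controlled channel-pattern drift — the
mechanism the replay framework targets — not that the specific accuracy
figures transfer to human data.

## Scaled study conditions used by the test suite

Real-protocol-sized runs (12 days × 700 segments × 50 epochs at 0.4 M
parameters) are not needed to check the framework's properties. The
end-to-end acceptance tests use: 3-day studies of 20 reps/class for the
within-day vs cross-day contrast (stratified 3-fold CV on day 1); a 5-day
study of 12 reps/class for the increment curve (the generic schedule then
yields two initial days and two increments); a 3-day study for the
forgetting-gap ablation (initial model on day 1, increments days 2–3,
scored on held-out day-1 segments, replay vs λ = 1); and 3-day studies
with one held-out gesture for class increments. All use the reduced spec,
10 epochs, batch 32, and are averaged over seeds {0, 1, 2}. With only two
initial days required by the schedule type, three days is the smallest
study with a meaningful forgetting experiment and five the smallest with
two increment steps.

## Numerical and degenerate-input choices

* Cross-entropy on probabilities clamps the true-class probability at
  1e−12 (logged) so perfect-confidence mistakes yield a large finite loss.
* Stratified validation splits never empty a class's training side; a
  fold request larger than the smallest class is an error.
* `epochs = 0` is a no-op returning an empty history.
* Energy blocks use the half-open convention `[t·hop, t·hop + N)`; block
  counts are `floor((n − N)/hop) + 1`.
* Empty incremental sets make `increment_step` a warned no-op; a λ < 1
  increment with an empty buffer is an error.
* Selector ties (equal spacing positions, equal distances) resolve to the
  lower index via stable sorts.
* File formats carry a `v<major>.<minor>` tag; readers reject unknown
  majors. Session CSVs store float64 via `repr`, which round-trips
  bit-exactly.

## Known limitations

* The numpy training stack is single-threaded GEMM-bound; it is sized for
  desk-scale studies, not for the full 12-day × 8-subject protocol.
* Bit-reproducibility holds per platform/BLAS build, not across different
  BLAS implementations.
* DBSCAN representativeness operates on 4-dimensional RMS features only;
  richer featurizations (spectral moments, time-domain descriptor sets)
  are out of scope.
* The λ floor and class-ratio rules are taken as given; no attempt is made
  to tune them, and dynamic (span-dependent) weighting is explicitly not
  implemented.
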