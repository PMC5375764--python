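# Methods

## Problem setting and model

The pipeline treats gait recognition as image classification over
orientation-invariant encodings of short inertial-sensor windows. Its
assumptions, in the order the data flows:

- The raw recording is a strictly increasing timestamp series with
  triaxial acceleration and angular velocity. Sampling may be irregular
  (consumer devices log at whatever rate the OS allows); cubic-spline
  resampling at `f = 50 Hz` restores a uniform grid. The grid is anchored
  at the first timestamp so the spline never extrapolates, and the
  not-a-knot boundary condition is used, which reproduces any cubic
  polynomial exactly — a property the tests rely on. No anti-aliasing is
  applied when upsampling (e.g. from ~28.6 Hz): the spline itself is the
  only smoother.
- Gait is quasi-periodic and every cycle is assumed to start at a peak of
  the acceleration magnitude `aM`. Because `‖R a‖ = ‖a‖` for any rotation
  `R`, segmentation on `aM` is already pose-independent.
- The per-cycle angle image (AE-GDI) depends only on angles between
  time-delay chords of the 3-D sample path, so any similarity transform of
  the sensor frame (rotation + translation + uniform scale) leaves it
  unchanged. This is the core invariance and is enforced to < 1e−9 by the
  acceptance suite.

## Segmentation

Period estimation uses the circular autocorrelation of the mean-removed
buffer, searched over a lag window of 0.4–2.0 s (a documented default
covering plausible human cadence; both ends are config keys). Two guards
make the estimator usable as a library primitive:

- a minimum normalized autocorrelation of 0.2 at the best lag, below which
  the input is rejected as non-periodic (white noise sits near
  `1/sqrt(N)`, clearly below; any walking signal sits far above);
- among *locally maximal* lags within 2 % of the best value the smallest
  is preferred, because an exactly periodic series correlates equally well
  at twice its period and measurement noise could otherwise flip the
  argmax.

Peaks are local maxima under a left-strict/right-non-strict comparison, so
a plateau collapses to its leftmost sample. Each peak `t` is scored
`τ(t) = aM(t) + lU(t)` where `lU` is the arc length of the nearest
U-shaped valley (adjacent decreasing-then-increasing monotone runs) ending
at or before `t`. Arc lengths treat the series as a planar curve whose
sample spacing has the equivalent length `ε/f`; each step contributes
`sqrt(ΔaM² + (ε/f)²)`. By default `ε` is set so that `ε/f` equals one
tenth of the buffer's standard deviation, making the score ranking
invariant to amplitude rescaling when `ε` is scaled along (tested).
Monotone runs with arc length below `L_T · ε/f` (default `L_T = 3` sample
lengths) are dropped and adjacent surviving runs of equal sign merged.

The candidate set keeps the `Nc` highest-scoring peaks with `Nc` the
smallest integer strictly greater than `2N/ĝ` — about two candidates per
expected cycle, enough to keep both the dominant and a plausible
sub-dominant peak in play.

Grid fitting runs in two stages. Stage 1 alternates between snapping each
grid index `int(b + k·c)` (`k = 0..int(N/c)−1`, `b` initialised to 0 and
`c` to `ĝ`) to the best-scoring candidate within `ĝ/2`, and re-estimating
`c` as the median per-index-gap difference of the snaps and `b` by the mean
snap residual, until both move by at most 0.5 samples (cap: 20 iterations;
`c` is clamped to `[0.5ĝ, 1.5ĝ]`). Two robustness choices proved necessary
on noisy input and are deliberate deviations from the plain mean-of-
differences update: when two grid points snap into the same cycle (closer
than `c/2`) only the higher-scoring snap is kept, and the converged offset
is reduced modulo `c` so the grid covers the whole buffer. Stage 2 drops
the equal-spacing constraint: each grid index snaps within `ĝ/4` using the
penalised score `τ(t) − (ε/f)·|t − ĥ(t)|` with `ĥ(t)` the nearest grid
index. Score ties break toward smaller distance, then smaller index, so
the search is deterministic; because the per-grid-point choices are
independent, the greedy assignment equals exhaustive search over all
within-radius candidate combinations (verified against enumeration in the
tests). Grid points with no candidate in radius are dropped, as are
duplicates; incomplete trailing cycles are never fabricated.

## Encoding

Pixel `(j, i)` of a cycle-aligned image is the vertex angle at
`x(start + i)` with delay `m = j` (rows `j = 1..Nh`; a delay-0 row would be
degenerate everywhere and is excluded). The angle is `arccos` of the
clipped normalized inner product; vertices with a chord shorter than
1e−12 are flagged degenerate and written as 0, with a per-image mask kept.
Cycles whose window would index outside the buffer are skipped rather than
padded — padding would fabricate angles. Experimental geometry is
`Nw = 64`, `Nh = 32` (1.28 s and 0.64 s at 50 Hz), chosen so the window
exceeds one full gait cycle for cadences up to 1.25 s. Pixels are fed to
the classifier in raw radians — `[0, π]` is already bounded. Both channels
(acceleration first, angular velocity second) use the same start indexes,
detected once per buffer on `aM`. The delay-inner-product GDI and the
1.28 s / 0.5 s-overlap sliding-window segmentation are provided as
baselines for comparison experiments.

## Classifier

The network is conv1 → mp1 → conv2 → conv3 → mp2 → fl1 (ReLU) → fl2 →
softmax, with 3×3 valid (no zero padding) convolutions — so each conv
shrinks both spatial dimensions by 2 — and 2×2 stride-2 max pooling with
floor on odd sizes (30×62 → 15×31). Dropout with drop probability 0.5 sits
before each fully connected layer (both fl1 and fl2) at training time.
Weights are initialised randomly and orthogonally (QR of a Gaussian
matrix; the flattened kernel matrix satisfies `W Wᵀ = I` on its smaller
side). Training minimises softmax cross-entropy with Adam (learning rate
0.001) on mini-batches of 100 for 50 epochs by default; trailing
mini-batches smaller than 100 are used, not dropped. One seed governs
initialisation, shuffling and dropout, so a run is bit-reproducible on the
same platform. The implementation is plain numpy with analytic
backpropagation, validated by finite-difference gradient checks and a
hand-computed forward-pass oracle in the test suite.

Per-layer feature-map counts are configuration, not logic; the defaults
are (32, 64, 64) with a 1024-wide fl1. The output width is 2 for
authentication and K for K-way labeling. A temporal ablation (TCNN) swaps
1×3 convolutions and 1×2 pooling in, leaving the delay axis untouched. The
`n_conv` knob keeps conv1/mp1 fixed and varies the number of convolution
layers before the second pooling layer; with `n_conv = 1` that pooling
layer is removed.

Multi-cycle decisions average the softmax probability vectors of N
consecutive cycles and take the argmax (ties to the lowest class index);
majority voting is available behind a flag. Mean aggregation uses the full
probability information and is deterministic.

## Synthetic data: what it emulates and what it does not

Each subject's signal is a per-axis sum of 4 harmonics of the cadence
frequency with seeded amplitudes and phases, plus a gravity offset on the
accelerometer; the cadence period is drawn from 0.9–1.25 s. Amplitude
ranges (fundamental 1.8–3.0 m/s², second harmonic 0.3–0.9, higher orders
smaller) give every cycle one dominant magnitude peak with sub-dominant
structure, mirroring the shape of real walking magnitude traces.
Timestamps use truncated-Gaussian inter-sample intervals (floored at 0.2×
the mean interval) around a target rate of 28.57 ± 4.17 Hz, emulating
multitasking-OS sampling. Sensor noise is i.i.d. Gaussian (0.15 m/s²,
0.05 rad/s). Each session applies a random proper rotation (and optionally
translation and scale) to both channels, emulating a device re-pocketed
with arbitrary pose. Ground-truth cycle starts are the global per-cycle
maxima of the noiseless magnitude; an attenuated-peak fixture scales one
cycle's dominant peak by 0.6 to exercise the weak-peak robustness of the
segmenter. Inter-subject separability is governed by the harmonic draw
ranges and is deliberately exposed as configuration — nothing in the
generator fixes how distinguishable real populations are.

Not emulated: biomechanics (double support, left/right asymmetry),
treadmill or incline variation, sensor bias and drift, clothing/payload
change within a subject, or subject-shifting inside one sequence. Passing
tests therefore demonstrate that the pipeline recovers identity whenever
per-subject waveform signatures are stable across sessions and device
pose changes arbitrarily — they do not quantify accuracy on real
populations.

One observed limitation follows directly from the scoring rule: the
detected cycle start is the peak following the *largest valley*, which
need not be the globally highest peak of the cycle. For most waveforms the
two coincide; for subjects where two peaks score nearly equally, detection
can lock onto different peaks in different sessions (a bistable
alignment), which degrades that subject's recognition. This mirrors the
method's real failure mode and is left visible in the evaluation tests
rather than patched away.

## Evaluation protocols

Labeling trains one K-way classifier on a configurable percentage of every
gallery sequence and labels each probe sequence by aggregating all its
AE-GDIs. Authentication trains one binary classifier per subject on μ % of
the subject's gallery images against an equal number of impostor images
drawn uniformly from the other subjects (the field gives no canonical
negative-class recipe; balanced 1:1 sampling is this package's choice),
then scores consecutive N-cycle probe groups, impostors balanced 1:1.
"Same-day" versus "different-day" conditions are modeled as same-session
versus new-session (fresh orientation and noise). All split, fold and
impostor randomness flows from a single experiment seed recorded in the
outputs. Metrics are precision, recall and accuracy from the pooled
confusion counts; a zero denominator reports the metric as undefined
rather than 0. Sweeps run one experiment per grid point and record
failures per row instead of aborting.

Experiment defaults in `ExperimentConfig` use a scaled-down classifier
(feature maps (8, 16, 16), fl1 width 96, 20 epochs) sized for the
synthetic cohorts the test suite runs — a few hundred training images —
while `CnnSpec.for_task` defaults describe the full-cohort architecture.
The acceptance benchmark (10 subjects, 2 sessions, 40 cycles/session)
finishes in a few minutes on one CPU at these sizes.

## Numerical choices

- Angles via `arccos` of the clipped cosine, as defined; the conditioning
  loss near θ = π is acceptable because random 3-D paths place negligible
  mass there (angle density ∝ sin θ).
- Rotation matrices are validated to orthonormality and det +1 within
  1e−8; random rotations come from sign-fixed QR of a Gaussian matrix.
- Degenerate angle vertices → pixel 0 plus a mask, never NaN.
- Training aborts on a non-finite loss with the epoch/batch in the
  message; a class missing from the training set warns.
- All randomness is generator-based (`numpy.random.Generator`) and seeded;
  derived seeds are produced by `SeedSequence` spawning and stay below 2³¹.
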