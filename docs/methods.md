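# Methods

## Synthetic cohort generator

The generator emulates a multi-subject, multi-speed treadmill study: each
subject walks one 60 s trial (100 Hz) at each of 9 speeds spanning 0.3 m/s
to a walk-to-run transition around 2 m/s; smaller cohorts are used for
desk-scale experiments. Channel sets follow standard gait-lab conventions:
6 sagittal-plane joint angles (2D kinematics), 18 joint angles in three
planes (3D kinematics), 42 kinetic channels (bilateral 3-axis GRFs plus
hip/knee/ankle moments and powers in three planes), or all 60 combined.

**Waveform model.** Cadence is linear in belt speed,
`cadence(s) = c0 + c1·s` (steps/min). Stride phase advances at
`cadence/120` strides/s; each stride's duration is perturbed
multiplicatively by `1 + jitter_sd·z`. Channel `c` is a truncated Fourier
series on stride phase with subject-specific amplitudes `A[c,h]` and phases
`ψ[c,h]`, an amplitude gain linear in speed,
`1 + γ·(s − s̄)/s̄` with `s̄` the cohort mid-speed (keeping the gain
positive across the grid), and additive Gaussian noise. The vertical GRF is
a body-weight-scaled two-peak stance template
(`0.15 + sin(πu) + 0.3·sin(3πu)` body weights on the stance-normalized
axis), exactly zero during swing; the stance fraction decreases linearly
from 0.65 at the slowest to 0.55 at the fastest grid speed. The 0.15-BW
pedestal makes loading onset steep, as in real force-plate data, so a 20 N
threshold detects foot contact at the first stance sample. Left events are
offset from right by half a stride (symmetric able-bodied gait). Kinetic
channels reuse the harmonic model; GRF channels are gated to their side's
stance and scaled toward body weight.

**Individuality and defaults.** A cohort-level harmonic structure is drawn
once per seed; subjects perturb it. All between-subject variation scales
with a single `dispersion` factor (0 collapses the cohort onto identical
waveforms). Defaults, chosen once as representative of able-bodied
inter-individual variability: amplitude dispersion 20% (log-normal), phase
dispersion 0.30 rad, cadence intercept 60 ± 4 steps/min, cadence slope
40 ± 4 steps/min per m/s, amplitude speed-gain γ = 0.3 ± 0.05, channel
noise SD 0.5 units, stride jitter SD 2%. Self-selected speed
(1.25 ± 0.15 m/s) and narrowing-beam balance score (15 ± 4 ft) are drawn
jointly with correlation 0.5, matching the positive association between
preferred speed and balance the analyses are designed to detect. Step
length ground truth uses the treadmill belt-frame definition
`speed × step time`; step width is a per-subject constant.

**What the generator does not emulate:** biomechanically validated joint
trajectories, asymmetric or impaired gait, nonlinear speed effects,
kinematic/kinetic coupling through actual dynamics, soft-tissue artifact.
Passing tests therefore demonstrate that the pipeline recovers known
cyclic, individual-specific, speed-modulated structure — not that it
characterizes real pathological gait.

## Dynamics model

A single-layer LSTM (gate order i, f, g, o; forget-gate bias 1; orthogonal
recurrent kernel, Glorot input kernel) with a linear readout is trained
sequence-to-sequence with teacher forcing to predict the next sample of the
per-channel standardized series. Standardization statistics are cohort-wide
and stored with the model so signatures are comparable across trials. All
trials form one batch per epoch; the loss is the mean squared one-step
error plus an L2 penalty on the LSTM input kernel. Optimization is Adam
with global-norm gradient clipping (5.0) and early stopping on a training
loss plateau (patience 25, tolerance 1e-5). Dropout applies only on the
hidden-state path into the readout, and only during training; latent
extraction always runs deterministically with dropout disabled.

The forward pass, backpropagation through time and Adam are implemented
directly on float64 NumPy arrays: training is deterministic for a fixed
seed, which the reproducibility contracts (manifest hashes, byte-identical
reruns) rely on.

Reference defaults are 512 hidden units, learning rate 1e-4, dropout 0.2,
L2 0.01. The desk-scale experiments in the tests and acceptance script use
a 64-unit model with learning rate 5e-3 and L2 1e-4 for 100 epochs — the
learning rate and penalty are scaled to the smaller model and shorter
training budget; identification results are insensitive to modest changes
here because the signature separability comes from the latent encoding of
the inputs, which is already strong once the predictor fits well.

"Internal activations" are the hidden states `h_t` (the layer output that
feeds the readout); the cell state can optionally be concatenated. Latents
align with predictions: `T−1` states for a length-`T` trial, zero initial
state, no warm-up trimming by default.

## Signatures

PCA is fit on the time-concatenated latents of all trials (centered, full
SVD); component signs are canonicalized (largest-magnitude loading
positive) so repeated fits are identical. Each trial's retained-PC
trajectory is resampled stride-by-stride — strides are half-open intervals
between consecutive right heel strikes, linearly interpolated onto 100
equispaced phase bins (conventional percent-gait-cycle resolution) — and
averaged pointwise; strides shorter than 0.5× or longer than 2× the median
are excluded. The loop flattened row-major is the signature vector.

The variance-explained curve replaces every trial's latents with their
rank-N PCA reconstruction, passes them through the model's existing linear
readout (no retraining — the readout is fixed, making the curve
deterministic and exactly complete at N = K), and pools
R² = 1 − SSE/SST across all channels and trials, SST about the per-channel
mean. The retained dimensionality is the smallest N reaching 80%
cumulative R². Because the readout maps the latent projection error into
channel space, the curve is non-decreasing only up to a small cross-term
with the prediction residual (observed ≤ 1e-4 R² units, high-N tail); the
N = K completeness identity is exact.

## Identification experiment

Subjects with incomplete speed grids are excluded (exactly `required_trials`
trials each). For each training-set size k, each run draws k trials per
subject uniformly without replacement (split seed = run number), z-scores
features with training-set statistics, trains a linear-kernel one-vs-one
SVM (C = 1), and pools accuracy over all test trials. The confidence
interval is the 2.5/97.5 percentile of per-run accuracies. Accuracy
distributions are compared with two-sided Mann-Whitney U tests; the effect
size is r = Z/√(n₁+n₂) from the tie-corrected normal approximation, signed
so r > 0 means the first sample tends larger. Discrete-variable baselines
(26 biomechanical, 18 kinematic-only, 8 kinetic-only, 10 spatiotemporal
features) run through the identical protocol.

## Gait map and speed models

Classical (Torgerson) MDS — double-centered squared distances, top-3
eigenvectors scaled by √eigenvalue — is used rather than iterative SMACOF
because it is deterministic; axis signs are canonicalized (axis 1 flipped
to correlate non-negatively with speed when speeds are supplied). Kruskal
stress-1 and the Pearson correlation between input and embedded distances
are recorded. Distance statistics (intra vs inter-individual, pooled
z-scores, two-sided Mann-Whitney U) are computed in the 3D map coordinates
by default, with a config switch for the full signature vectors.

Mixed-effects models are fit by maximum likelihood (statsmodels MixedLM,
L-BFGS); model R² is reported as the squared correlation between fitted
values (including random effects) and observations. When the
random-intercept variance collapses to the boundary the ML Hessian can be
singular; the fit then degenerates to pooled OLS with zero random-effect
variance and is flagged `singular` rather than hidden. The hierarchical
bootstrap refits the model for every (left-out subject × trial count
4–8 × 5 random per-subject trial selections) cell, with selection seeds
derived from the cell coordinates. Residual diagnostics report the
Shapiro-Wilk normality test and the correlation of absolute residuals with
fitted values as a homoscedasticity check.

## Correlates

Signature shifts (self-selected → extreme slow, self-selected → extreme
fast; extremes are the subject's minimum/maximum grid speeds, the SS trial
is the grid point nearest the subject's self-selected speed) are Euclidean
distances in the 3D map by default. The balance/SS-speed block runs at
α = 0.05; the ten spatiotemporal-delta tests per condition pair run at the
Bonferroni-corrected α = 0.005. A spatiotemporal delta that is exactly
constant across subjects (step width, by construction) is reported as a
null result (r = 0, p = 1) rather than an error. All correlations are
two-sided and reported regardless of significance.

## Numerical and design choices

- Filtering: zero-phase 4th-order Butterworth; kinematic channels at 6 Hz,
  kinetic at 30 Hz; both cutoffs well below the 50 Hz Nyquist limit.
- Downsampling: FIR anti-alias filter + decimation, integer factors only.
- Event detection: 20 N threshold, crossings merged within 20% of the
  median stride; at least 3 right strides required.
- 0-based sample indexing; half-open stride intervals avoid
  double-counting boundary samples in phase averaging.
- Body-weight normalization uses g = 9.81 m/s².
- The 26-variable discrete set is defined as per-side
  {peak, minimum, excursion} of hip/knee/ankle sagittal angles (18) plus
  per-side peak vertical GRF, peak propulsive GRF, peak ankle moment and
  peak ankle power (8).
- Seed hierarchy: a master seed derives the cohort seed (master) and model
  seed (master + 1); split seeds inside the identification experiment are
  the run numbers; bootstrap selection seeds derive from
  (master, subject index, k, replicate).

## Problem sizes

Tests and the acceptance script run the full chain on an 8-subject ×
6-speed cohort (20 s trials at 100 Hz, 18 channels, 64-unit model) — large
enough for all statistical structure to be estimable, small enough for
single-CPU runs in minutes. Mixed-model recovery uses the full 17 × 9
design simulated directly from the random-intercept model. Unit tests use
smaller cohorts still (2–5 subjects, 6–12 s).

## Known limitations

- The generator's linearity in speed is exact by construction; real gait
  shows mild nonlinearity near the walk-to-run transition.
- Identification accuracy on synthetic cohorts is driven by harmonic
  amplitude/phase differences and is typically higher than on real data at
  matched cohort sizes.
- The variance-explained curve uses the fixed linear readout; retraining a
  reduced model would give slightly different (not deterministic) curves.
- ML (not REML) estimation slightly biases random-effect SDs downward in
  small cohorts; the recovery tests account for this within their
  tolerances.
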