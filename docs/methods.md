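# Methods

This note documents the models, the synthetic study conditions, the numerical
choices and the known limits of the `gatingnet` package.

## Task structure and gating contrasts

The reference-back task crosses *Switching* (switch/nonswitch) × *Trial Type*
(reference/comparison) × *Matching* (match/mismatch).  Gate opening and gate
closing are the switch costs within reference and comparison trials
respectively, computed from the four Switching × Trial Type cell values of any
measure.  The contrast is linear, so it commutes with averaging; this is
verified by property tests.

The synthetic task generator draws frame colors i.i.d. with
P(reference) = 0.5 (the real task's trial ratio and block structure are
exposed as parameters, not fixed), labels switching from the previous trial's
frame, and drops each subject's first (unlabeled) trial.  Generation continues
until every cell holds exactly `trials_per_condition` trials, giving
deterministic cell counts.  All randomness flows from one seed through
`numpy.random.SeedSequence` spawning (per subject, per trial batch).

## Drift-diffusion model

Unit-diffusion Wiener process from `zr·a` with absorbing boundaries at 0
("mismatch") and `a` ("match"); `zr` is fixed at 0.5 and the inter-trial
variability parameters at zero, so each Switching × Trial Type cell has free
(a, v, t0).  Defaults for the synthetic cohort are the study-scale cell
means: switch a = 0.93, t0 = 356 ms; nonswitch a = 0.86, t0 = 332 ms; drift
0.09/0.01.

**Simulator.**  Euler–Maruyama with dt = 1e-4 s.  The first-passage
discretization bias scales with √dt (boundary overshoot); at 1e-4 the induced
bias on `a` is ≈ 0.01, well under the recovery tolerances.  Trials not
absorbed within 20 s of decision time are resampled and counted.

**Density.**  The first-passage density uses the standard small-time (image
sum) and large-time (eigenfunction) expansions with the per-time error-bound
rule choosing the cheaper branch; truncation targets an absolute error of
1e-4 on the scaled density.  The upper-boundary density is the lower-boundary
density under (v, zr) → (−v, 1−zr).  Quadrature of each boundary's density
reproduces the closed-form absorption probability to ~1e-9.

**Fitting.**  Nelder–Mead on (a, v, t0) with five seeded restarts;
out-of-bounds proposals (a ∉ (0.3, 3), v ∉ (−5, 5), t0 ∉ (0, min rt)) are
rejected by penalty.  The first start uses a = 1, a choice-fraction-based
drift guess and t0 = 0.85·min rt; restarts jitter all three.  Only correct
trials enter the likelihood, boundary-coded by the response ("match" → upper,
"mismatch" → lower).

**Drift coding.**  The behavioral generator is stimulus-coded: the drift sign
follows the match/mismatch ground truth.  The fit is response-coded with a
single v per cell, as in the boundary convention above.  At `zr = 0.5` the
correct-trial RT distribution is symmetric in the drift sign, so on
stimulus-coded cohorts the fitted v shrinks toward zero while a and t0 remain
identified — which is why fitted drift rates are expected to be small even
when the generating |v| is not.  Parameter-recovery benchmarks therefore use
the simulator's response-coded output directly, where all three parameters
including the sign of v are identified.

## Behavioral statistics

Outlier handling is two-level: within-subject trials outside mean ± k·SD of
RT are removed first (k = 2 by default; SD = 0 removes nothing), then
subjects whose mean RT or per-cell trial counts fall outside the group
mean ± k·SD are flagged for exclusion.  Trial-level trimming precedes the
subject-level rule, and both are logged so the alternative order can be
audited.

All ANOVA factors are 2-level and within-subject, so each effect is computed
from its per-subject contrast score; F is the squared one-sample t of those
scores, which is algebraically exact for 2-level designs (verified against an
independent repeated-measures ANOVA solver to 1e-8) and makes sphericity
correction unnecessary.  Effect sizes: partial eta squared
ηp² = F·df_num/(F·df_num + df_err), and the paired Cohen's d_z = t/√n — the
d_z convention is fixed because it is the one consistent with published
(t, d) pairs for this paradigm (e.g. 6.93/√61 = 0.887).

## Spectral analysis

Morlet wavelets with width 5.5 cycles and support of 3 Gaussian SDs per side
("width" read as cycles and "length" as SD units — the common toolbox
convention; both are parameters).  Frequencies 1–30 Hz in 0.5 Hz steps;
per-trial convolution power is averaged within condition, and samples where
the wavelet overruns the epoch are masked as missing (at 1 Hz the wavelet
exceeds the 4 s epoch entirely and the row is masked with a warning).
Decibel baseline normalization divides by the mean power in −200…0 ms per
condition, channel and frequency.  Band averages use inclusive edges (theta
4–7, alpha 8–12, beta 13–30 Hz); at the 0.5 Hz grid the 7.5 and 12.5 Hz bins
belong to no band.

The cluster-based permutation test thresholds the pointwise paired t two-sided
at α = 0.05, clusters suprathreshold neighbors of equal sign (adjacent time
samples within a channel; spatially adjacent channels at the same sample,
adjacency = distance below 1.5× the median nearest-neighbor spacing), scores
clusters by summed t, and builds the max-|cluster| null from within-subject
sign flips (conditions are within-subject, so sign flipping is the exact
exchangeability scheme).  Monte-Carlo p-values have floor 1/(n_perm+1).
Calibration on exchangeable null data keeps the familywise error rate inside
the binomial band around 0.05.

## Source reconstruction

A Hamming-windowed sinc FIR band-pass (order from the 3.3/transition-width
rule, applied forward-backward for zero phase) precedes beamforming.  The
LCMV filter is scalar/fixed-orientation with unit gain at each voxel's own
leadfield row; the sensor covariance averages single-trial covariances across
the appended conditions (the covariance of the trial average is available by
flag) and is regularized by 5% of the mean sensor variance.  The
switch − nonswitch source-power contrast is reduced to its top percentile *by
absolute value* — so suppression effects (alpha/beta decreases) remain
selectable — with ties broken by voxel index.  DBSCAN (min_pts = 2, eps
defaulting to 1.5× the grid spacing, which connects face/edge neighbors but
not diagonal-distant voxels) discards singleton noise voxels.  Cluster
signals are per-trial: the mean nonswitch signal is subtracted per voxel
before averaging over the cluster's voxels, then cropped to the half-open
window [−500, 1500) ms (512 samples at 256 Hz).

The synthetic leadfield is a distance-decaying gain (1/(1+d²)) from a regular
unit-spaced voxel grid to channels on an enclosing Fibonacci-lattice sphere;
the spherical montage gives depth sensitivity in every direction, which a
planar montage lacks.  It deliberately omits realistic head-model features
(BEM conductivities, dipole orientations), so passing recovery tests
demonstrate the algebra and the pipeline logic, not real-EEG localization
accuracy.

## Effective connectivity (nMVAR + ANN)

The model predicts each node's sample from the `p` past samples of all nodes
through an explicit linear path plus a one-hidden-layer tanh path (default
2·M·p hidden units).  Training is full-batch L-BFGS on one-step-ahead squared
error; the linear path is initialized at the ordinary-VAR least-squares
solution and left unpenalized, while the hidden path carries a weight decay
of 1e-2 and an O(1) init.  The best of 3 seeded restarts is kept.  Model
order is fixed at p = 10 for pipeline parity across subjects and conditions,
with AIC/BIC order selection available as a diagnostic (BIC is the
recommendation; AIC's weaker penalty never selects a smaller order).

Two identifiability safeguards matter and are deliberate design choices:

1. **Validation gating.**  A seeded 10% row holdout scores the trained
   network against the plain least-squares VAR; if the hidden path does not
   improve held-out error it is pruned, leaving exactly the VAR (nonlinear
   connectivity identically zero).  Without this, a flexible hidden path
   fits noise and reports spurious nonlinear coupling on purely linear data.
2. **Re-centering.**  tanh is locally linear, so the hidden path can absorb
   linear structure.  After training, the hidden path's best linear
   approximation over the training trajectory (OLS of its output on the
   embedded inputs) is folded into the linear weights; predictions are
   unchanged, but the residual path is purely nonlinear.  This makes the
   fLin/fNonLin split well defined.

Connectivity read-out: lC[i→j] is the mean over lags of the absolute linear
weight (j ← i); NC[i→j] is the mean over samples and lags of the absolute
partial derivative of the residual nonlinear path of node j with respect to
x_i(n−k).  The sensitivity definition is a documented stand-in validated by
limit behavior: on linear data NC vanishes, on square-coupled data the
planted direction dominates, and deleting the hidden layer reduces the model
to an ordinary VAR.  Matrices are stored source-row/target-column.
Normalization divides every lC (and independently every NC) in a subject's
band × condition set by the set's maximum, giving values in [0, 1] with at
least one exact 1; the operation is idempotent and order-preserving.

Benchmark problem sizes: 5-node random sparse stable VARs with T = 4000
samples, fit at p = 10 with 32 hidden units and 600 L-BFGS iterations (the
smaller hidden layer is ample for a linear target and keeps the 10-seed
battery to a few minutes); the square-coupling system is 3 nodes with a 0.4
gain square term, fit at p = 5 with 30 hidden units.

## Brain–behavior regression

One-hidden-layer (8 tanh units) network per DDM parameter, band and gating
process, trained by L-BFGS with a ridge penalty (α = 0.1) as capacity
control — at a few dozen subjects an inner early-stopping split would leave
too little data, so an explicit penalty plays that role.  Inputs are
standardized per training fold.  Normalized error = mean 10-fold CV MSE
divided by mean |target|; the 95% interval is the t-interval over normalized
fold errors, and two conditions differ significantly when their intervals do
not overlap.  The normalized error scales linearly (not quadratically) in the
target's scale; this is a property of the definition and is tested with a
bracket because network training is only approximately scale-equivariant.

The synthetic cohort for this stage couples the boundary-separation parameter
to the connectivity summaries (smooth function plus small noise at n = 60
subjects, the study's scale) while the drift rate is independent noise of
matching magnitude, so the expected result — a predicted well, v at its null
baseline, disjoint intervals — has a known ground truth.

## Pipeline

The orchestrated pipeline (simulate → behavior → ddm → tfr → permtest →
source → connectivity → regress) stamps every artifact with a hash of the
analysis configuration (output location excluded) and the master seed;
per-stage seeds derive from the master seed by hashing, so single stages are
independently reproducible and a re-run with the same seed is byte-identical.
Stage dependencies are validated before anything runs; completed stages can
be resumed.  In the pipeline's synthetic cohort each subject's source-coupling
gain shifts their boundary separation, so the final regression stage sees a
real a-to-connectivity link and a null v link — the full-pipeline smoke test
checks exactly this pattern qualitatively.

## Known limitations

- The synthetic data contain no artifacts, no 1/f background, no volume
  conduction beyond the toy leadfield, and no inter-subject anatomical
  variability; tests certify the estimators' internal correctness, not their
  behavior on real EEG.
- The response-coded single-drift DDM fit is the paradigm's convention, and
  on stimulus-coded data it attenuates |v| by design (see above).
- Connectivity is constant over the analysis window; time-varying coupling is
  out of scope.
- The nonlinear-connectivity definition is sensitivity-based; other
  attributions (e.g., integrated gradients) would differ numerically though
  not in the tested limits.
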