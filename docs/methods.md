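# Methods

## Problem and pipeline

The package addresses group-difference detection in functional brain
networks under a three-arm design: saline control, low-dose and high-dose
nicotine exposure.  Each subject contributes a region-by-region Pearson
correlation matrix (the functional connectome) computed from regional fMRI
time series.  The pipeline has four stages:

1. **Connectome construction** — sample Pearson correlation between region
   time series; symmetry, unit diagonal and the [-1, 1] range are enforced
   exactly.  Columns with standard deviation below 1e-12 are rejected
   rather than silently producing NaN.
2. **Per-group generative modelling** — an independent denoising diffusion
   probabilistic model (DDPM) per group over the vectorized upper triangle.
3. **Reconstruction-error classification** — partial noising plus reverse
   denoising under each group's model; assignment to the best-reconstructing
   group.
4. **Edge/region difference ranking** — absolute difference of group-mean
   networks, aggregated to regions by incidence sums.

## Modelling scale

Correlations are bounded in [-1, 1] while the DDPM adds unbounded Gaussian
noise, so matrices are mapped to the Fisher z scale (atanh, with inputs
clipped to |r| <= 1 - 1e-7) before modelling and mapped back (tanh, clipped,
diagonal restored) afterwards.  Group means are likewise taken on the z
scale.  `transform: none` switches to raw correlations for comparison.

## Diffusion model

* **Schedule.**  Steps are numbered 1..T with abar_t = prod_{s<=t}(1-beta_s).
  Default: linear beta from 1e-4 to 0.02 over T=1000, the canonical DDPM
  choice; a squared-cosine schedule is available.  Package-level experiments
  and the bundled pipeline run at T=200, which is ample for these
  low-dimensional vectors.
* **Reverse variance** is fixed to beta_t (not learned), consistent with
  training on the simplified noise-prediction loss.
* **Noise predictor.**  eps_theta is a fully connected residual network
  (default width 128, two hidden blocks, SiLU activations) on the
  upper-triangle vector, with a 32-dimensional sinusoidal time embedding,
  implemented directly in numpy (forward pass, backpropagation, Adam).
  Connectivity matrices are dense, fixed-size objects of modest dimension
  (45 entries for the 10-region test scale, 11 175 at the 150-region atlas
  scale), so an MLP is the minimal faithful architecture and trains in
  seconds on one CPU.
* **Denoised-signal head.**  The network outputs an estimate f(x_t, t) of
  x_0 and the noise prediction is recovered analytically,
  eps_theta = (x_t - sqrt(abar_t) f)/sqrt(1 - abar_t).  This is an exact
  reparameterization — training minimizes the standard noise MSE — but it
  removes the 1/sqrt(1-abar_t) steepness of the small-t noise map.  A plain
  eps-output MLP cannot represent that near-singular linear map, which we
  measured to bias ancestral sampling by ~0.13 (z scale) on a point-mass
  target; with the head the bias is below 0.01.
* **Optimization.**  Adam at learning rate 0.001 (the pipeline's standard
  setting) for 1000 epochs by default (300 at the test scale), minibatch 16,
  t drawn uniformly in [1, T] and fresh standard-normal noise each step.
  Gradients are clipped to global norm 1.0: with the denoised-signal head
  the per-sample loss weight is abar/(1-abar), up to 1e4 at t=1, and the
  resulting heavy-tailed gradients otherwise destabilize Adam at some seeds.
  Training is fully deterministic given the config seed.
* **Loss reporting.**  `loss_history` holds the loss on a fixed (t, eps)
  evaluation set drawn once before training, one value per epoch.  Raw
  minibatch epoch means are not comparable across epochs because the
  noise-prediction error varies by orders of magnitude in t.
* **Variational bound.**  A Monte-Carlo estimate of the negative
  variational lower bound (prior KL + per-step posterior KLs + step-1
  reconstruction term) is provided as a diagnostic only.

## Classification

A subject is scored against group g by noising its z-vector to
t_noise = T/4 (default; enough noise to engage the learned prior while
preserving subject identity) and denoising back to step 0, repeated
n_repeats = 8 times with common random numbers across groups — the same
repeat uses the same noise for every candidate group, so error differences
are not inflated by independent sampling noise.  The score is the mean
squared error on the z scale; the predicted group is the argmin, with ties
broken in fixed order saline < low < high.  A logistic-regression baseline
on upper-triangle features is included for comparison.  The classifier
mechanism itself is this package's design choice: it uses only machinery the
generative model already provides.

## Detection

Edge score: |A_ij - B_ij| between the two group-mean networks (means on the
z scale); an optional per-edge Welch t statistic across individual matrices
is available.  Region score: sum of incident edge scores — consistent with
the observed coupling between strong regions and strong connections.
Outputs are deterministically ordered (descending score, lexicographic
tie-break), with defaults of 20 edges and 15 regions per comparison,
matching the lengths of the package's reporting tables.  The edge-score
threshold defaults to the 99th percentile of the score distribution and is
user-overridable.  Both detection paths are supported: empirical group means
of observed matrices ("oracle" path), and means of matrices sampled from the
trained models (full generative path).

## Synthetic cohorts

The generator emulates the three-group design with known ground truth:

* base correlation: block structure (blocks of 5 regions at r = 0.3,
  zero between blocks) — a coarse stand-in for modular brain organisation;
* planted effects: 10 randomly placed upper-triangle edges shifted by
  delta-r = 0.4 (high group) and 0.2 (low group), then projected to the
  nearest positive-definite correlation matrix (eigenvalue clipping at 1e-6
  plus diagonal renormalization, iterated to convergence);
* subject variability: symmetric Gaussian jitter of the group matrix
  (sigma_subj = 0.05, re-projected to a valid correlation) plus
  finite-sample Pearson noise from 200 i.i.d. multivariate-normal
  timepoints;
* standard test scale: 10 regions, 40 subjects per group (plus 30 held-out
  for classification), chosen so the full pipeline runs in seconds; the
  150-region atlas scale is used for output-shape checks and demos.

What the generator does **not** emulate: temporal autocorrelation of BOLD
signals (rows are i.i.d.), hemodynamics, scanner artefacts, motion, or
realistic anatomical covariance structure.  Passing tests therefore show
the method recovers planted covariance differences under idealized noise,
not that it would do so at real-data effect sizes.

## Numerical choices

* Pearson values within 1e-12 of +/-1 are snapped to exactly +/-1 (float
  residue of perfectly correlated columns).
* Text formats carry 12 significant digits; round-trips are exact to that
  precision.  Matrix files symmetrize on read to absorb text quantization.
* Reconstruction at t_noise = 0 is the identity by definition.
* The forward-marginal test checks the pooled scalar mean and variance at 3
  Monte-Carlo standard errors (the marginal is isotropic, so these are the
  sufficient summaries) and every coordinate at the familywise-equivalent
  bound 4.65; a literal per-coordinate 3-SE test over 270 simultaneous
  z-scores would fail about half the time for a correct implementation.
* Seeds: every stochastic operation takes an explicit seed; derived seeds
  stay below 2^31.

## Known limitations

* One model per group; a single conditional model across groups is not
  implemented.
* Ancestral DDPM sampling only (no DDIM-style acceleration, no learned
  variances, no guidance).
* The noise predictor is an MLP; a graph-structured predictor could exploit
  the network topology but is out of scope.
* No statistical significance or multiple-testing control on edge scores —
  rankings are descriptive, mirroring the detector's design.
* The atlas ships with 33 named regions (those appearing in the reporting
  tables); remaining indices carry placeholder labels, and node coordinates
  for surface rendering are zero-filled unless supplied.
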