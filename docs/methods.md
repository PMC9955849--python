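# Methods

## The model and its assumptions

`fallwatch` classifies human posture from the trajectory of a detected
bounding box.  The modeling chain is:

1. **Centroid features.**  Each box becomes a centroid (x, y) in normalized
   image coordinates (origin top-left, y downward, both axes divided by the
   frame dimensions so different cameras share a scale) plus speeds
   (vx, vy) by first-order backward difference scaled by the frame rate.
   No smoothing is applied; a stream's first sample has zero speed.
2. **Windows.**  Features are grouped into sliding windows of 21
   consecutive frames, dated by their first sample.  Windows spanning a
   detection gap larger than two frame intervals are dropped.  The default
   stride is 1.
3. **Attention.**  Within a window, each frame's 4-vector f(t) is gated by
   c(t) = 4·softmax(G f(t) + b) — the rescaling by 4 makes the uniform gate
   an identity multiplier — combined as c(t) ⊙ f(t) + f(t) (a residual
   add), mean-pooled over the 21 frames, and linearly projected to a 2-D
   sample s.  The gating is per-time-point only; there is no cross-time
   attention.  The output dimension of 2 keeps the feature space fully
   visualizable as maps.
4. **Variational mixture.**  Samples follow a K-component Gaussian mixture
   with latent parameters: weights α ~ Dirichlet(D), means
   μ_k ~ N(N1_k, diag(N2_k²)), precisions Λ_k ~ Wishart(W1_k, W2_k).
   Priors: N(0, 1) per mean coordinate, Wishart(3, I/3) on precisions
   (ν = 3 > d − 1 for d = 2; I is the 2×2 identity of the feature space),
   and a symmetric Dirichlet on the weights with concentration 2/K per
   component (a weakly informative default; the literal concentration 2K is
   selectable via `dirichlet_interpretation="2K"`).
5. **Loss.**  The negative Monte-Carlo evidence lower bound
   −((1/L) Σ_l mean_i log p(s_i|θ_l) − kld_scale·KL(q‖p)), with the KL term
   a sum of closed-form Gaussian, Wishart and Dirichlet divergences.  Since
   KL ≥ 0 the loss is bounded below by the negative Monte-Carlo likelihood
   term.
6. **Posterior and alarms.**  Responsibilities
   r_k(s) = α_k N(s|μ_k, Σ_k)/Σ_j α_j N(s|μ_j, Σ_j) tag each sample with
   the region of its winning cluster (ties to the lowest index).  A state
   machine escalates to Warning1 (transition region) or Warning2 (falling
   region) after `persistence` consecutive confident classifications, and
   de-escalates under the same rule; samples whose winning responsibility
   is below `threshold` are "uncertain" and freeze the counter.

Cluster identity is assigned *after* training by majority vote of labeled
training windows per cluster, with ties resolved toward the more severe
label; a cluster that captured no labeled points falls back to the most
severe label seen (a cautious default for an alarm system).

## Reparameterized sampling

Gradients must flow through the Monte-Carlo likelihood term, so all draws
are pathwise:

* **Means** use the location-scale transform N1 + N2 ⊙ ε.
* **Precisions** use a Bartlett factorization Λ = (L_W A)(L_W A)^T with
  L_W the Cholesky factor of W2 and A lower-triangular.  The chi-square
  diagonal entries of A are replaced by moment-matched log-normal
  surrogates, c = a·exp(σZ − σ²/2) with σ² = log(1 + 2/a), which match the
  chi-square mean and variance exactly and are differentiable in the
  degrees of freedom (an exact chi-square path is not).  Consequently
  E[Λ] = W1·W2 holds exactly; higher moments are approximate.
* **Weights** use normalized Gamma surrogates of the same log-normal form
  (σ² = log(1 + 1/D_k)), matching the Gamma mean and variance.

In diagonal covariance mode the off-diagonal Bartlett noise and the
off-diagonal entry of L_W are both zero, so sampled precisions are exactly
diagonal (independent per-axis Gamma precisions).

One parameter draw is shared by the whole minibatch per Monte-Carlo sample
(per-batch sampling), which keeps the estimator cheap and the variance
adequate at the default L = 10.

## Training

All constrained quantities live on unconstrained scales: log for N2 and the
W1 offset (W1 = d − 1 + e^w), the Cholesky factor for W2, softplus for D.
Positive-definiteness is therefore structural, never projected.

Optimization is minibatch SGD with momentum on a small built-in
reverse-mode tape (`fallwatch._tape`), whose vector-Jacobian products are
validated against central finite differences in the test suite.  Defaults:
batch 64, step size 1e-2, momentum 0.9, 2000 steps, L = 10 draws.
Numerical choices that matter:

* **KL scaling.**  `svi_loss` defaults to the literal form with the KL term
  at full weight (`kld_scale=1.0`), which is the right object for loss
  identities and unit analysis.  `svi_fit` defaults to `kld_scale="auto"` =
  1/N, charging the KL once per dataset — the standard stochastic
  variational scaling.  With the full-weight reading, the unit-scale priors
  would shrink recovered means by 10–20% on unit-scale clusters; with 1/N
  the fit approaches maximum likelihood as N grows while retaining the
  prior's regularization against degenerate components on small data.
* **Initialization.**  k-means (scikit-learn) on up to 4096 samples seeds
  the cluster means; per-cluster sample covariances seed W2 through
  W2 = Σ̂⁻¹/W1 so the Wishart mean matches; cluster fractions seed D; N2
  starts at 5% of the global feature scale.  `init="prior"` starts exactly
  at the prior (KL = 0), useful for diagnostics.
* **Gradient clipping.**  Each parameter tensor's gradient norm is capped
  (default 10).  Early steps occasionally see very large curvature when a
  sampled precision lands far from the data scale; clipping converts those
  into bounded steps instead of divergence.
* **Attention step scale.**  The attention block trains at
  `step_size × 1e-3`.  The mixture density is invariant under any affine
  reparameterization of a linear feature map (the log-determinant term
  compensates), so the joint objective has an exactly flat direction along
  which minibatch noise plus momentum performs a random walk.  Rarely
  reinforced clusters cannot track a fast-drifting feature space and
  collapse; slowing the feature extractor relative to the mixture removes
  the failure while keeping both jointly trained.
* **Channel standardization.**  The end-to-end pipeline z-scores the four
  window channels (statistics from training windows only, stored with the
  model) before the attention block.  Positions are bounded in [0,1] while
  speeds scale with the frame rate; a fixed-step optimizer needs the
  mixture's inputs on a common O(1) scale.
* **Determinism.**  All randomness (batches, draws, k-means seeding)
  derives from one `numpy` generator; float64 single-threaded execution
  makes reruns with the same seed bit-identical.
* **Empirical-Bayes refresh.**  Optionally (`empirical_bayes_every=k`,
  off by default) the prior is replaced every k steps by the current
  variational summary, letting sequentially collected data gradually
  re-center p(z); with it on, the KL term decays toward zero during
  training.

Divergence (a non-finite loss) raises an error naming the step.

## Maps

Likelihood and region maps are rendered at 200×200 by default on the
min-max-normalized unit square (the normalization record is fitted on
training features only, and refuses to be applied twice).  The mixture is
pushed through the min-max transform analytically (affine map of means and
covariances); responsibilities — and therefore region maps and alarms — are
invariant under that transform, so alarms run in raw feature space while
maps are drawn normalized.  Covariance ellipses come from the
eigendecomposition of each component covariance, with semi-axes
n_std·√eigenvalue and the rotation of the leading eigenvector.

## The synthetic generator

The generator emulates the monitoring protocol the classifier targets:
walking (constant-velocity centroid with a small vertical gait bob at
1.9 Hz), ~30 s of in-place rotation (stationary centroid with postural
sway; box width oscillates as the body turns), then a fall onto a mattress,
rendered as 60 FPS bounding-box streams from cameras mounted at 1.6 m and
3.1 m.  Camera height scales the box by perspective
(size ∝ 1/camera-subject distance) and shifts the standing centroid row
only slightly, since cameras are tilted to center the subject.  Subject
heights are drawn from N(1.586 m, 0.143 m), the cohort statistics of the
protocol.  Detection jitter is additive Gaussian noise (default 2 px) on
every box corner.

The fall is a piecewise-quadratic template over 0.7 s: constant-acceleration
drop covering 80% of the centroid descent in 80% of the phase (mattress
contact), then a constant-deceleration settle to rest with a continuous
velocity profile.  `impact_time` is annotated at the fall/rest boundary —
the body at rest on the mattress — so mattress contact precedes it by the
settle (~0.14 s).  Per-frame labels: `transition` for the 40 frames before
impact (the pre-impact transit; configurable), `falling` from impact on,
`normal` elsewhere.

What the generator does *not* emulate: limb articulation and pose within
the box, detector dropouts and identity switches, multiple people,
occlusion, lens distortion, lighting.  Its classes are also cleaner and
more stereotyped than real falls, so the pipeline's high held-out accuracy
(~0.99) on synthetic cohorts is an upper bound on, not a prediction of,
real-world performance; the tests establish that the machinery is correct
and that the qualitative orderings (full > diagonal covariance, K=3 > K=2,
alarms ahead of impact) hold under realistic geometry and noise, not that a
deployed system would reach these numbers.

A note on speeds and noise: at 60 FPS, per-frame backward-difference speeds
amplify corner jitter (2 px of jitter is ~0.25 units/s of vy noise, the
same order as a fall's peak vy), so per-frame speed properties of the
template are only meaningful at zero noise.  The 21-frame window mean —
which is what the classifier consumes — telescopes the differences and
suppresses this noise by a factor of ~21.

## Evaluation choices

Per-window predictions are compared to the ground-truth label at the
window's anchor frame.  Confusion counts binarize alert-centrically
(transition and falling are positive) by default; accuracy is
(TP+TN)/total, rounded to two decimals only for display.  Model comparison
fits each (K, covariance) variant with a shared seed and reports held-out
mean log-likelihood under the expected mixture
(μ_k = N1_k, Σ_k = (W1_k W2_k)⁻¹, α = D/ΣD).

## Problem sizes

The shipped tests and the acceptance script use: n = 3000 for the EM
agreement check, n = 5000 for parameter recovery, 3000/1000 train/test
points for model ordering, a 15-subject × 2-camera cohort (~82k windows;
10 subjects train, 5 test) for the end-to-end pipeline, and 20 noise seeds
for alarm timing.  These sizes give stable statistics for every quantity
reported while keeping a full run in the minutes range on one CPU.

## Known limitations

* The attention block is a per-frame feature gate; it cannot express
  cross-time dependencies beyond what mean pooling captures.
* The Wishart/Gamma log-normal surrogates bias higher moments of the
  draws; parameter recovery and the EM cross-check bound the practical
  effect, but the sampled posterior is not exactly the named distribution.
* Fixed-step SGD with momentum was chosen for transparency; an adaptive
  optimizer would tolerate wider feature scalings without the channel
  standardization step.
* One subject per scene; no tracking or association logic.
* K is fixed by configuration (2 or 3 studied); no automatic selection.
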