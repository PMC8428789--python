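# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `lungpf`, and what the synthetic test conditions do and do
not demonstrate.

## State model

The latent diagnostic state `u ∈ [0, 1]` moves between screenings under the
exponential-power kernel `p(u_k | u_{k-1}) ∝ exp(−|Δ|^α / α)` restricted to
the unit interval.

Two properties of this kernel family matter in practice:

- **It is weakly informative for every α.** Its characteristic scale is of
  order one on [0, 1]: at the default `α = 0.1` the kernel is nearly uniform
  apart from a spike at Δ = 0 of negligible mass (< 1e−10); at large α it is
  a plateau that only falls off near |Δ| = 1. The filter's information
  therefore comes almost entirely from the measurement likelihood, and the
  transition prior contributes only a mild pull toward the previous
  interval's posterior.
- **Naive rejection sampling is infeasible at small α.** The kernel's mean
  value on [0, 1] at `α = 0.1` is ≈ 2e−4, so a uniform-proposal/unit-envelope
  rejection sampler accepts ~1 in 5000 proposals. Instead we sample exactly
  through a transform: with `y = |Δ|^α`, the jump magnitude's law is
  Gamma(1/α, scale = α) truncated to y ∈ [0, 1], inverted via the gamma ppf;
  the sign is symmetric, and proposals leaving [0, 1] are redrawn, which
  realizes the restriction (truncation) of the kernel without distorting its
  shape. The sampler was validated against an adaptive-quadrature CDF
  (Kolmogorov–Smirnov p = 0.72 at n = 5000) and is covered by a chi-square
  goodness-of-fit test at n = 100 000.

`α` is configurable (`FilterConfig.alpha`, default 0.1, dimensionless). The
initial state at the first screening is drawn uniform on [0, 1] — an
uninformative choice, since nothing earlier than the first reading is
observed.

## Likelihood design

The two diagnostic polynomials (quartic-plus-log in SVR and sum entropy for
benign/malignant; linear in the five stage features) are hard-coded with
their published coefficients and are never refit. The combined likelihood
gates on SVR and SE: both at or above their thresholds `(Ta, Tb)` selects
the stage polynomial, anything else the benign/malignant one. Notes:

- The gate follows the empirical observation that SVR and SE sit above
  threshold for malignant nodules, so above-threshold features are scored
  with the *stage* likelihood. (The case pairing is sometimes typeset the
  other way round in secondary material; the prose meaning is implemented.)
- Mixed outcomes (exactly one gate feature above threshold) default to the
  conservative benign branch; `LikelihoodConfig.mixed_to_stage` flips this.
- `Ta`, `Tb` have no published numeric values; the defaults
  (`Ta = −0.08767…`, `Tb = 1.0`) are calibrated against the synthetic
  generator: `Ta` is the SVR at which the benign/malignant polynomial
  crosses 0.51 on its first ascending branch holding SE at the generator's
  malignant level (1.25), and `Tb` separates the generator's benign (0.8)
  and malignant (1.25) SE levels. Real data would need recalibrated gates.
- Scores ≥ 0.70 classify as advanced-stage; values above the stated 0.90
  upper edge of that range are clamped into advanced-stage with a logged
  warning (the range's upper edge is treated as descriptive, not as a cap of
  the likelihood model).
- The z4/z5 (LDHGLE, cluster prominence) stage terms have coefficients of
  order 1e−7 and may be dropped (`drop_small_terms`); the default keeps
  them.

## Measurement model

Each feature is an independent order-M polynomial in `u`, fit by ordinary
least squares (numpy's SVD-backed `polyfit` — stable on [0, 1] at M = 3–4,
unlike normal equations). M defaults to 3, the order found to classify best
(M = 2 underestimates malignant scores; M = 4 adds nothing). The per-feature
residual standard deviation is recorded as the measurement-noise scale.
Fitting requires at least M + 1 distinct states; exactly M + 1 means exact
interpolation and a recorded noise of zero.

## Particle filter

Bootstrap SIR with `Ns = 4000` particles: the importance density is the
transition prior, so weights reduce to the likelihood kernel. The "closeness
of likelihoods" weighting is a Gaussian kernel on the difference between the
combined likelihood of the model-predicted features at each particle and
that of the observed features, width `sigma_w = 0.05` (dimensionless, on the
likelihood scale; smooth, symmetric, maximal at zero discrepancy). Each of
the two likelihood evaluations applies the threshold gate to its own feature
vector. Degenerate all-zero weight vectors (kernel underflow) reset to
uniform with a logged warning rather than aborting a batch.

Resampling is systematic (single uniform offset) and, by default,
unconditional after every update (`ess_fraction = 1.0`); an ESS-triggered
mode (`ess_fraction < 1`) is available. The posterior mean estimate (PME)
is recorded *before* resampling.

The outer convergence loop re-runs the whole K-interval sweep with a fresh
deterministic sub-stream of the master seed (nothing else varies between
iterations besides Monte-Carlo randomness) until the mean squared change of
the PME sequence is ≤ `ξ = 1e−4`, cap 50 iterations; with Ns = 4000 the
second sweep almost always converges. Non-convergence is flagged on the
result, not raised. Identical configuration and seed give bitwise-identical
results.

## Grid-Bayes oracle

`grid_posterior` discretizes `u` onto `n_grid` uniform points and applies
the exact predict/update recursion with the same likelihood kernel. The
transition matrix is **cell-integrated** (per destination cell, via the
closed-form magnitude CDF), not pointwise-evaluated: at small α the kernel's
Δ = 0 spike has height 1 but negligible mass, and a pointwise diagonal would
absorb ~90 % of each column's mass, which is a discretization artifact. With
cell integration the particle filter and the oracle agree to ≤ 0.004 in PME
at Ns = 4000 (tolerance budget 0.02), and the deviation scales as 1/√Ns.

## Synthetic cohort generator

The generator inverse-solves the likelihood polynomials so that, noise-free,
`combined_likelihood(features(u)) = u` exactly:

- **SVR** inverts the benign/malignant quartic on its first ascending branch
  (bracket [−0.3, 0.2612], Brent's method, xtol 1e−12) in *both* regimes, so
  `svr(u)` is smooth and increasing across the gate; benign values are
  negative (features enter the polynomials on a normalized scale where the
  cohort mean is near zero).
- **SE** is a two-level constant: 0.8 (benign regime) / 1.25 (malignant),
  straddling `Tb`. Its likelihood contribution is the small log term, so the
  step contributes < 0.002 to any score.
- **Sphericity** carries the stage information: the stage polynomial is
  solved in closed form for `z3`, whose coefficient (−1.1348) is the only
  stage coefficient of magnitude > 1 — small-area emphasis (coefficient
  0.3917) cannot span the required score range within its (0, 1] domain.
  Benign states continue the same linear-in-u expression, making `z3(u)`
  globally linear (hence exactly representable by the cubic measurement
  model). Sphericity decreasing in malignancy also matches the morphology of
  progressing nodules.
- **SAE and strength** are class-typical constants (0.5, 73.0); **LDHGLE and
  cluster prominence** are 0 (their stage coefficients are negligible) but
  keep their columns in all I/O.
- Gaussian noise of sd `feature_noise_sd` (default 0.01) is added per
  feature, re-clipped to valid domains.

Ground-truth state paths: benign nodules stay flat at their target score;
malignant nodules ramp linearly from 0.08 to the target over the K
intervals, with truncated-Gaussian jitter (sd `state_noise_sd`, default
0.01) on interior points. Final-state targets are drawn uniformly from
per-class ranges — [0.05, 0.45], [0.52, 0.68], [0.72, 0.88] — insets of the
diagnostic ranges so measurement noise cannot straddle a class boundary.
Default cohort composition is 70 benign / 70 early / 60 advanced, matching
the screening cohort the method was designed around; the recovery studies in
the test suite use a 20/20/20 cohort and a 500-pair training set, sizes
chosen to exercise every class while keeping the full pipeline fast.

What the generator does **not** emulate: real marginal feature
distributions, inter-feature correlation, scanner effects, or any benign
feature dynamics beyond flat-low states. Passing tests demonstrate that the
inversion machinery recovers states that are *consistent with the likelihood
model*; they say nothing about the likelihood model's fit to real nodules.

## Numerical behaviour worth knowing

- The order-3 fit of the quartic-inverse SVR curve leaves a small systematic
  distortion: the combined likelihood of predicted features tracks `u`
  within 0.02 over the operating range [0.05, 0.95], degrading to ≤ 0.05 at
  the `u = 0` edge, which cohort states never reach.
- Near the 0.51 benign/early boundary the PME carries a ≈ 0.02 downward bias
  (fit distortion plus the transition prior's pull toward the previous,
  lower state on ramp paths), so early-stage nodules whose true final score
  is within ~0.02 of 0.51 can be labelled benign. This is a property of the
  method at these settings, visible in the worked example's confusion
  matrix.
- Natural cubic splines (the densification of three annual readings to five
  half-yearly points) can overshoot monotone data by up to 3/32 of the data
  range; midpoints leaving a feature's valid domain are clipped to it with a
  warning (relevant for strictly-positive sum entropy).
- One-vs-rest AUC on the final score is uninformative for the *middle*
  (early-stage) class: a single threshold on a monotone score cannot isolate
  a middle interval.

## Limitations

- No real imaging data or extracted-feature dataset is included or fitted;
  gate thresholds and generator constants would need recalibration on real
  cohorts.
- The filter processes exactly K = 5 intervals; online arrival of further
  screenings, smoothing, and auxiliary/Rao-Blackwellized variants are out of
  scope.
- α is shared between benign and malignant dynamics; per-class or
  per-patient transition parameters are not modelled.
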