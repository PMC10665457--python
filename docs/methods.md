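# Methods

This note documents the models implemented in `motionbayes`, the choices
made where the design was genuinely open, and what the synthetic-data
experiments do and do not establish.

## The observer model

A stimulus moving in direction `s` (degrees on the full circle) elicits two
noisy internal measurements: a velocity measurement `x_V ~ VM(s, κ_V)` in
the 360° direction space, and a spatial-orientation measurement — the
"motion streak" left by temporal integration — `x_O`, built by adding
`VM(0, κ_O)` noise to `s` on the full circle and wrapping into the 180°
orientation space.  `VM(μ, κ)` is the von Mises distribution; the circular
standard deviation corresponding to κ is `σ = sqrt(-2 ln(I₁(κ)/I₀(κ)))`
(converted to degrees at all public interfaces; `sigma_to_kappa` inverts
this by bracketed root finding).

With a flat prior, the posterior over direction is proportional to the
product of the velocity likelihood (a von Mises at `x_V`) and the
orientation likelihood (equal von Mises peaks at `x_O` and `x_O + 180°`,
because a streak is consistent with two opposite directions).  The product
collapses analytically to a **two-component von Mises mixture**: each
component's location and concentration follow from resultant-vector
addition of the two constituent von Mises terms, and the component weights
are proportional to `I₀(κ_component)` normalizers, evaluated in log space
with scaled Bessel functions (`scipy.special.ive`) so that concentrations
up to ~1e8 are handled without overflow.  Component A is by convention the
one nearer `x_V`.  A grid-evaluation oracle (normalizing the brute-force
likelihood product on the 0.5° grid) verifies the analytic mixture to
1e-8 sup-norm in the tests.

Readouts:

* **MAP readout** — argmax of the mixture on a uniform 0.5° grid (720 bins,
  centers at 0, 0.5, …; ties break to the smallest canonical angle).
* **velocity-only readout** — `x_V` itself (the velocity posterior's mode).

When velocity noise is low, the distribution of MAP estimates across
trials is approximately `VM(s, κ_V + κ_O)`; `map_distribution_approx`
returns this approximation and warns when the posterior's secondary weight
makes it invalid.

Uncertainty is the Shannon entropy of the grid-evaluated posterior, in
bits.  Absolute entropy depends on the bin count (uniform = log₂ 720 ≈
9.49 bits on the default grid), so only entropy differences and orderings
are treated as meaningful.

## Simulation conditions

* **Noise grid** — σ_V, σ_O ∈ {3, 5, 10, 20, 30, 40, 60, 100}°, 10,000
  trials per cell, stimulus fixed at 0° (the model is equivariant, so all
  quantities are relative angles).  Per cell we store the across-trial mean
  posterior, mean entropies for both observers, and the MAP-response
  sample.
* **fMRI-matched regime** — trial-wise κ_V, κ_O drawn independently from a
  log-normal with natural-log parameters μ = 3.8, σ = 0.6; measurement
  (MRI) noise precisions κ′_V ~ LogNormal(0.9, 1.1) and κ′_O ~
  LogNormal(1.4, 0.7).  Behavioral responses are read out from the *neural*
  posterior; the *decoded* posterior uses the offset measurements
  `x + x'` with `x' ~ VM(0, κ')`.

**Decoded-likelihood width.**  For cascaded noise the concentration of
`x + x'` about `s` is *not* `κ + κ'`: precisions of sequential
corruptions do not add (adding them is correct only for independent
parallel measurements).  The implemented width uses the von Mises
convolution identity — resultant lengths multiply, `A(κ_eff) =
A(κ)·A(κ')` — so `κ_eff ≈ κ'` when the measurement noise dominates.
This choice (option `width="mri"`, the default) is what produces the
characteristic joint distribution of fitted peak locations with unimodal,
bimodal and flipped configurations, and a majority of decoded posteriors
with a visible secondary component; the additive-precision variant is
retained as `width="combined"` for comparison but yields decoded
posteriors as concentrated as the neural ones, whose secondary component
(weight ~e^-80) is numerically invisible.

**Known limitation.**  Under these printed noise parameters the fraction
of "flipped" trials (larger fitted component at the opposite direction,
smaller at the true direction) is governed by the probability that the
velocity measurement-noise offset exceeds 90°, which averages ~10% over
the κ′_V log-normal.  The pipeline reports the fraction it actually
computes.  Relatedly, the large velocity offsets dilute the coupling
between the decoded second peak's location and the behavioral error for
the MAP readout: the first-peak slope and the velocity-only sign reversal
are clear, while the MAP second-peak slope is positive but small relative
to its permutation null.

### Mean-posterior bimodality detection

A cell's across-trial mean posterior is classified as bimodal when its
density at the opposite direction (primary mode + 180°) is at least 2% of
the density at the primary mode.  A strict local-maximum test is not
usable at the boundary: exact quadrature over the measurement
distributions shows that at σ_V = 40°, σ_O = 30° the expected mean
posterior carries clearly localized mass at 180° (3.5% relative density)
but as a perfectly flat shoulder with zero prominence, while σ_V = 30°,
σ_O = 3° has a genuine but tiny local maximum (0.9% relative).  The 2%
relative-height rule was fixed from that noise-free boundary analysis and
separates the regimes with a factor-of-two margin on both sides.

The secondary peak's *location* is read from a lapse-free two-component
mixture fit when its smaller component lands within 45° of the opposite
direction; on flat-shoulder cells, where the uniform lapse is degenerate
with a broad opposite component (it can absorb the entire shoulder) and
even a lapse-free fit represents the shoulder as a near-uniform component
with unidentified location, the location falls back to the
density-weighted circular centroid of the ±45° opposite window — an
unbiased estimate because the generative model is symmetric about the
stimulus.

## Descriptive mixture fitting

Trial-level posterior shape is quantified with a mixture of two von Mises
components plus a circular-uniform lapse, fitted by minimizing the
Jensen–Shannon divergence (base 2) between the posterior and the mixture
on the grid.  Bounds: κ ∈ [0.001, 100], α ∈ [1e-5, 1-1e-5], lapse ∈
[0, 0.9].  Optimization is bounded L-BFGS-B with an analytic JSD gradient
(chain rule through the normalization and the von Mises density partials;
verified against finite differences), from 100 random restarts by default
plus data-driven starts built from the posterior's own peaks (including a
co-located pair, which is the natural description of a single bump's peak
and shoulder).  Restart dispersion — the circular SD of component
locations across solutions within 5% of the best JSD — flags trials whose
description is not unique.  Since JSD ≥ 0, a restart reaching ≤ 1e-10 is a
global optimum and terminates the restart loop early.

For large simulation batches where each posterior is an *exact* mixture
with known analytic parameters, those parameters seed one optimizer start
and the restart count is reduced to 2; this is a runtime choice (the
analytic start converges to the global optimum immediately), not a change
to the fitted model.

Components are disambiguated two ways and both are stored: by height
(density of the full mixture at each component's mean; exact ties fall
back to proximity) and by proximity to the true direction.

## Peak-location clustering and WAIC

The joint distribution of (larger, smaller) component locations is
modeled with mixtures of 1–3 bivariate von Mises clusters (independent
coordinates within a cluster — an assumption, since nothing constrains the
within-cluster dependence) plus a circular-uniform background component
that absorbs pairs whose smaller component is unidentifiable.  Models are
compared by WAIC: each cluster count is sampled with the affine-invariant
ensemble sampler (emcee) initialized at a deterministic EM solution
(projected into the prior's support), and WAIC is computed from the
pointwise log-likelihood over posterior draws
(`-2 Σᵢ [log meanₛ p(yᵢ|θₛ) - varₛ log p(yᵢ|θₛ)]`; cross-checked against
arviz).  A deterministic EM + BIC path is available
(`method="bic"`) for fast runs.

The *reported* cluster count is the number of **distinct peak-location
clusters** of the preferred model: mixture components within 90° of each
other in both coordinates are merged (they describe one cluster's
dispersion shape — on decoded data the criteria reliably prefer an extra
co-located component capturing heavy tails — not a new location), and
merged clusters below 5% weight are dropped.  Clean simulated pair sets
are unaffected by either robustification.

Priors for the sampler: flat on cluster locations, log κ ~ N(log 5, 1.5²)
bounded below κ = 500, logistic-normal (scale 3) on mixing weights.

## Probabilistic decoder

Voxel tuning: each voxel's mean response is a weighted sum of K = 8
half-rectified cosine channels raised to the 5th power, with preferred
directions evenly spaced on the circle.  Weights are estimated by ordinary
least squares.  Noise is multivariate normal with covariance shrunk
toward the structured form `σ²WWᵀ + (1-ρ)diag(τ²) + ρττᵀ` (tuning-shared,
independent, and globally shared variance): `Ω = λΩ_sample + (1-λ)Ω₀`,
with per-voxel variances shrunk toward their median by λ_var.  (ρ, σ²)
maximize the Gaussian likelihood of the training residuals with τ′ fixed
at the residual SDs (a moment-matching fallback fits the off-diagonal
covariance by least squares); because τ′ absorbs part of the
tuning-shared variance, σ² recovers with a known downward bias.  λ and
λ_var are selected once per cross-validation fold by held-out likelihood
on an inner run split and reused across that fold's bootstraps — refitting
them per bootstrap costs two orders of magnitude more Cholesky
factorizations for no measurable gain at these problem sizes.

Decoding inverts the model with Bayes' rule under a flat prior: the log
posterior over the 0.5° grid is the Gaussian log-likelihood of the pattern
at each grid direction's mean, computed via one triangular solve of the
grid means per model fit plus one per trial, max-subtracted before
exponentiation.  Cross-validated decoding leaves one run out, refits on
`n_boot` bootstrap resamples of the training trials (degenerate resamples
are redrawn), and averages the per-trial posteriors across resamples
("bagging"; `n_boot=50` by default, 10–20 in the bundled experiments).
The decoded direction is the posterior's circular mean by default with
the MAP also reported, and uncertainty is the posterior entropy.

## Synthetic data

The voxel generator draws ground-truth tuning weights as nonnegative
gamma-distributed mixtures over the 8 channels (heterogeneous tuning
across voxels), optionally blending in a 180°-periodic orientation-code
component built from equal-weight pairs of opposite-preferring channels
(`orientation_mix`).  Noise is drawn from the decoder's own structured
covariance.  Responses are z-scored per voxel within run; no hemodynamic
time course is simulated, so the normalization applies to trial patterns
directly.  Designs follow the task structure: per run, 18 directions
evenly spaced at 20° with a uniformly random offset, in random order.

Nothing pins the synthetic SNR to empirical data, so the defaults are
calibrated against the study regime the pipeline is meant to exercise:
`noise_scale=0.3` with `orientation_mix=0.3` gives decoded-vs-true
circular correlations of ~0.75–0.85 and ~20% bimodal peak pairs.  The
decoder-recovery experiment uses these defaults; the shape-contrast
experiment (pure vs dual code) uses `noise_scale=0.2`, where decoded
posteriors are clean enough that the cluster analysis discriminates the
two codes reliably — at noise 0.3, pure-direction data itself produces
~10% noise-induced secondary modes that the information criteria rightly
model as structure.  Passing these experiments shows the pipeline's
machinery discriminates the two coding schemes under its own generative
assumptions; it does not establish performance on real BOLD data, whose
tuning heterogeneity, SNR and noise structure are not matched here.

The behavioral generator layers three empirical features onto observer
responses: an oblique effect (cue noise SDs scaled by `1 + a·sin²(2s)`),
an attractive cardinal bias on the mean response, and a uniform lapse.

## Behavioral analysis

Cardinal-bias removal fits, per 90° bin, a 4th-degree Legendre polynomial
(on direction re-centered to the bin center, scaled to [-1, 1]) to the
errors, with the residual SD modeled log-linearly in distance-to-center
(two-stage fit; the dispersion model's functional form is a choice — only
the sign and shape of the oblique effect are treated as testable).  Two
binnings are fitted — bins centered on the cardinals (attraction, whose
biases vanish there) or on the obliques (repulsion) — and the
better-likelihood variant is selected per subject.  Errors beyond ±3
predicted SDs are flagged as outliers (~0.27% under Gaussian residuals).

The response-distribution comparison fits, by bounded maximum likelihood
from multiple starts, a unimodal model (von Mises at 0° plus uniform
lapse) against a bimodal model (second von Mises fixed at 180°), and
compares BIC per subject; group inference sums ΔBIC across subjects.

The uncertainty–variability regression predicts squared (optionally
log-transformed) behavioral error from within-subject-demeaned decoded
entropy with distance-to-cardinal as a covariate and per-subject
intercepts; inference is by within-subject permutation of the entropy.
The peak–error regression selects bimodal trials (one peak within 90° of
the true, the other within 90° of the opposite direction), re-centers the
first peak on the true and the second on the opposite direction, applies
the sine transform `μ' = sin(πμ/90)` to linearize the circular relation,
and regresses the behavioral error on both transformed locations with
per-subject intercepts and permutation p-values.  Hierarchical Bayesian
regression is deliberately simplified to fixed slopes + per-subject
intercepts with permutation inference throughout.

## Problem sizes and reproducibility

The bundled experiments use 10,000 trials per simulated condition, 64
noise-grid cells, and voxel datasets of 10 runs × 18 trials × 200 voxels
with 10–20 bagging iterations; the unit-test suite runs reduced versions
of every pathway.  All randomness flows through seeded
`numpy.random.Generator` instances (per-cell seeds spawned from a root
`SeedSequence`), making stored tables bit-for-bit reproducible for a
fixed seed.  Workflow runs archive their configuration and a SHA-256
manifest of outputs next to the results.
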