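# Methods

## The model

`fakemix` implements a person-by-item mixture measurement model for faking
in high-stakes personality assessment.  Every response of person *n* to
item *i* is attributed to one of three latent response strategies,
represented by a cell-level class variable ζ_ni:

* **S-only** (ζ = 0): the response reflects the substantive traits only.
  Conditional on this class the item response follows a multidimensional
  generalized partial credit model: the category-*k* propensity is
  Σ_d α_iSd · s_iSdk · θ_nd + γ_ik^(S), mapped to probabilities by a
  softmax over the K+1 categories.
* **S&F** (ζ = 1): the response reflects traits *and* a faking dimension;
  the propensity adds α_iF · s_iFk · η_n and uses its own intercepts
  γ_ik^(SF) (a constrained multidimensional nominal response model).
* **F-only** (ζ = 2): the response reflects faking alone (a unidimensional
  nominal response model with desirability scoring weights and intercepts
  γ_ik^(F)).

Scoring weights define the latent dimensions: for the trait an item
measures they are the evenly spaced integers 0..K; for the faking
dimension they are the social-desirability values of the item's categories
rescaled to the common 0–6 metric (so nonmonotonic desirability
trajectories are representable).  Slopes are class-invariant so the same
latent variables are measured in every class; the first-category intercept
is fixed at 0 per item and class for identification.

Response times are log-normal with person speed φ_n and class-specific
time intensities: mean δ_i^(S) − ν_φ φ_n in S-only, δ_i^(F) − ν_φ φ_n in
F-only, and δ_i^(S) + λ δ_i^(F) − ν_φ φ_n in S&F, with class-specific
residual SDs ς.  λ > 0 encodes the assumption that trait responding
followed by desirability editing takes longer than trait responding alone.

Class membership follows a partial credit model on a strategy-inclination
score ψ_n with integer class scores 0, 1, 2 and item-class intercepts
β_ic (β_i0 = 0): p(ζ_ni = c) = softmax_c(ν_ψ c ψ_n + β_ic).  The D+3
person parameters (θ, η, φ, ψ) are jointly multivariate normal with mean
zero, unit variances (scale identification), and a free correlation
matrix.  The likelihood marginalizes ζ per cell by a three-term
log-sum-exp.

Reduced comparison variants: a person-by-item mixture without RTs; person
mixtures (class constant per person, categorical with a flat Dirichlet
prior on the proportions) with and without RTs; and three non-mixture
models that fix a single class for everyone (MNRM = S&F structure,
MGPCM = S-only, NRM = F-only; fitted to responses only).

## Priors

Slopes (α, ν_φ, ν_ψ): positive-truncated normal N+(0, 2²).  Category and
class intercepts: N(0, 4²).  Time intensities: N(m, 1²) with m the
empirical mean log-RT.  λ: N+(0, 0.5²).  Residual SDs: half-Cauchy(1).
The latent correlation matrix has a uniform prior over positive-definite
correlation matrices (proposals leaving the PD cone are rejected).  An
element-wise U(−1, 1) prior on the individual correlations would not by
itself guarantee positive definiteness; the uniform-over-PD prior is the
closest proper analogue and is practically indistinguishable at dimension
six.

## Estimation

The default sampler is Hamiltonian Monte Carlo over all continuous
parameters jointly (person scores, item parameters, global slopes and
scales, class proportions), on the unconstrained scale: positive
parameters are log-transformed with the change-of-variable Jacobian
(equivalent to truncation at zero for the priors used), simplex
proportions use fixed-anchor logits.  Gradients of the class-marginalized
log-posterior are derived analytically (responsibility-weighted chain
rule through the softmax, normal and log-normal terms) and are verified
against central finite differences to ~1e-8 in the test suite for all
seven variants.  Warmup adapts the step size toward an acceptance rate of
0.8 and estimates a diagonal mass matrix from the middle warmup window;
trajectory lengths are jittered around `n_leapfrog` steps.

Two classes of updates complement the trajectories:

* the latent correlation matrix keeps a joint random-walk Metropolis step
  on its off-diagonal elements (its conditional given the sampled latents
  is cheap, and rejecting non-PD proposals implements the prior support);
* likelihood-invariant parameter-expansion moves rescale each latent
  column together with the slopes that multiply it, and shift each latent
  column with the compensating intercepts, decorrelating the latent
  scale/location from slopes and intercepts along ridges the trajectories
  traverse slowly.

A data-augmented Gibbs variant (`marginalize=False`) samples ζ explicitly
from its categorical full conditional and updates all parameters by
adaptive blocked random-walk Metropolis, mirroring the classical BUGS-style
estimation of this model family.  It targets the identical posterior and
serves as an independent cross-check of the HMC implementation in the
tests.  Chains are initialized at data-informed, chain-jittered values
(empirical category logits, per-item mean log-RTs, standardized scale and
desirability scores); purely diffuse starts frequently stall in a
degenerate flat-class mode (ν_ψ ≈ 0) within desk-scale warmup.

Convergence is assessed by split R-hat (via arviz) on all item-level and
global parameters, with the conventional threshold 1.1; per-person scores
can be added with a flag.  Point estimates are posterior means.  A
non-convergent run is returned with `converged=False`, never silently
passed.  Identification constraints (zero first-category intercepts, zero
S-only class intercepts, positivity) hold exactly in every retained draw
by construction of the parameterization.

## Synthetic data

The generator reproduces the design of the parameter-recovery study:
three substantive traits, ten items per trait interleaved in random
order, seven response categories, N = 500 persons by default, fresh
person draws per replication (a flag freezes them).  Generating values
are calibrated to estimates from an operational high-stakes selection
assessment:

* time intensities N(1.72, 0.15²) and N(1.53, 0.15²) log-seconds for the
  S-only and F-only classes, λ = 0.23, ν_ψ = 1.05;
* the latent correlation matrix uses the empirically estimated pattern
  (trait intercorrelations .20–.36, trait-faking correlations around
  −.23, faking–strategy-inclination correlation .32);
* ν_φ = 0.5 and ς = (0.30, 0.33, 0.30), chosen so the model-implied raw-RT
  medians and MADs match the empirically estimated per-class values (about 5.9, 6.5 and
  4.7 s medians with MADs near 2–3 s; total log-RT SD ≈ √(ν_φ² + ς²));
* item-class intercept means (−0.45, −1.0) solved numerically so average
  class proportions are ≈ 49/26/25% at ν_ψ = 1.05, with scatter SD 0.7
  reproducing the wide item-to-item spread of class proportions;
* discrimination slopes U(0.8, 1.6) — moderate per-step discriminations
  typical of selection-context personality scales; weaker slopes produce
  trait-recovery correlations far below what operational personality
  scales achieve;
* class-specific category intercepts combine item scatter N(0, 0.7²) with
  a desirability tilt (0 / 0.35 / 0.8 × the centered faking weights for
  S-only / S&F / F-only), so F-only responses concentrate on desirable
  categories — the class-specific response-distribution pattern seen in
  operational data.  Without this tilt the F-only class degenerates
  into an unconstrained sponge for poorly fitting cells and classification
  accuracy collapses;
* desirability trajectories cycle through monotone-increasing,
  interior-peak and midpoint-peak shapes, so nonmonotonic faking effects
  are present by default.

What the generator does *not* emulate: item content and wording effects,
speededness/stationarity violations across test position, person-specific
perception of desirability, and missingness.  Passing recovery tests
therefore show that the estimation machinery inverts the model's own
generative process at realistic parameter values — not that the model is
robust to violations of its assumptions.

## Classification and recovery metrics

Posterior class probabilities come in two flavors: *structural* (plugging
each retained draw of ν_ψ, ψ, β into the latent response model — the
plug-in class-proportion estimator) and *conditional* (normalizing the
three mixture summands of each cell, i.e. conditioning on the cell's
response and RT — what explicit class sampling implicitly does).  Modal
assignment uses the conditional table by default; ties break toward the
less pronounced strategy.  Hit rates pool person-by-item cells.  Recovery
metrics are computed within replication and averaged (bias, RMSE), with
person-parameter recovery correlations aggregated via Fisher's z;
aggregates use converged replications only.  Credible intervals for class
proportions are central 95% intervals of the draw-wise mean proportion.

## Model fit

WAIC and LOOIC (PSIS) are computed from the pointwise posterior
log-likelihood of person-by-item cells (classes marginalized per cell;
for person-mixture variants the cell likelihood is Rao-Blackwellized with
the person's posterior class weights), on the deviance scale, in a
response-only and a joint scope.  arviz provides the estimators; a
conjugate-normal analytic oracle validates the route in the tests.
Unstable Pareto-k values are counted and reported.  PPMC-SRMR compares
observed Pearson item intercorrelations of the raw category scores with
their posterior predictive means (averaging replicate correlation
matrices before differencing; a flag averages per-replicate SRMRs
instead).  The RT check reports per-item posterior predictive p-values
for mean log-RTs.  Default 200 posterior predictive replicates.

## Numerical choices and problem sizes

All mixture arithmetic is in log space with log-sum-exp; −30 on the
propensity scale serves as a finite surrogate for −∞ in degenerate
designs.  The hot likelihood and gradient kernels are numba-compiled.
The package's own validation studies run at reduced scale chosen for a
desk machine: the test suite uses N ≈ 200–300 persons, 30 items, two
chains with 500 warmup / 500 retained draws and a handful of
replications; `scripts/acceptance.py` re-runs the same pipeline at the
sizes documented in its header.  The full reference design (N = 500,
50 replications, 4 × 14,000-iteration chains) is available through the
same configuration objects.

## Known limitations

Short desk-scale chains occasionally leave isolated item intercepts above
the R-hat threshold; the convergence gate then excludes that replication,
mirroring standard practice for this model family.  Posterior means of mixture
slopes carry a mild finite-sample bias at small N when class separation
is weak (the intercept-shrinkage/slope-inflation trade visible in this
model family); the calibrated default scenario keeps this small.  The
NRM-parameterized latent response model, unconstrained S&F time
intensities and stochastic-independence F-only variants are out of scope.
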