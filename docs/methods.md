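# Methods

## Model

`icjm` fits a Bayesian joint model for a continuous longitudinal response and
an interval-censored event time that share a subject-level frailty.

**Longitudinal submodel.** For subject *i* measured at times
*t*<sub>i1</sub> < … < *t*<sub>im_i</sub>,

y_ij = μ(t_ij) + X_i′θ + ξ_i + u_i + ε_ij,

with μ(·) an unspecified baseline mean, θ fixed covariate effects,
ξ_i ~ N(0, σ_ξ²) a longitudinal-only frailty, u_i ~ N(0, σ_u²) the shared
frailty, and ε_ij ~ N(0, σ_ε²) independent errors.

**Survival submodel.** The event time T_i follows a normal-frailty probit
model: conditional on X_i and u_i,

P(T_i ≤ t | X_i, u_i) = Φ(α(t) + X_i′β + u_i),

where α(·) is an unspecified increasing transform with range (−∞, ∞).  T_i is
never observed exactly; each subject contributes an interval (L_i, R_i]
formed by adjacent examination times, with L_i = 0 for left censoring and
R_i = ∞ for right censoring.

**Association.** Because u_i enters both submodels with opposite sign
conventions, y_ij and the transformed event time α(T_i) are negatively
associated with Pearson correlation
ρ = −σ_u² / √((1+σ_u²)(σ_ε²+σ_ξ²+σ_u²)) and Kendall's
τ = (2/π)·arcsin(ρ) ∈ (−1, 0].  τ depends only on the variance components,
never on covariates, and τ → 0 as σ_u² → 0.

## Spline baselines

μ(·) is a free linear combination of M-splines (nonnegative, density-
normalized); α(·) is an intercept r₀ plus a nonnegative combination of
I-splines (integrated M-splines), which makes monotonicity a simple sign
constraint r_k ≥ 0.  Both bases are realized through `scipy.interpolate.
BSpline` (M-spline = degree-normalized B-spline; I-spline = its
antiderivative), with cubic degree and 3 interior knots by default.  Interior
knots sit at empirical quantiles — of all observation times for μ, and of the
finite interval endpoints {L_i > 0} ∪ {R_i < ∞} for α.  Boundary knots are
the data min/max expanded by a relative 1e-8 so every datum is strictly
in-support; I-splines evaluate to their plateau value 1 at +∞.  These
conventions (quantile type, boundary padding) are interpolation details the
inference is insensitive to; robustness of the fit to the number of interior
knots is a known property of monotone-spline baselines.

## Data augmentation and Gibbs sampling

A latent normal z_i ~ N(α(t_i) + X_i′β + u_i, 1), with anchor time
t_i = R_i if left-censored else L_i, is constrained to a censoring region
C_i: (0, ∞) if left-censored, (α(L_i)−α(R_i), 0) if interval-censored,
(−∞, 0) if right-censored.  Integrating z_i over C_i recovers the
observed-likelihood survival factor (a property the test suite checks by
quadrature).  With this augmentation every full conditional is standard:
truncated normal (z_i, r_k), normal (r₀, β, θ, η, u_i, ξ_i), gamma (the
precisions, the spline shrinkage rate ρ), inverse-Gaussian (Lasso scale
latents), Bernoulli/beta (spike-and-slab indicators).

Sweep order: z → r₀ → r → ρ → survival-side coefficients+shrinkage →
longitudinal-side coefficients+shrinkage → η → u → σ_u⁻² → ξ → σ_ξ⁻² → σ_ε⁻².
Under the spike-and-slab prior the inclusion indicators and their shared
probability are updated before the coefficient vector; under the Lasso
priors the coefficient vector precedes its penalty/scale updates.

The r_k sweep is Gauss–Seidel (ascending k, conditioning on already-updated
components).  Each r_k is truncated below at d_k* = max(c_k*, 0), where c_k*
is the largest bound over interval-censored subjects required to keep every
z_i above its region edge:

c_k* = max over {i: δ_i2 = 1, b_k(R_i) − b_k(L_i) > 0} of
  [−z_i − Σ_{k′≠k} r_{k′}(b_{k′}(R_i) − b_{k′}(L_i))] / (b_k(R_i) − b_k(L_i)).

Subjects with b_k(R_i) = b_k(L_i) impose no constraint.  When a basis
function carries (numerically) no anchor-point information
(Σ_i b_k(t_i)² ≤ 1e-12), r_k is drawn from its Exp(ρ) prior shifted to
(d_k*, ∞) — exact by memorylessness and immune to the catastrophic
cancellation that the normal-form draw suffers in that regime.

### Prior variants

* **BL** — Bayesian Lasso: β_j | τ²_{s,j} ~ N(0, τ²_{s,j}),
  τ²_{s,j} ~ Exp(λ_s/2) with a common Ga(a_λ, b_λ) penalty; the θ prior is
  scaled by σ_ε² (θ_j | τ², σ_ε² ~ N(0, σ_ε²τ²_{l,j})), which adds p/2 to the
  σ_ε⁻² shape and ½θ′D⁻¹θ to its rate.  The gamma-updated penalty parameter
  is the squared rate λ² of the exponential mixing density (its conditional
  Ga(p + a_λ, ½Στ² + b_λ) and the inverse-Gaussian scale-latent update
  IG(√(λ²/β_j²), λ²) are mutually consistent only on that scale).
* **BAL** — adaptive Lasso: one penalty per coefficient,
  λ²_{s,j} ~ Ga(1 + a_λ, ½τ²_{s,j} + b_λ).
* **SS** — spike-and-slab: two-component normal mixture with variances
  (σ²_spike, σ²_slab) = (0.01, 100), Bernoulli indicators Δ, and a shared
  inclusion probability ω per submodel with a Beta(a_ω, b_ω) prior.  Both the
  β and the θ mixtures use the fixed variances directly — the θ mixture is
  *not* scaled by σ_ε².  (The scaled version shrinks truly-zero θ roughly
  twice as hard whenever σ_ε² < 1 and is empirically inconsistent with the
  operating characteristics this package reproduces; with σ_ε² = 1 the two
  parameterizations coincide.)  Accordingly the σ_ε⁻² conditional carries no
  θ terms under SS.
* **GB** — general multivariate normal priors N(0, 100·I) on β and θ; no
  selection machinery.  Serves as the no-shrinkage reference.

Remaining priors: Ga(0.1, 0.1) on each precision, N(−6, 1) on r₀, Exp(ρ) on
each r_k with ρ ~ Ga(1, 1), N(0, 100·I) on η, Ga(1, 2) on Lasso penalties,
Beta(1, 1) on inclusion probabilities.

### Numerical choices

* Truncated normals: inverse-CDF after reflecting the interval into the
  lower half line, where `ndtr`/`ndtri` remain accurate to ~38 sd;
  beyond that, shifted-exponential tail rejection.  On sliver intervals
  (width ≪ 1/|bound|) the density is constant to machine precision and the
  draw is uniform — rejection would almost surely never accept there.
* Inverse-Gaussian draws via `numpy.random.Generator.wald`; the mean
  parameter √(λ²/β_j²) is guarded by clipping |β_j| (and |θ_j|/σ_ε) below
  1e-10, where the conditional is proper but the mean diverges.
* Multivariate normal draws factor the conditional precision (LAPACK
  Cholesky) — never an explicit inverse.
* Initialization: β = θ = 0, η = 0, r₀ at its prior mean, r_k = 0.1, ρ = 1,
  u = ξ = 0, all variances 1, τ² = 1, λ = 1, Δ = 1, ω = 0.5, then one z pass.
* Chains are bit-reproducible given a seed; default burn-in is 20% of the
  chain when not specified.

## Synthetic data

The generator emulates a periodic-examination cohort: visit counts
m_i = min(Poisson(3) + 1, 10), visit times as cumulative Exp(mean 0.5) gaps,
baseline mean μ(t) = 4·log(t+1) − 2t, baseline transform
α(t) = 2·log t + t², σ_ξ² = 0.25, and covariates half Bernoulli(0.5) (the
first p/2 columns) followed by half N(0,1), shared across submodels.  Event
times are drawn exactly by inverting the conditional CDF,
T = α⁻¹(Φ⁻¹(U) − X′β − u), via bracketing bisection to |α(t) − c| < 1e-10;
the recorded interval is the pair of adjacent points of
{0, t_i1, …, t_im_i, ∞} with T ∈ (L, R].  Scenario I uses p = 10 with
θ = (1,0,1,0,1,0,1,0,1,0) and β = (1,1,0,0,1,1,0,0,1,0); Scenario II uses
p = 30 with θ = (1₁₀, 0₂₀) and β = (1₅, 0₅, 1₅, 0₁₅).  One design seed spawns
independent substreams for schedule, covariates, frailties, errors and event
uniforms.

What the generator does **not** emulate: informative or irregular visit
processes, dropout, time-varying covariates, administrative censoring
horizons, or non-normal frailties.  Tests passing under this generator
demonstrate correctness of the machinery under the model's own assumptions,
not robustness to their violation.

## Summaries and replicate metrics

Point estimates are posterior means; intervals are equal-tailed 2.5/97.5%
quantiles (not HPD).  A coefficient is labeled **positive** (selected) when
its closed 95% interval excludes 0 — endpoint ties count as containing 0, a
measure-zero deterministic tie-break.  Across replicates: BIAS = mean
estimate − truth, RMSE = root mean squared estimate error, CP95 = interval
coverage of the truth; per submodel: aver.size = mean count of positives,
TN = truly-zero coefficients labeled negative, FN = truly-nonzero
coefficients labeled negative.  aver.size + TN + FN = p in every report.
Kendall's τ is computed per retained draw from the variance triplet and
summarized like any scalar.

## Study sizes

The replicate studies run at 50 replicates of n = 500 with 3000-iteration
chains (500 burn-in); the full-scale analogue is 500 replicates with
5000-iteration chains (1000 burn-in).  At 50 replicates the Monte-Carlo
standard error of an RMSE around 0.08 is roughly 0.008, of a coverage
probability roughly 0.034, and of a selection count a few hundredths — the
tolerances used in the acceptance suite reflect this.  Scalar-conditional
distribution checks use 10⁵ single-block draws against grid-normalized
densities (KS at α = 0.001); the association check uses 10⁵ simulated
subjects (3 Monte-Carlo standard errors).

## Known limitations

* **Spike-and-slab false negatives in the sparse, weak-information regime.**
  In Scenario II's survival submodel the per-coefficient information is
  modest (posterior sd ≈ 0.28 for the Bernoulli covariates), so a spike at
  sd 0.1 against a slab at sd 10 leaves non-negligible posterior spike mass
  even for unit-size true effects; the 95% interval then touches 0 and the
  coefficient is counted as a false negative.  The converged sampler labels
  roughly 5 of 10 true survival effects negative in that regime — the
  spike-and-slab prior is genuinely the weakest of the four there, and this
  implementation reports the converged value rather than an under-mixed
  chain's lower one.  The ordering (SS misses more survival signals than BL)
  is robust.
* The indicator update conditions on the current coefficient value, which
  mixes slowly between spike and slab when the likelihood is weak; chains in
  that regime should be run long and checked with standard MCMC diagnostics
  (`arviz` works directly on the returned draw arrays).
* Single shared frailty only; no time-varying covariates; no nonparametric
  frailty distribution.
* The observed-data likelihood is never maximized or evaluated directly; it
  appears only through the augmentation identity verified in the tests.
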