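# Methods

`cmgipd` estimates treatment-effect moderation from pooled
individual-participant data (IPD) across randomized trials, using
Bayesian shrinkage priors built for the multi-study setting. This note
records the model, the priors, the sampler, the synthetic-data
generator, the risk metrics, and the numerical and design choices that
were genuinely open.

## Model

For participant *j* in study *i* (*i* = 1..*I*, *j* = 1..*n_i*) with
continuous outcome *y_ij*, treatment indicator *t_ij* ∈ {0, 1} and
centered baseline covariates *x_ij* ∈ ℝ^p, the one-stage linear mixed
model is

```
y_ij = μ + t_ij α + x_ij' β + xem_ij' γ
       + u_μi + t_ij u_αi + xem_ij' u_i + ε_ij,
ε_ij ~ N(0, σ_i²),
u_μi ~ N(0, τ_μ²),  u_αi ~ N(0, τ_α²),  u_ki ~ N(0, τ_k²),
```

where `xem_ij = t_ij · x_ij[moderators]` collects the *d*
covariate-by-treatment interactions and γ ∈ ℝ^d — the moderation
effects — is the target of inference. The random effects *u_i* on the
moderation terms can be dropped (`include_moderation_random_effects=False`)
to reduce model complexity; this is also the variant that the DIC
comparison in `analyze_dataset` evaluates against the full model.

Nuisance priors are fixed across all methods so that only the prior on γ
differs: π(μ, α, β, σ_i²) ∝ 1/σ_i² (independent Jeffreys per study —
the noise is study-specific, so the scale-invariant prior is applied per
σ_i²) and half-Cauchy C⁺(0, 1) priors on every between-study SD τ.

## Priors on the moderation effects

Twenty interchangeable specifications are registered by name:

* **Flat** — π(γ_k) ∝ 1.
* **HS** — horseshoe: γ_k ~ N(0, λ_k² τ_hs²), λ_k, τ_hs ~ C⁺(0, 1).
  (The horseshoe global scale is written τ_hs internally to avoid
  collision with the between-study τ's.)
* **SSVS** — γ_k ~ (1 − I_k) N(0, η²) + I_k N(0, h_k η²), with
  I_k ~ Bernoulli(0.5), η ~ Uniform(0, c). Defaults h_k = 100, c = 5,
  both exposed on `PriorSpec`.
* **NMG** (naive mixtures of g-priors) —
  γ_k ~ N(0, g_k [(t∘x[k])' Λ (t∘x[k])]⁻¹) with
  Λ = diag(σ_i⁻² 1_{n_i}), i.e. a per-moderator g-prior whose Gram
  matrix is weighted by the study-specific noise. Rules for g_k:
  **UIP** g_k = N (total sample size); **ZS** g_k ~ IG(1/2, N/2);
  **HG** g_k/(1+g_k) ~ Beta(1, a/2−1) and **HGN**
  g_k/(g_k+N) ~ Beta(1, a/2−1), each with a ∈ {3, 4}.
* **CMG** (calibrated mixtures of g-priors) — the same structure with
  Λ\* = diag(σ_i⁻² f(n_i)⁻¹ 1_{n_i}), where f(n_i | p_i) is a
  study-level sample-size tuning function bounded by n_i:
  linear `n` f = n_i p_i with p_i ~ U(1/n_i, 1); logarithmic `log`
  f = log(n_i p_i), same support (f > 0 enforced); fractional-power
  `pow` f = n_i^{p_i} with p_i ~ U(0, 1). Shrinkage hyperpriors:
  **S1** g_k/(1+g_k) ~ Beta(2, b_k) (least shrinkage, expected prior
  shrinkage E[g/(1+g)] = ln 2 ≈ 0.69 when b_k ~ U(0, 2)); **S2**
  Beta(1, 1) (uniform, 0.50); **S3** Beta(b_k, 2) (most shrinkage,
  1 − ln 2 ≈ 0.31). **CUIP** sets g_k = 1 and f = N; **CZS** uses
  g_k ~ IG(1/2, 1/2) with the linear tuning form.

Inverse-gamma convention: IG(shape, scale) has density
∝ g^(−shape−1) e^(−scale/g). The Beta shape b_k is per-moderator with
b_k ~ Uniform(0, 2) by default; a fixed-b mode (`b_fixed`) is exposed.
The tuning parameter p_i is per-study and shared across moderators
(Λ\* does not depend on k). All hyperprior densities on the g scale
include the Jacobian of the g ↦ g/(1+g) (or g/(g+N)) transform; unit
tests verify total mass 1 by quadrature and the Jacobian by a
Kolmogorov–Smirnov check against the closed-form CDF.

## Sampler

`fit` runs a Metropolis-within-Gibbs sampler (one independent NumPy
generator per chain, spawned from the user seed, so runs are exactly
reproducible):

* **(μ, α, β, γ)** — one exact joint Gaussian draw from the full
  conditional; the γ block's prior precision is q_k/g_k with
  q_k = (t∘x[k])' Λ\* (t∘x[k]) under g-priors, 1/(λ_k² τ_hs²) under the
  horseshoe, and 1/(h_k^{I_k} η²) under SSVS.
* **Random effects** — exact Gaussian full conditional per study.
* **τ²** — the half-Cauchy prior is handled by the inverse-gamma
  parameter expansion (τ ~ C⁺(0, A) ⟺ τ² | a ~ IG(1/2, 1/a),
  a ~ IG(1/2, 1/A²)), giving conjugate draws.
* **σ_i²** — under Flat/HS/SSVS the conditional is exactly
  IG(n_i/2, SSR_i/2). Under g-priors the γ prior also depends on σ_i²
  through q_k; the conjugate IG draw is then used as an *independence
  proposal* and accepted with the ratio of the g-prior terms
  ∏_k q_k^{1/2} exp(−γ_k² q_k / 2g_k), which accounts for the extra
  dependence exactly.
* **g_k** — exact conjugate IG draw for ZS/CZS (shape 1,
  scale s₀ + q_k γ_k²/2); log-scale random-walk Metropolis (step 1.0,
  vectorized over k) for the Beta-shrinkage hyperpriors.
* **p_i, b_k** — uniform independence Metropolis on their bounded
  supports; for p_i the change to every q_k is recomputed
  incrementally per study.
* **Horseshoe scales** — the standard inverse-gamma auxiliary-variable
  chain; **SSVS** indicators by their exact Bernoulli conditional and η
  by shrinkage slice sampling on (0, c).

Defaults are two chains of 20,000 iterations, burn-in 10,000, thinning
10 (`FULL_MCMC`); the reduced profile `TEST_MCMC` (2 × 2,000, burn-in
1,000, thin 2) is used throughout the test suite and the replicated
comparisons. Initialization is deterministic: fixed effects at least
squares, σ_i² at per-study residual variances, all τ² at 1, g_k = 1,
p_i at mid-support, b_k = 1. This simple fixed start keeps burn-in fast
and runs byte-reproducible.

A subtlety worth recording: a g-prior's variance scales with σ², so an
"uninformative outcome" cannot make the posterior of the shrinkage
factor collapse to its hyperprior — integrating γ out leaves a
(1 + g f)^{−1/2} factor regardless of how large σ² is. The sampler is
therefore validated against that exact tilted density (2-D quadrature in
the single-study, d = 1, S2 + pow case), not against the bare
hyperprior, and against the closed-form conjugate posterior mean
g/(1+g) · (X'X)⁻¹X'Y in the fixed-g case.

## Synthetic data

`generate_dataset` draws from the model itself under the grid of 36
conditions: I = 5 trials, n_i ~ U{100..150}, p = 8 covariates
~ MVN(0, Σ_i) with unit SDs; fixed truths μ = 2, α = 3,
β = (1.8, 2.7, 2.3, 1.5, 1.7, 2.2, 1.3, 2.6),
(σ_1..σ_5) = (3.5, 2.5, 2.1, 2.8, 3), τ_μ = τ_α = 1.5. The grid crosses
between-trial moderation variability τ_k ∈ (1.5, 2.5) / (0.5, 1.5) / 0,
sparsity 2/4/6 true moderators, covariate correlation 0 or pairwise
(0.5, 0.9), and strength γ_k = 1.5 or 0.75.

Choices the design left open, fixed here:

* τ_k within a range are assigned **equally spaced** across the 8
  moderators (deterministic given the setting), so the true mean
  structure is constant across replicates as the replicate-level metrics
  require.
* High-correlation matrices draw i.i.d. U(0.5, 0.9) off-diagonals,
  symmetrize, clip eigenvalues to restore positive definiteness and
  rescale to unit diagonal — one draw per study per replicate.
* Treatment is a **balanced permutation** within study (1:1 allocation),
  mimicking the randomized designs being emulated.
* The true moderators are the **first** 2/4/6 covariates; by exchange-
  ability of the covariates the choice is immaterial.

The generator emulates the stated generative model only: covariates are
Gaussian and complete, treatment is perfectly randomized, outcomes are
linear with Gaussian noise. Real IPD-MA features it does not emulate —
missingness, non-Gaussian or categorical covariates beyond binary,
nonlinearity, differential trial designs — mean that passing tests
demonstrate correct behavior *under the model*, not robustness to
model violations.

## Risk metrics

With posterior means γ̂^(r) over R replicates and fixed truth γ,
relative metrics divide by the mean absolute truth Σ|γ_k|/d:
ARRMSE (root mean square of all errors over r and k), AARBias (mean
absolute bias of the per-k replicate means), ARSD (root mean square of
deviations from per-k replicate means). Participant-level risk averages
per-replicate Euclidean norms of (tα + Xem γ) − (tα̂ + Xem γ̂) divided
by N (PSRMSE), or of the moderation part only (PSRMSE(EM)). The exact
per-k identity MSE = variance + bias² holds before the relative
aggregation and is unit-tested; no general ordering between ARRMSE and
ARSD survives the aggregation. In the benchmark the replicates redraw
n_i, so the per-replicate value ‖·‖/N_r is averaged — identical to the
single-N formula when N is constant.

DIC uses the **conditional** deviance (Gaussian likelihood given the
random effects), D̄ + p_D with p_D = D̄ − D(θ̄) and the plug-in at the
posterior means of all parameters including random effects and σ_i²;
the marginal (random-effects-integrated) deviance is out of scope.

The scaled neighborhood criterion reports
p_γk = P(|γ_k| < SD(γ_k | y) | y), with the posterior SD estimated from
the same retained draws (plug-in), and flags a moderator as important
when p_γk < 0.5. For draws ~ N(1, 1) the closed form is
Φ(0) − Φ(−2) ≈ 0.477, which the tests check.

## Problem sizes used in the shipped runs

The package's own replicated comparisons run at a reduced scale chosen
for routine re-execution: 20 replicates of the most challenging cell
(high variability, weak moderation, high sparsity, correlated
covariates) under the `TEST_MCMC` profile for the method ranking, and
20–50 replicates for the coverage check. At this scale the directional
findings are stable (the calibrated S3-log prior beats Flat, horseshoe
and SSVS; Flat is worst; S1 ≥ S2 ≥ S3 in posterior norm) and the
percent ARRMSE reductions are reproduced to within a few points of the
full-scale (500-replicate) values; the full grid at 500 replicates and
the 2 × 20,000 profile is available through `run_benchmark` /
`cmgipd benchmark`.

## Known limitations

* Continuous outcomes only; the model is linear.
* No per-study shrinkage parameters g_{k,i}; the calibrated weighting
  enters only through f(n_i | p_i).
* Random-walk/independence Metropolis steps use fixed proposal scales;
  for very small studies (n_i < 10) mixing of p_i and g_k should be
  checked with `convergence_report`.
* DIC is conditional on random effects; comparing models with different
  random-effect structures by conditional DIC is a convention, and the
  test suite checks only directional behavior.
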