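# Methods

## Model

`mlmirt` estimates a three-level latent-variable model for binary test
responses of persons nested in schools.

**Level 1 (measurement).** Person *i* in school *j* answers item *k*
correctly with probability

    P(Y_ijk = 1 | θ_ij, ξ_k) = Φ(η_ijk),    η_ijk = Σ_q a_kq θ_ijq − b_k,

a multidimensional two-parameter normal-ogive (probit) model.  The model is
*within-item* multidimensional: every item may load on every ability
dimension.  Discriminations a_kq are non-negative; b_k is the difficulty.

**Level 2 (person).** Abilities are regressed on person covariates with
school-specific coefficients:

    θ_ijq = X_ij β_jq + e_ijq,    e_ij ~ N(0, Σ_e),

where X_ij carries an explicit leading constant, and Σ_e is a full Q×Q
covariance.

**Level 3 (school).** Each coefficient may vary across schools and be
predicted by school covariates:

    β_hjq = w_j γ_hq + u_hjq,     u_jq ~ N(0, T_q),

with the level-3 residual covariance between different ability dimensions
constrained to zero (T block-diagonal over q).  A `ModelSpec` declares, per
coefficient and dimension, whether the residual u exists (random vs fixed
coefficient) and which school-design columns enter w_j γ_hq.  A fixed
coefficient with only the constant column reduces to one global parameter.

**Identification.** The latent location, scale and rotation are pinned by
anchoring Q items: item k ≤ Q has a_kk = 1, a_kq = 0 (k ≠ q), b_k = 0.
Anchors default to the first Q items and are configurable; anchored entries
never change during sampling.

## Estimation

All full conditionals are conjugate after augmenting each response with a
latent score Z_ijk ~ N(η_ijk, 1) whose sign is tied to Y_ijk.  One sweep
updates, in order: Z (truncated normals); θ dimension-by-dimension, each
combining the measurement pseudo-observation
θ̃_q = (a_q'a_q)^{-1} a_q'(Z + b − θ_{−q}A_{−q}') with the conditional
structural prior given the other dimensions; free item parameters from a
multivariate normal truncated to a_kq > 0 (one coordinate-wise
truncated-normal sub-sweep per iteration, started from the current value —
itself a valid Gibbs kernel); random school coefficients in precision form
(X'X/σ_q² + T_q^{-1})^{-1}; fixed (global) coefficients pooled across
schools under a flat prior; fixed effects γ_q by generalized least squares
through T_q (flat prior, optionally confined to a uniform box by rejection
with a coordinate-wise truncated fallback); Σ_e ~ IW(v0 + n, S + Σ0); and
each T_q ~ IW(v1 + J, S1 + Σ1).

The coefficient step uses the conditional variance σ_q² (the Schur
complement of Σ_e) with the raw ability column, without residualizing
against the other dimensions' level-2 residuals.  This is exact when Σ_e is
diagonal and an approximation otherwise; an independent MCMC implementation
of the same model with exact conditionals reproduced our posterior on
shared data, so the approximation is immaterial at the default designs.

**Priors and defaults.** Item parameters: a_k ~ N(μ_a 1, σ_a² I) truncated
to the positive orthant and b_k ~ N(μ_b, σ_b²), defaulting to the
noninformative μ=0, σ²=100.  Fixed effects: flat, or uniform on
[−bound, bound] (the reference protocol uses bound 2).  Σ_e: inverse-Wishart
with v0 = Q+2 and identity scale.  T_q: inverse-Wishart with v1 = r_q+2 and
identity scale by default; `improper_T=True` implements p(T_q) ∝ 1, read as
v1 = 0 with zero scale, requiring J > r_q + 1.  The inverse-Wishart is
parameterized so that the posterior scale is the residual cross-product
plus the prior scale (precision ~ Wishart of the inverse scale); the
alternative literal reading concentrates on the wrong scale.

**Numerical choices.** Truncated normals use inverse-CDF sampling for
cross-platform reproducibility, switching to an exponential-proposal
rejection sampler beyond six standard deviations where the CDF underflows.
Covariance factorizations get one scale-relative 1e-8 jitter retry, then a
hard error naming the step; the level-3 inverse-Wishart scale receives the
same relative jitter because chains under the improper prior can visit
|residual correlation| ≈ 1 where the scale matrix degenerates in floats.
Initialization: θ = 0, free a = 1, b = 0, γ = 0, β = wγ, Σ_e = I,
T_q = 0.1 I.  Overdispersed multi-chain starts scale the covariances by
1 + 0.25·chain and offset γ by ±0.4·⌈chain/2⌉ — three to six posterior
standard deviations out at the reference design.

## Model comparison

The deviance information criterion is computed on the *top-level
marginalized* deviance D(γ) = −2 log p(Z | Ω₁), Ω₁ = (ξ, Σ_e, T), with the
mid-level random effects θ and β integrated out analytically.  Per school
the stacked scores are multivariate normal with a person-block-diagonal
part A Σ_e A' + I_K plus a low-rank coupling M_j blockdiag(T_q) M_j'
through the shared random coefficients; it is evaluated with
Woodbury/determinant-lemma updates (cost linear in school size) and matches
a dense evaluation to 1e-8 in tests.  Along the single joint chain, thinned
snapshots of (Z, Ω₁, γ) give D̄; replacing γ with its overall posterior mean
gives D̂; pD = D̄ − D̂ and DIC = D̄ + pD.  Whether the plug-in mean should
instead be conditional on each snapshot is ambiguous; we use the overall
mean.  Smaller DIC is preferred.  Snapshots are stored every 20th kept draw
by default to bound memory.

## Synthetic designs

`simulation1_design`: Q=2, K=30, J=10 schools × 200 students, one person
covariate ~ N(0.25, 1), one school covariate ~ N(0.5, 1); intercept and
slope both random with level-3 variance 0.100 (zero covariance); level-2
covariance [[0.300, 0.075], [0.075, 0.500]]; fixed-effect truths
(1.000, 0.300, 0.500, 0.350) on dimension 1 and (−0.350, 0.300, 0.500,
−1.000) on dimension 2.  Item truths default to the canonical printed
30-item bank (free loadings historically drawn from N(1.5, 1) truncated
positive, difficulties from N(0, 1)); `redraw_items=True` redraws from
those distributions.  `simulation2_design`: Q=4, N ∈ {1000, 2000, 3000}
equally split over 10 schools, K ∈ {40, 100, 200} split evenly into four
subtests; level-2 variances (0.300, 0.500, 0.750, 1.000) with covariance
0.075; the same fixed-effect vector (1.000, 0.300, 0.500, 0.350) on every
dimension; item truths are redrawn per seed since the printed
two-dimensional bank does not extend to four dimensions.  Every stochastic
component consumes an independent child stream of the master seed, so
regenerating one component leaves the others untouched.  The generators
emulate the stated study conditions only: covariates are independent
Gaussians, responses are complete, and item banks are unstructured beyond
the anchors — real test batteries with planned missingness, correlated
covariates or simple-structure subtests are outside what passing tests
demonstrate.

## What the validation does and does not show

The sampler's joint correctness is established by a
successive-conditional vs marginal-conditional (Geweke-style) moment
comparison on a small configuration with independent residual dimensions,
by conjugate closed-form oracles per step, and by agreement with an
independent MCMC implementation (JAGS) of the same model on shared data.

Two genuine statistical features of this model class surfaced during
validation and are documented rather than patched:

1. **Scale ridge.** With flat positive-truncated discrimination priors, the
   posterior has a weakly identified ridge trading free discriminations up
   against ability dispersion (hence Σ_e) down; only the Q anchor items pin
   the scale.  At the reference design the posterior mean sits visibly
   up-ridge (free a about +10–15%, σ²_e1 near 0.25 for a generating value
   of 0.30), and single-chain EAPs inherit that displacement.  Chains
   traverse the ridge over thousands of iterations, so four overdispersed
   chains do not reach a potential-scale-reduction ratio of 1.2 on every
   structural parameter at desk scale.
2. **Improper level-3 prior at small n_j.** With p(T_q) ∝ 1 and few persons
   per school, the T chain can lock near degeneracy, pinning γ and
   shrinking its intervals far below nominal coverage.  The proper
   inverse-Wishart default avoids this; calibration (interval coverage) is
   therefore assessed under the proper prior, while the reference protocol
   keeps the improper prior at its original n_j.

## Scaled-down study sizes

Desk-scale defaults used by the test suite: single reference fit at the
full 20,000/5,000 protocol; replication study with 20 replicates at
n_j = 50 and 4,000 iterations; four-dimensional grid at K = 40 with one
replicate per N; four-chain convergence check at n_j = 100 with 6,000
iterations; interval-coverage study over 50 unidimensional micro
replicates; DIC ordering over 20 three-way comparisons at J = 16 schools.

## Known limitations

Binary responses only (no polytomous or guessing extensions); no missing
data; no posterior predictive checks; the DIC uses the plug-in pD
estimator, not a nested-expectation estimator; the structural layout
(which coefficients are random, which school covariates enter) is shared
across dimensions in the named model variants.
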