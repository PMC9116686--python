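# Methods

This package quantifies how much of the prediction error of a polygenic
score applied to an ancient (or otherwise temporally diverged) sample is
attributable to **allelic turnover** — the drift of causal allele
frequencies between the time the score is applied and the present day, when
the genome-wide association (GWA) study is conducted.

## Model

### Population genetics

Each of `L` unlinked, interchangeable causal loci evolves independently
under the discrete Wright–Fisher model with `two_N` chromosomes and
symmetric recurrent mutation at rate `mu` per site per generation in each
direction. The population-scaled mutation rate is `a = 4*N*mu =
2*two_N*mu`. The population is at stationarity, where the allele frequency
`Z` of each locus follows a Beta(a, a) law. Time is measured in coalescent
units: one unit equals `two_N` generations, and an ancient sampling time
`tau` corresponds to `round(tau * two_N)` generations before present.

In the diffusion limit, the transition density has a spectral
representation in polynomials orthonormal under the stationary beta law,
with eigenvalues `lambda_k = k (k - 1 + 2a) / 2` per coalescent unit. Every
statistic this package computes reduces to expectations of polynomials of
degree at most two in the ancient frequency `Z_tau`, so projecting onto the
first three eigenfunctions evaluates the conditional expectation
`E[f(Z_tau) | Z_0]` **exactly** — there is no series truncation anywhere in
the analytic code. The orthonormal polynomials are built by Gram–Schmidt
from the closed-form beta moments rather than from a Jacobi-polynomial
recurrence; for degree two this is exact and keeps the implementation
transparent.

### Trait and GWA study

The trait is fully additive: `L` loci with a common true effect `beta >= 0`
per copy of the trait-increasing allele (genotypes encoded −1, 0, 1), plus
Gaussian environmental noise with variance `sigma_e_sq`. The compound
parameter `sigma_e_prime_sq = sigma_e_sq / (L beta^2)` and the
narrow-sense heritability `h2 = (a/(2a+1)) / (a/(2a+1) +
sigma_e_prime_sq)` are interchangeable parameterizations.

The GWA study of `n` diploids is modeled with a threshold estimator: the
effect estimate is `beta` when the sample allele count `D ~ Binomial(2n,
Z_0)` falls strictly inside the detection interval `(d1, 2n - d2)`, and `0`
otherwise. The threshold itself comes from the standard two-sided power
condition for an additive association test on a continuous trait,
`2 n p (1-p) beta^2 / Vp = z^2` with `z` the standard-normal quantile at
`alpha/2`; the lower root is taken and `d = round(2 n p)`. With the
defaults `beta^2 = 0.01`, `Vp = 1`, `alpha = 1e-8`, this yields `d = 4142,
3340, 3290` at `n = 1e4, 1e5, 1e6`.

### Error metrics

With `miss = 1{beta_hat = 0}`, `det = 1 - miss`, and the Hardy–Weinberg
identities `E[X | z] = 2z - 1`, `Var[X | z] = 2 z (1 - z)`, and GWA-sample
mean genotype `X_bar = D/n - 1`, the per-locus metrics are exact joint
expectations over `(D, Z_tau)` (conditionally independent given `Z_0`):

- `bias_l(tau) = beta * E[miss * (D/n - 2 Z_tau)]`
- `mse_l(tau) = beta^2 * E[miss * (2 Z_tau (1 - Z_tau) + (2 Z_tau - D/n)^2)]`
- `va_hat_l(tau) = 2 ((2 n_a - 1)/(2 n_a)) beta^2 * E[det * Z_tau (1 - Z_tau)]`
- `rho2(tau) = 2 E[det * Z_tau (1 - Z_tau)] / (a/(2a+1) + sigma_e_prime_sq)`

The outer expectation over `D` is a finite beta-binomial sum evaluated in
log space over the support of the indicator, so even `n = 1e6` designs cost
only the size of the miss (or detected-complement) set. Trait-wide curves
are `L` times the per-locus curves; the trait-wide mse adds
`((n-1)/n) sigma_e_sq`. Relative accuracy `rho2(tau)/rho2(0)` cancels the
heritability-dependent denominator and, for small `a`, is closely
approximated by `e^(-tau)` (available as an explicit curve variant, as are
the small-`tau` linear approximations).

A two-population scenario — a sample taken `tau_prime` before present from
a population that split from the GWA population `tau_split` ago — maps onto
a single ancient sampling time `tau = 2 tau_split - tau_prime`.

### Initial-rate duality

The linear (small-`tau`) approximations of the mse increase and the
decrease of the estimated additive genetic variance are both
`2 beta^2 a P^(d) tau`, up to the finite-ancient-sample factor
`(2 n_a - 1)/(2 n_a)`. Note this duality is a statement about the
initial-rate approximations: the exact mse slope contains an additional
term — growth of `E[miss (2 Z_tau - D/n)^2]` as drift separates the ancient
frequency from the GWA-sample frequency — that the approximation drops, and
which is non-negligible when `d/2n` is large (for example `n = 1e4`,
`d = 4142`).

## Verification strategy

Three independent oracles back every analytic result:

1. **Dense discrete chain.** A `(two_N+1)`-state Wright–Fisher transition
   matrix (selection, then mutation, then binomial resampling) with its
   stationary law obtained by a dense linear solve. Spectral conditional
   moments and joint expectations are compared against matrix propagation
   at `two_N = 2000` within 2% (the chain differs from the diffusion at
   `O(1/N)`; validation at smaller `two_N` scales the tolerance as
   `0.02 * 2000 / two_N`).
2. **Monte-Carlo process emulation.** Over a million draws of the full
   data-generating process (stationary frequency → GWA allele count →
   evolved ancient frequency → ancient genotypes and sample frequency)
   check each exact curve within three standard errors.
3. **Closed-form cross-checks.** Beta-binomial tail identities, posterior
   moments of the stationary law, eigenvalue decay of the first moment, and
   the reversibility of the stationary diffusion (checked through the
   chain in both time directions, since the spectral computation is
   self-adjoint by construction).

## Forward simulator

The simulator draws initial counts from the exact discrete stationary law
(for `two_N <= 4000`; otherwise Beta(a, a) rounded to the grid plus a
burn-in), evolves `L` loci for `span` coalescent units (neutrally, then
under genic selection with fitnesses `1 : 1+s : 1+2s`,
`s = sigma/(2*two_N)`, for the final `tau_s` units when `sigma != 0`),
conducts the threshold GWA study on the present-day frequencies, scores
Hardy–Weinberg samples of `n_a` diploids at each requested ancient time,
and records per-replicate bias, mse, sample `r^2`, and estimated additive
genetic variance. All randomness flows from one seed through spawned
per-replicate generators, so studies are bit-reproducible.

## Default scales and their rationale

The full published-figure scale (`K = 5000` replicates of `L = 5000` loci,
`two_N = 2000`) is available through the `fig3`/`fig4` CLI profiles but
takes hours on one CPU. The test suite and worked examples use a reduced
scale — `two_N = 1000`, `L = 500`, `K = 200` — that preserves every
qualitative regime (`a = 1e-3`, thresholds at the same sample allele
frequencies) while running in minutes.

One caveat at the reduced scale matters for interpretation. With `L = 500`
and `a = 1e-3`, the expected number of detected loci per replicate is about
1.4, so many replicates detect no locus at all and have an undefined sample
`r^2`. The study summary excludes those replicates and reports the
exclusion count (`r2_excluded`). This exclusion conditions on the detected
loci still segregating in the ancient sample, which inflates the average
`r^2` relative to `rho^2(tau)` by several standard errors at `tau >= 0.2`;
counting undefined replicates as zero instead deflates it at small `tau`.
The discrepancy is a small-`L` property of the sample statistic, not of the
theory: at `L = 5000` the average `r^2` matches `rho^2(tau)` within
Monte-Carlo error, and at `L = 500` the moment-ratio estimator
`E[Cov(score, phenotype)]^2 / (E[Var score] E[Var phenotype])` — the
quantity `rho^2` actually approximates — agrees with the theory. Accuracy
comparisons at reduced scale should therefore either use the moment-ratio
form or compare simulations against matched simulations rather than against
`rho^2` directly.

## Numerical choices

- All beta-function and binomial-coefficient arithmetic is done in log
  space (`gammaln`, `betaln`) to remain stable at `n = 1e6`.
- Indicator-weighted beta-binomial sums run only over the indicator's
  support.
- The detected-set expectation is computed via its complement
  (`E[Z(1-Z)] - E[miss Z_tau(1-Z_tau)]`), keeping sums over the small miss
  set.
- The dense oracle is guarded at `two_N <= 4000` (memory and cubic solve
  cost); the forward simulator has no such limit.

## Limitations

- Analytic results require symmetric mutation (`mu = nu`) and stationarity;
  asymmetric mutation and non-equilibrium demographies are only available
  through the simulator.
- Selection is available only in the simulator; the analytic curves are
  neutral.
- Effects are shared across time; changing effects, stratification, and
  ancient-genotype measurement error are out of scope.
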