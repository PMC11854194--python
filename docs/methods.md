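# Methods

## Model and fiducial construction

The package targets the Gaussian linear mixed-effects model with a single
grouping level and diagonal random-effect covariance:

    y_i = x_i β + z_i γ_i + e_i,   γ_i ~ N_q(0, diag(δ_1², …, δ_q²)),
    e_i ~ N(0, σ² I_{n_i}),        i = 1..m,  Σ n_i = n > p + q.

Substituting γ_i = diag(δ) U_i with standardized latents U_i ~ N(0, I_q)
turns the random-effect SDs into regression coefficients δ on the columns
z_i diag(U_i).  Conditional on U = u the model is an ordinary linear model
in θ = (β′, δ′)′, and its fiducial quantities are the classical ones: σ²|u
is the residual sum of squares divided by an independent χ²_{n−p−q}
variable, and θ|u is Gaussian around the least-squares estimate with
covariance σ²(X_u′X_u)⁻¹.  Alternating (σ², θ) | u with the Gaussian
conditional of U | η, y forms a reversible chain whose stationary density
is r_y(η) ∝ p(y|η)/σ², where p(y|η) is the likelihood with U integrated
out (per-subject covariance σ² I + z_i D z_i′).  `log_fiducial_density`
evaluates this target directly and `mh_reference_sampler` is an
independent random-walk Metropolis sampler of it; the test suite uses both
to certify the Gibbs chain's stationary law on fixed datasets.

The degrees of freedom n − p − q are fixed by the model dimensions, which
is why construction requires n > p + q — but *not* n_i ≥ q: designs with a
single observation per subject and several random effects are valid, a
regime in which REML/profile-likelihood fitters cannot run at all.

## Trimming (c0)

When a sampled u brings X_u close to interpolating y, the residual sum of
squares collapses and with it the σ² draw, freezing the chain.  The σ²
quantity is therefore drawn from a χ² truncated above at rss/c0 via the
inverse-CDF construction, constraining σ² ≥ c0.  Default c0 = 0.01 (on the
σ² scale).  As c0 → 0 the trimmed draw converges in law to the untrimmed
one (a Kolmogorov–Smirnov test at c0 = 10⁻¹² is part of the suite).  c0
bounds every retained σ² draw from below, so inference on σ cannot resolve
values below √c0 = 0.1; for responses on very small scales, rescale y or
lower c0.

## Sign convention for the latent-effect conditional

The stationary density is exactly symmetric under δ_j → −δ_j: only δ_j²
enters p(y|η).  The U-update uses D^{1/2} = diag(|δ_j|).  This anchors the
orientation of U to the data (the conditional mean of U_i follows the sign
of the residual projection, not the current sign of δ), so each δ_j
marginal of the chain occupies a single side of zero and its histogram is
unimodal.  The alternative — propagating the signed δ_j — makes the chain
wander across both symmetric modes; sign-invariant functionals (|δ_j|, β,
σ²) have the same stationary law either way, but the signed variant's
equal-tailed δ intervals straddle zero even for strong random effects,
which destroys the interval construction for σ_j.  Because the stationary
density is symmetric, anchoring is a labelling convention, not an
approximation.

Interval construction for σ_j works on the δ_j sample: if the sample
median is negative the whole sample is sign-flipped (exact by symmetry),
then the α/2 and 1−α/2 order statistics are taken and the lower endpoint
clipped at max{0, ·}.  An interval for a null component typically becomes
[0, u], covering zero; a genuine component's interval excludes zero.  The
fiducial p-value for σ_j = 0 is the two-sided tail formula applied to the
δ_j draws at 0 and needs no orientation.

## Chain protocol and defaults

* `chain_length` 6000, `warmup` 300, `thin` 3 — the common single-chain
  protocol for this sampler; note floor((6000−300)/3) = 1900 retained
  draws.  Runs meant to yield exactly N = 2000 (the table-replication
  preset) use `chain_length` 6300.
* Per-sweep order: σ² first (trimmed draw), then θ at that σ², then U at
  the new η.  The θ draw requires a σ² value, which fixes the order.
* One seeded RNG stream per sweep component (σ², ζ, U), split from the
  chain seed via `SeedSequence.spawn`; results are bit-reproducible and
  stable under refactoring of any single component.
* (X_u′X_u)^{−1/2} is the lower Cholesky factor of the inverse Gram matrix
  — any square root gives the same Gaussian law; Cholesky is fixed for
  determinism.
* Rank deficiency of X_u (possible only on a measure-zero set of u, hit
  numerically when U draws are tiny): detected by a rank-revealing
  eigendecomposition with singular-value tolerance sqrt(max(n,k)·eps)·s_max
  (the sqrt reflects that singular values are computed through the Gram
  matrix); the sweep then uses the minimum-norm least-squares solution and
  the pseudo-inverse factor, with degrees of freedom kept at n − p − q.
  An exactly zero residual sum of squares triggers up to 10 retries with a
  fresh U, then aborts with a diagnostic.
* Effective sample size (Geyer initial-positive-sequence) is computed per
  marginal after every chain and logged as a warning when small; it never
  alters output.  Low ESS for δ components on tiny datasets is expected —
  the coverage studies below measure the consequences directly.
* Balanced designs run through compiled (numba) kernels that restate the
  numpy sweep arithmetic with explicit loops; a test pins the two paths to
  each other at 1e−9, and unbalanced or ill-conditioned sweeps always use
  the numpy path.

## Interval and p-value conventions

Order-statistic indices are floor(N·α/2) and floor(N·(1−α/2)), 1-based,
clamped to [1, N].  Truncation only ever raises the lower endpoint.  The
p-value uses a strict ">" in one tail and "≤" in the other, so ties at g₀
(measure-zero for continuous draws) resolve conservatively toward the
lower tail.  `summarize` attaches a crude dip-style bimodality flag
(smoothed Freedman–Diaconis histogram, two peaks separated by a ≥25%
trough); a bimodal δ marginal warns that equal-tailed intervals and
two-sided p-values may be inapplicable — with the |δ| convention this is
not expected in practice, but samplers targeting r_y directly can produce
it.

## Synthetic scenarios

The named generators draw covariates i.i.d. standard normal (or use the
1-based subject index as a longitudinal time score), subject effects
γ_i ~ N(0, diag(truth²)) and noise e ~ N(0, σ²I), exactly per their
generating equations:

| name | m | n_i | fixed | random | truth |
|------|---|-----|-------|--------|-------|
| example1 | 10 | 2 | intercept | slope on z | β₀=0.8, σ₁=0.75, σ=0.7 |
| example2 | 10 | 2 | intercept | intercept + slope | adds null σ₀=0 |
| example2_ni4 | 5 | 4 | as example2 | as example2 | as example2 |
| example2_fixedslope | 10 | 2 | intercept + z | intercept + slope | adds β₁=0 |
| example3 | 10 | 1 | intercept + index | intercept + index | β₀=10, β₁=0, σ₀=σ₁=σ=1 |
| gfi / gfi_zero | 10 | 2 | intercept + x | intercept | β₀=0.8, β₁=0.5, δ=0.75 / 0, σ=1 |

These are deliberately tiny designs: they emulate the small-sample regime
the method is for.  They do not emulate features of real grouped data such
as unbalanced group sizes, non-Gaussian noise, covariate–effect
correlation, or crossed grouping factors, so passing coverage here
demonstrates calibration under the model's own assumptions, not robustness
to their violation.

`coverage_study` replicates generate → chain → intervals with
per-replicate RNG streams keyed by (master seed, replicate index), making
results independent of execution order and worker count (joblib optional).
Coverage is the fraction of replicates whose interval contains the truth;
lengths are summarized by the median across replicates.  `power_study`
reports rejection rates of the δ_j = 0 fiducial test at α under null and
alternative processes, alongside fixed-effect tests.

## Problem sizes used in the shipped studies

The replication suite and `scripts/acceptance.py` run R = 300–500
replicates per scenario with chains of 2100 sweeps (300 warmup, thinning
2; 900 retained draws per fit).  At these sizes a coverage estimate
carries binomial standard error ≈ 0.01–0.016 and the study-level checks
use ±0.04 coverage bands and ±10–15% length bands.  A full-scale preset
(R = 1000, N = 2000 via chain length 6300) is exposed through the CLI's
`--preset full`.

## Known limitations

* Diagonal D only: correlated random effects would require a fiducial
  density on the correlation matrix and a three-block sweep; out of scope.
* Single grouping level; no crossed or nested factors, no R-style formula
  parsing.
* The Gibbs chain mixes slowly on weakly identified δ components; ESS
  warnings flag this, and longer chains are the remedy.
* σ² inference is floored at c0; see the trimming note.
* Comparator methods (REML profiling, Bayesian fits, bootstrap, interval-
  data generalized fiducial software) are not reimplemented; the harness
  can export its replicate datasets as CSV so external tools can be run on
  identical data.
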