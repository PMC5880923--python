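# Methods

## Model family

An analysis model (`ModelSpec`) is a polynomial latent growth model for
`t ≥ 3` complete repeated measures:

* **Mean structure** — μ = Λα with Λ the polynomial basis in time codes
  0, 1, …, t−1 (entry `(i, j) = i**j`), order `q` ≤ t−1.  The
  measurement intercepts τ are fixed to zero, so α₀ is first-wave
  status — standard LGM practice and the identification convention
  assumed throughout.
* **Between-subject covariance** — Ψ over the growth factors, governed
  by a policy.  `full_identified` (default) keeps a full Ψ over the
  largest leading block of factors that passes moment counting
  (`k < t + t(t+1)/2`, with structural caps: at most t−1 random
  effects; none at all under an unstructured Θ, which absorbs ΛΨΛ′).
  Higher-order factors keep a fixed-effect mean.  `match_mean` demands
  Ψ over every factor and errors when unidentified; `none` drops Ψ.
* **Within-subject covariance** — Θ from one of four families: ID
  (σ²I, 1 parameter), AR(1) (σ²ρ^|i−j|, 2), UN(1) (free diagonal, t),
  UN (free PSD matrix, t(t+1)/2).

Implied covariance: Σ = Λ_r Ψ Λ_r′ + Θ.  Free parameters
k = (q+1) + |Ψ| + |Θ|; degrees of freedom df = t + t(t+1)/2 − k.

## Estimation

`fit_ml` minimizes the normal-theory discrepancy

    F_ML = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) + (ȳ−μ(θ))′ Σ(θ)⁻¹ (ȳ−μ(θ)) − ln|S| − t

with S the divisor-n sample covariance (the ML convention; using n−1
would shift χ² slightly).  The log-likelihood retains the
−(nt/2)·ln 2π constant so AIC = −2ℓ + 2k and BIC = −2ℓ + k·ln n are
comparable across software, and χ² = n·F_ML at the optimum.

Numerical choices:

* Unconstrained transforms: log variances, atanh ρ, Cholesky factors
  with log diagonals for Ψ and an unstructured Θ.
* The polynomial basis is QR-orthonormalized internally (raw time-code
  powers reach (t−1)^q and condition the surface badly); estimates are
  mapped back to the raw basis on exit.
* L-BFGS-B with analytic gradients; moment-based starts (OLS growth
  coefficients, residual moments); up to 3 jittered restarts.
  Convergence = projected-gradient norm < 1e−5 (default) — projection
  treats a variance pinned at its bound (a boundary/Heywood-type
  solution) as converged.  Non-convergence is reported via a flag,
  never an exception.
* Degenerate input (singular S, n ≤ k) is rejected with a named error.

Indices: CFI against an independence baseline (free means and
variances, zero covariances — closed form, k = 2t); RMSEA =
√(max(χ²−df,0)/(df·n)) with the df = 0 convention RMSEA = 0, CFI = 1;
SRMR averages squared standardized residuals over the t(t+1)/2 unique
covariance elements **and** the t means (the mean structure is the
search target; a covariance-only SRMR is blind to it — switchable via
`FitOptions.srmr_include_means`).  LRT uses the χ² difference with
α = 0.05 (the conventional level; the sources using these rules do not
state one).

A caution surfaced by testing: with an AR(1) Θ plus random
intercept/slope the likelihood is near-flat along a trade between Ψ₁₁
and (σ², ρ) — estimates of that split can wander far from the
population values at realistic n even when the fit is at the true ML
optimum.  Selection criteria are unaffected (they depend on the
maximized likelihood), but individual parameter estimates from that
combination should be read with care.

## Search

Starting models: 1 = (intercept-only, ID), 2 = (highest order, ID),
3 = (intercept-only, UN), 4 = (highest order, UN, the "fully
saturated" start).  The residual structure stays fixed within a
search; all search models are unconditional (covariates excluded).
The maximum order defaults to t−2 for both residual structures: under
UN it leaves one degree of freedom for fit statistics, and under ID it
keeps the top model comparable (a t−1 mean with a full Ψ is
unidentified at t = 4).  Step-up compares order q against q+1 from
q = 0 and advances while the complex model wins; top-down compares
q−1 against q from the top and descends while the simpler model wins;
both stop at the first contrary decision (no re-testing after a stop).
A nonconverged fit loses its comparison — the decision falls to the
simpler model and the search result is flagged; the harness keeps
flagged records in denominators by default (an intent-to-analyze
convention; a switch excludes them).

## Synthetic populations

The generator emulates a two-trajectory factorial design:

| factor | levels |
|---|---|
| trajectory | linear, 4 waves (true order 1); quadratic, 8 waves (true order 2) |
| residual structure | ID (variance 1.00); AR(1) (variance 1.00, ρ = 0.50); UN(1) (variances 1.00·0.80^(j−1)) |
| covariate effect γ | 0.1, 0.3, 0.5 |
| sample size n | 100, 210, 390 |

Total factor covariance: intercept variance 0.20, growth-term
variances 0.10, all factor correlations 0.35 (linear: off-diagonal
0.05; quadratic: linear–quadratic covariance 0.035).  Growth-factor
means default to α = (1.0, 0.5) and (1.0, 0.5, 0.1) — configurable,
and deliberately so: hit rates for the quadratic population at small n
are sensitive to the quadratic mean (see limitations).

The covariate w ~ N(0,1) loads equally on every factor.  Two readings
of γ are implemented.  **standardized** (default): γ is the
factor–covariate correlation, Γ_j = γ·√Ψ_jj and Ψ_ζ = Ψ_total − ΓΓ′,
so the *total* factor covariance equals the printed matrix for every
γ.  The naive alternative — a constant raw coefficient on top of the
printed totals — turns negative-definite at γ = 0.5 (0.20 − 0.25 < 0),
which is why the standardized reading is the default; the **raw** mode
is retained for sensitivity analysis with the printed matrix treated
as the residual covariance.  A consequence of the standardized
reading: the marginal distribution of y is identical across γ, so
unconditional-search hit rates differ across γ only through seed
noise.

Seeding: every dataset's seed derives from
`SeedSequence((master_seed, cell_index, replicate))`, so any single
dataset is regenerable in isolation and full runs are byte-identical
for a fixed master seed.

What the generator does **not** emulate: non-normal outcomes, missing
data, time-varying covariates, unequal covariate loadings across
factors, non-polynomial (piecewise/exponential) trajectories.  Passing
tests therefore speak to the search machinery under clean multivariate
normality, not to robustness against those features of real data.

## Problem sizes used in the checks

The full factorial with 1,000 replications (54,000 datasets) is the
design the harness enumerates; the standing test and acceptance runs
use 50 replications per cell (2,700 datasets) for the saturated-start
ΔBIC hit rate, 2,000 replications for the LRT type-I calibration at
n = 390, 50 random instances for the GLS-oracle equivalence check, and
n = 100,000 subjects for the generator's moment checks.  Hit rates are
binomial, so 50 reps/cell carries a Monte Carlo standard error of at
most ≈ 7 points per cell and ≈ 1 point on the 54-cell average.

## Known limitations

* The quadratic-population hit rate of the saturated ΔBIC search is
  limited by the default quadratic mean (0.1): the quadratic signal it
  leaves after orthogonalization against the lower orders is modest
  relative to the quadratic-factor spread, so the ΔBIC ≥ 2 retention
  rule under-selects order 2 in the small-n cells.  The acceptance run
  reports the resulting 54-cell average; it is sensitive to this one
  default, which is kept deliberately and exposed via
  `PopulationCondition.alpha`.
* `match_mean` + AR(1) combinations are estimable but weakly
  identified (see the caution above).
* The search does not explore residual structures; choosing Θ after
  the mean structure is a separate task outside this package's scope.
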