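# Methods notes

## Model and assumptions

The demographic model is the two-species Beverton–Holt annual-plant map.
Within a growing season, a focal germinant of species *x* produces

    F = lambda_x / (1 + alpha_x,intra * N_intra + alpha_x,inter * N_inter)

seeds in expectation, where neighbour densities are plants per pot (or per
plot). Germination fractions `g` are estimated from binomial trials but are
not folded into the coexistence formulas by default (see below). The model
deliberately has **no seed-bank survival term**: both species are treated
as lacking dormancy, so there is no temporal storage effect in the model
and the long-term prediction rests entirely on `lambda`, the four `alpha`s
and their uncertainty.

Conventions: species *i* is the native (*P. congesta*) and *j* the
introduced (*V. locusta*); `alpha_xy` is the effect **on** *x* **of** one
*y* individual. The fitness ratio is reported as *j* over *i*; the
competitive-response ratio as *i* over *j* (values < 1 mean the native is
less sensitive to competition); invasion growth rates are labelled by
invader into resident.

## Estimation

Each focal species × treatment is fitted as a single joint likelihood over
all of its pots: the no-neighbour pots anchor `lambda` for both the
conspecific and heterospecific density gradients simultaneously, which is
why the two `alpha`s cannot be estimated from separate per-gradient
regressions. The error model is NB2 (`Var = mu + mu^2/theta`), with
`theta` estimated jointly.

Numerical choices:

- optimisation over `(log lambda, log alpha_intra, log alpha_inter,
  log theta)` with L-BFGS-B, relative-likelihood tolerance `1e-8`; the log
  scale for the alphas enforces competitive (non-negative) interactions,
  which matches all reference estimates. `allow_negative_alpha=True`
  switches the alphas to an identity scale (facilitation permitted) with a
  warning.
- multi-start: `lambda_0` = mean seed count of the N=0 pots; `alpha_0` in
  {0.01, 0.1, 1} (both alphas together); `theta_0` by method of moments
  from the N=0 pots, clipped to [0.2, 50].
- covariance: inverse observed information (numerical Hessian of the
  negative log-likelihood at the optimum), delta-method-mapped to the
  natural scale. Hessians use a relative step of `1e-4`; second
  differences at smaller steps are dominated by floating-point
  cancellation. First-order gradients elsewhere use central differences at
  relative step `1e-6`.
- pots with zero seed counts are retained (NB2 has mass at zero); rows
  with missing seed counts are dropped with a logged count.

The bootstrap resamples pots with replacement **within each neighbour-type
× density cell**, so every replicate retains the experimental design; the
resampling unit is the pot (residual resampling would presume a correctly
specified mean everywhere). Replicates are warm-started at the full-data
optimum; non-converged replicates are flagged, excluded from summaries and
counted. Headline estimates are reported as bootstrap means with the
bootstrap SD as SE — mirroring the provenance of the reference estimates —
while full-data ML estimates and observed-information SEs are retained
alongside, labelled `*_ml`.

## Coexistence algebra

The formulas in the README are implemented as pure functions; the identity
`kappa_j/kappa_i = demographic ratio × competitive response ratio` holds
exactly (same floating-point expression), and the equivalence between the
`rho < kappa < 1/rho` condition and mutual invasibility is exercised as a
property test over random admissible parameter sets. Classification at a
boundary (`|kappa - rho| < 1e-9`, or `rho = kappa = 1`) returns
`indeterminate` rather than an arbitrary side.

Germination: the reference demographic ratios are ratios of `(lambda - 1)`,
not `(lambda g - 1)`, so `g` is estimated and reported but not applied by
default. `summarize_pair(..., germination=(g_i, g_j))` computes the
`eta = lambda g` variant for sensitivity analysis.

Reporting rounds to 2 decimals; all internal computation is full
precision.

## Uncertainty propagation

Three routes, in decreasing order of preference for reporting:

1. **Paired bootstrap** (default): each derived metric is evaluated on the
   replicate-paired parameter sets of the two focal fits; SE is the
   replicate SD. Cross-species pairing carries no dependence by
   construction (the two focal species are separate fits); inadmissible
   replicates are dropped and counted.
2. **Taylor (delta method)**, order 1 or 2, through a block-diagonal
   covariance (the two fits treated as independent — the shared N=0 pots
   induce dependence only within a focal species, an approximation noted
   here). Order 2 adds `tr((H S)^2)/2` to the variance and `tr(H S)/2` to
   the mean.
3. **Monte Carlo**: multivariate-normal parameter draws (default `1e5`),
   with domain-violating draws rejected and counted; > 50 % rejection
   aborts, since the normal-propagation regime is then invalid. Used as
   the oracle for the Taylor routes; at the reference estimates all three
   agree within ~5 % relative SD.

Covariance inputs may be full or diagonal; the `table1-check` mode uses
diagonal covariance built from the published per-parameter SEs, since the
published table reports no cross-covariances.

## Synthetic data: what it emulates, what it does not

The pot generator reproduces the published design exactly: per focal ×
treatment, 16 no-neighbour pots, 12+12 at density 4, 8+8 at 10, 8+8 at 20
(72 pots; 288 total), with NB2 seed counts around the Beverton–Holt mean.
Defaults are the reference parameter estimates; the NB2 dispersion is not
published, so the generator defaults to `theta = 5` — strongly
over-dispersed, count-realistic — and is configurable. Neighbour densities
are exact post-thinning counts, not germination realisations. Germination
trials are binomial, 72 pots × 3 seeds per species (the error distribution
for germination is not stated in the source; binomial is the natural
choice for per-seed success).

The field generator produces 70 1-m² plots, each with two nested 0.1-m²
subplots (140), across 2 sites × 5 transects, with log-link NB2 abundances,
Gaussian site/transect random intercepts, a configurable cross-species
coefficient on the log scale (negative by default, reproducing the inverse
abundance pattern), binomial area-thinning for subplot counts, and
per-individual fecundity proxies with height-driven seed output plus an
interspecific-only density penalty on the introduced species.

Not emulated: spatial autocorrelation within transects, weather/soil
physics, seed dispersal, observation error in the proxies, and any
temporal dynamics. Passing tests therefore demonstrate that the estimators
recover the generating process under design-faithful sampling noise — not
that field data satisfy the model.

## Field GLMs

NB2 GLMs with log link, dispersion estimated by ML jointly with the
coefficients. Random effects for site/transect are approximated by
categorical fixed adjustments — the inferential targets here are
fixed-effect signs and likelihood ratios, and the approximation keeps the
artifact dependency-light; outputs record the grouping factors used. AIC
is `2k - 2 logL` with `k` counting the dispersion parameter; model
selection walks candidates from simplest to most complex and accepts a
more complex model only when it lowers AIC by more than 2. LRT p-values
are chi-square upper tails of `2 Δ logL`.

The best-supported proxy structures are encoded as defaults for the two
species: seed count ~ height for the native; ~ inflorescences + height +
inflorescence size for the introduced species.

## Problem sizes in tests

Stochastic checks use sizes chosen to bound Monte-Carlo error while
keeping the suite quick: 20 simulated experiments for parameter recovery
(median relative error thresholds 10 % for `lambda`, 30 % per `alpha`),
`1e5` draws for Monte-Carlo propagation oracles, 1 000 plots for
field-sign recovery, 100 simulations for the AIC selection-consistency
check, and a 4-D grid-search likelihood oracle on ~30-pot fixtures.

## Known limitations

- Two species only; no generalisation to guilds.
- The pot likelihood has no random effects (none are needed for a
  single-bench pot design).
- Taylor propagation assumes mild nonlinearity at the estimate; the
  Monte-Carlo oracle and rejection accounting are the guardrails.
- The `rho`/`kappa` ↔ invasion-rate equivalence is exact for this model
  family but not for other competition kernels.
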