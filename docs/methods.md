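# Methods

## The problem

Across birds and mammals, adult survival differs systematically between
the sexes, and competing evolutionary explanations — precopulatory sexual
selection (size dimorphism, mating system, plumage dichromatism),
postcopulatory sexual selection (relative testis mass as a proxy for
sperm competition), and the female cost of reproduction — make different
predictions about which sex dies faster and why.  `alediff` implements
the full quantitative chain needed to test these predictions: per-species
Bayesian estimation of sex-specific mortality trajectories from
individual records, a proportional sex-difference statistic on adult life
expectancy, approximations for published wild-population data, and a
weighted Bayesian phylogenetic regression of the sex difference on
life-history predictors.

## Mortality model

Age-specific mortality follows the five-parameter Siler (bathtub) hazard

    mu(x) = exp(a0 - a1 x) + c + exp(b0 + b1 x)

with `a0, b0` unbounded (log-scale levels of the juvenile and senescent
components) and `a1, c, b1 > 0` (juvenile decline rate, constant
background hazard, senescence rate; all rates in 1/years).  Every term
integrates in closed form, so survival `S(x) = exp(-H(x))` is exact:

    H(x) = e^{a0}/a1 (1 - e^{-a1 x}) + c x + e^{b0}/b1 (e^{b1 x} - 1)

Adult life expectancy (ALE) conditional on reaching the age at first
reproduction `alpha` is

    e = Integral_alpha^inf S(t) dt / S(alpha)

computed by adaptive quadrature (absolute/relative tolerance 1e-8) with
the infinite upper limit replaced by the age where conditional survival
falls below 1e-9 of `S(alpha)`, found by bracketed root finding on the
closed-form cumulative hazard — the rising senescent term guarantees
such an age exists.  Ages are continuous years throughout; no
discretization is imposed anywhere in the likelihood or the ALE
integral.

Exact sampling of ages at death uses the inverse-CDF identity
`H(x) - H(alpha) ~ Exponential(1)` solved by vectorized bisection to
1e-8 years, so simulated cohorts follow the model distribution without
rejection tuning.

## Survival estimation

Individual records carry `(entry_age, end_age, event)`.  Deaths
contribute `log[mu(end) S(end)/S(entry)]`, right-censored animals (alive
at data extraction) `log[S(end)/S(entry)]`; conditioning on survival to
the entry age handles left truncation at `alpha`.  Both sexes of a
species are fitted at the same `alpha` (the larger of the two sexes'
values) so their ALEs are comparable.

Inclusion rules before fitting: an observation-window filter, removal of
life spans strictly above the species' 99th percentile (linear-
interpolation quantile, computed among deaths), and a minimum of 35
individuals per sex.  The age at first reproduction is the lower 10%
quantile (same quantile definition) of individual ages at first
offspring.

The sampler is component-wise Metropolis-Hastings with weakly
informative priors: `a0, b0 ~ Normal(-3, 2)` and
`a1, c, b1 ~ Normal(0.01, 1)` truncated to `(0, inf)`.  Proposal scales
adapt during burn-in only (multiplicative updates every 50 iterations
toward a 0.20-0.30 acceptance window) and are frozen afterwards to
preserve detailed balance.  Updates of the rate parameters `a1` and
`b1` move along the (level, rate) likelihood ridge: the paired level
parameter is shifted so the term's log hazard at a reference age (the
minimum entry age for the juvenile term, the mean observed end age for
the senescent term) stays constant.  This is a linear unit-Jacobian
shear of the parameter space, so the Metropolis ratio is unchanged while
mixing of the strongly correlated `(b0, b1)` pair improves by roughly an
order of magnitude.

Convergence is monitored with the classic Gelman-Rubin potential scale
reduction across parallel chains (threshold 1.1); a fit exceeding it is
returned flagged, never silently.  The library default protocol is 8
chains of 60,000 iterations, burn-in 10,001, thinning 100; tests and
examples use `MCMCConfig.test_scale()` (4 chains of 6,000, burn-in
1,001, thinning 10), which the calibration experiments below show is
sufficient at the sample sizes involved.

Two data-quality gates replace subjective trace inspection: (i) the
left-truncated product-limit (Kaplan-Meier) survivorship of the observed
data must drop to at most 0.1 by the oldest observed age — otherwise too
little of the mortality trajectory is observed to trust extrapolated
ALE (the direction of this rule is configurable because either reading
is defensible); (ii) `fit_discrepancy` reports the maximum absolute gap
between the product-limit curve and the posterior-mean fitted survival.

ALE is recomputed per retained posterior draw, giving a posterior ALE
sample per species-sex.

## The sex-difference statistic

    delta_e = (e_f - e_m) / max(e_f, e_m)   in [-1, 1]

applied draw-wise to paired posterior ALE samples.  `delta_e` is
antisymmetric under sex relabelling and invariant to rescaling both
expectancies; `P = 100 |delta_e|` is the percent advantage of the
favored sex (females when positive).  Evidence that `delta_e` differs
from zero is the *zero overlap*: twice the smaller of the posterior
masses below/above zero (values <= 0.05 read as strong, <= 0.125 as
moderate evidence; the undoubled tail is available for sensitivity).
Group (class/order) summaries are inverse-SD-weighted means with
SE = sqrt(weighted variance / n_eff), n_eff = (sum w)^2 / sum w^2, and
normal-approximation 95% CIs (multiplier 1.96).

## Wild-data approximations

Published wild data rarely include individual records.  From an annual
adult mortality probability `qa`, survivorship is `lx = (1-qa)^x`
(equivalently a constant hazard `b = -log(1-qa)`), and
`e ~= sum_x lx` up to the species' maximum age.  The sampling variance
uses Chiang's approximation

    var(e) ~= sum_x lx^2 [(1-ax) + e_{x+1}]^2 [qx^2 (1-qx) / Dx]

with `ax = 0.5` the fraction of the interval lived and `e_{x+1}` the
half-interval-adjusted (Chiang) remaining expectancy; with that
convention the bracket equals the plain tail sum of the `lx` series over
`l_{x+1}`, and the formula is exactly the delta-method variance of the
`sum lx` estimator under independent binomial death counts — verified
here against a Monte Carlo bootstrap.  `qa` may be age-constant (as in
the constant-hazard pathway) or an age-specific vector.

Full life tables are converted to pseudo-cohorts by
`Nx = floor(N lx)`, `Dx = Nx - N_{x+1}`, with deaths placed at the
interval start (configurable to `x + ax`) and survivors past the final
age emitted as censored — record counts are preserved exactly.
Reported Siler parameters (the wild-mammal pathway) are turned into
simulated cohorts by exact sampling and refitted like any other data.

## Weighted Bayesian PGLS

The comparative model is

    y ~ MVN(X beta, sigma^2 W^{-1/2} C(lambda) W^{-1/2})

where `C` is the Brownian-motion correlation implied by an ultrametric
tree (shared root-to-MRCA depth over tree depth), Pagel's `lambda`
multiplies its off-diagonals, and the weights

    v_i = log(1/sigma_i + 1),  omega_i = v_i / max(v)

downweight species with large posterior SEs `sigma_i` of `delta_e`
(residual variance of species i scales with `1/omega_i`).  The weight
definition fixes `omega` but not where it enters the covariance; the
symmetric `W^{-1/2} C W^{-1/2}` sandwich is the standard weighted-GLS
contract and is isolated in one place so it can be swapped.

Priors: `beta ~ Normal(0, variance 100)` per coefficient,
`sigma^2 ~ inverse-gamma(0.01, 0.01)`, `lambda ~ Uniform(0, 1)`.
Sampling is Gibbs for `beta` (conjugate multivariate normal) and
`sigma^2` (conjugate inverse-gamma) with reflected-normal
Metropolis-Hastings for `lambda` (proposal scale adapted in burn-in).
Writing `C = Q L Q'` once gives
`C(lambda) = Q (lambda(L-1)+1) Q'`, so after a single O(n^3)
eigendecomposition every iteration costs O(np); the MH sampler was
validated against brute-force grid integration of the marginal
likelihood.  Default chain: 12,000 iterations, burn-in 2,000, thinning
5.

Model comparison uses DIC = mean deviance + pD with Spiegelhalter's
pD = mean deviance - deviance at the posterior means (not the
half-variance variant).  Mammal and bird trees are grafted under a
common root of age 319 MY (each crown attached by a stem preserving its
depth) for combined-class models.  The allometric exponent relating male
to female mass (or testis to body mass) is recovered from the additive
log-mass coefficients as `gamma = -beta2/beta1`.

## Covariate coding

Monogamy: 1 iff both sexes exceed the threshold fraction (default 0.80;
0.95/0.99 for sensitivity) of socially monogamous individuals; bird 0-4
ordinal scores are mapped to fractions as score/4 (the original source's
exact mapping is not published, so the linear map is used and
documented).  Parental care: female-care indicator for scores > 0 on
the [-2, 2] scale (cutoffs +-0.5, +-1 supported).  Annual productivity:
neonate/egg mass x litter/clutch size x litters/clutches per year;
non-positive values are excluded from log-scale designs with a report
entry.  Hypothesis designs: precopulatory (log male mass, log female
mass, monogamy, optionally dichromatism in birds-only runs),
postcopulatory (log male mass, log testis mass, monogamy), cost of
reproduction (log female mass, log age at first birth, log productivity,
female care); class enters as an intercept indicator or full
interactions, and a hunted flag with hunted x monogamy is available for
wild-data sensitivity models.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analysis assumes:
Siler death ages truncated at `alpha` with uniform right censoring;
pure-birth (Yule) ultrametric trees; responses with
`lambda`-structured phylogenetic residuals plus independent per-species
observation noise (the layer the regression weights absorb); and
power-law allometry with phylogenetically correlated deviations.
Presets: "mammal-like" (a0=-2, a1=1, c=0.01/yr, b0=-5.5, b1=0.15/yr; ALE
~17 y from alpha=2) and "bird-like" (c=0.03/yr, b1=0.25/yr; faster).

They deliberately do not emulate: uncertain or missing birth dates
(latent-age estimation is out of scope), institution transfers and
record-keeping artifacts, taxonomic synonymy, non-uniform censoring
processes, or model misspecification (real hazards are not exactly
Siler).  Passing tests therefore demonstrate correctness of the
estimators under their own assumptions — calibration, invariances, and
oracle agreement — not robustness to every feature of real census data.

## Problem sizes used in tests

Simulation-based calibration runs 20 replicates of n=1000 deaths at 4
chains x 6,000 iterations; BPGLS recovery uses 20 replicates of 200
tips; the planted comparative effect (-0.06 on the monogamy indicator,
lambda=0.8, residual SD 0.1, per-species SEs U(0.02, 0.08) — scales
chosen to match realistic delta_e posteriors) uses 20 replicates of 300
species on a grafted two-class tree, with delta_e observations generated
from the regression observation model.  The survival -> delta_e stage is
round-tripped separately on 10 species at 500 individuals per sex with
20% censoring.  These sizes make the posterior informative enough that
coverage and sign checks are sharp while each replicate remains a
desk-scale computation.

## Numerical choices and edge cases

- Quadrature/root-finding tolerances: 1e-8; sampling bisection: 1e-8
  years; survival underflow below ~exp(-700) raises a degenerate-
  survival error rather than returning 0-divisions.
- Quantiles (10% age at first reproduction, 99% outlier rule): linear
  interpolation between order statistics; the outlier rule removes
  values strictly above the quantile.
- Identical MCMC chains give a Gelman-Rubin statistic of
  sqrt((n-1)/n), marginally below 1.
- `lambda` proposals are reflected at 0 and 1; eigenvalues of
  `C(lambda)` are floored at 1e-12 before inversion.
- Grafting requires disjoint tip sets, ultrametric crowns (1e-3
  relative tolerance) and crown depths not exceeding the root age.
- Singular designs are rejected with the rank reported; a zero
  `beta1` makes `gamma` undefined and raises.

## Known limitations

- The Metropolis sampler is random-walk; species with very flat
  likelihoods (tiny samples, heavy censoring) may need longer chains
  than the test-scale settings.
- The weighted-covariance insertion point and the zero-overlap doubling
  are documented conventions, not uniquely determined by the source
  material; both are configurable.
- DIC is computed from retained draws; with heavy thinning pD has Monte
  Carlo noise of a fraction of a parameter.
- Wild approximations assume the reported `qa` applies from the source's
  age at first reproduction onward and ignore sampling error in `qa`
  itself beyond the Chiang term.
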