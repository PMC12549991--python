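# Methods

`lekdemog` implements a hierarchical Bayesian analysis of population- and
life-stage-level demography for lek-breeding birds (the motivating system is
the greater sage-grouse, *Centrocercus urophasianus*, censused by annual
maximum male counts at leks). Two model families sit at its core, joined by
covariate engineering, two-stage variable/scale selection, and a synthetic
data generator that makes every stage verifiable by parameter recovery.

## Population state-space model

For lek *i* in region *R(i)* and year *t*, latent apparent abundance
follows a log-scale random walk with covariate-dependent drift and Gompertz
density dependence:

    log N[i,t+1] = log N[i,t] + r[i,t]
    r[i,t] ~ Normal(mu_r[i,t], sigma_r[i]^2)
    mu_r[i,t] = alpha_R + X[i,t]' beta_R + theta_R * log N[i,t]
    y[i,t] ~ Poisson(N[i,t])

Counts are an unbiased Poisson index of abundance (constant detection and
attendance over the series is assumed, as in any lek-count analysis).
`theta_R < 0` produces stationary log-abundance dynamics with noise-free
equilibrium `log N* = -alpha/theta`; in the no-covariate case log N is an
AR(1) process with slope `1 + theta` and stationary standard deviation
`sigma_r / sqrt(1 - (1+theta)^2)`. Both closed forms are used as simulation
oracles in the tests.

The density term multiplies `log N[i,t]`, the abundance at the *start* of
the t -> t+1 transition — i.e., the prior year's density relative to the
resulting count. A variant where the density covariate is centred (mean
observed log-count subtracted) is available via `SSMConfig.center_density`
for users who prefer intercepts interpretable at average density; it is a
reparameterization, not a different model. `theta * N` (Ricker-type) is
available via `density_on_log=False`.

Region-level parameters are hierarchical: `alpha_R ~ Normal(mu, sigma^2)`,
`beta[k,R] ~ Normal(mu_beta_k, sigma_beta_k^2)`. Hyperpriors are vague
Normal(0, 5^2) on means and half-Normal(1) on all standard deviations;
`theta_R ~ Normal(0, 5^2)` independently per region. These are documented
stand-ins chosen to be diffuse relative to plausible growth-rate effects
(|r| rarely exceeds 1 on the log scale). The latent initial condition is
`log N[i,1] ~ Normal(log(y_first + 1), 1)` — weakly data-anchored and
proper at zero counts. Reporting defaults to the grand means `mu`,
`mu_beta_k` rather than region-specific effects. With a single region the
hierarchy collapses (with a warning) to vague non-hierarchical priors.

### Sampler

Gradient-based samplers were not used; the SSM is fitted by blocked
Metropolis-within-Gibbs designed around the model's conditional structure:

* latent `log N[i,t]`: single-site Metropolis in a red-black (even/odd
  year) schedule — sites of one parity are conditionally independent given
  the other, so all are updated simultaneously with vectorized accept
  ratios; per-site proposal scales adapt toward 0.44 acceptance during
  burn-in only;
* `(alpha_R, beta_R, theta_R)`: exact conjugate multivariate-normal Gibbs
  draws per region (the growth rates are linear-Gaussian in these given the
  latents);
* hypermeans: exact conjugate normal draws;
* all standard deviations: log-scale random-walk Metropolis with the
  multiplicative-proposal Jacobian.

Summaries are gated on convergence: `SSMFit.summarize()` refuses (unless
forced) while any top-level R-hat >= 1.1.

## Logistic-exposure survival models

For an encounter interval of `t` exposure days with covariates `x`:

    eta = beta0 + x' beta
    DSR = logit^-1(eta)        (daily survival rate)
    S   = DSR^t                (interval survival)
    y ~ Bernoulli(S)

Cumulative stage survival is DSR raised to the stage horizon — 38 d
(nest incubation), 50 d (brood-rearing), 167 d (the day-75-to-242
reproductive season for adults/yearlings). The identity `S = DSR^t` holds
per posterior draw, never only in summary. Derived DSR is reported at the
reference point: standardized covariates at 0, indicators at their
reference level — numerically the inverse-logit of the intercept, which
makes derived survival directly comparable with tabled field estimates
(agreement <= 1e-3 at the stage intercepts).

Stage designs mirror the fitted field models: nest — 7 covariates, no
interactions (8 coefficients); brood — 10 environmental mains, day of
season, hen age, brood age, and 5 interactions (19 coefficients); adult —
11 mains, sex, and an SPEI-by-day-of-season interaction (14 coefficients).
Brood interval success means >= 1 chick alive; chick-level survival is not
modelled. Brood/adult covariates represent the window preceding each
observed location. No site/year random effects are fitted: shrinkage
carries the hierarchical structure, matching the fixed-effects-plus-Λ
reporting convention.

Non-intercept coefficients carry a Laplace (double-exponential) shrinkage
prior with density proportional to `exp(-Λ|β|)`; Λ has a Uniform(0.01, 10)
hyperprior and is drawn by its exact conditional — a Gamma(k+1, Σ|β_j|)
truncated to the prior support. The intercept is Normal(0, 10^2). The
linear predictor is clipped at |eta| = 35 before the inverse logit; at
double precision this is inert below ~1e-15.

Coefficient blocks are sampled with adaptive random-walk Metropolis
(Haario empirical-covariance adaptation plus Robbins–Monro step-size
tuning, frozen after burn-in), initialized at the penalized posterior mode
with the BFGS inverse-Hessian seeding the proposal covariance. Sampling
uses a centered design parameterization (columns shifted to mean zero) to
decorrelate slopes from the intercept; intercept draws are shifted back
afterwards, an exact reparameterization.

## Covariate engineering

Landscape covariates are summarized in circular moving windows (mean of
cells whose centres fall within the radius; cells off the grid excluded
from numerator and denominator). Candidate radii are 2.5/5/10 km for
population covariates and 75/167/260/370/439/1451 m for life-stage
covariates; 1439 m is accepted as an alias of the largest radius, for
which both figures circulate. Proximity covariates use
`exp(-d/alpha)` with alpha from the life-stage set. Coarse (4 km) climate
grids are sampled at the focal location without a moving window.

Lag windows for a population response in year *t* (spring lek count):
previous calendar year = 14 Mar *t-1* .. 14 Mar *t*; water year = 1 Oct
*t-2* .. 30 Sep *t-1*; growing season (1 Apr–31 Oct), spring (1 Mar–31
May), summer, and fall resolve to those seasons of *t-1*; winter = 1 Dec
*t-1* .. end Feb *t*. The calendar mapping of "previous" windows is fixed
here (and surfaced in config) on the rationale that prior-year moisture
drives current-year abundance with lags of 0–1.5 years. The winter window
ends 29 Feb in leap years — a no-data-loss extension of the nominal
28 Feb endpoint. Survival-model concurrent windows (current month, previous month,
Mar–May spring) resolve from the encounter interval's midpoint date; the
reference-date convention (start vs midpoint) is genuinely open, and
midpoint was chosen as the least biased for multi-week intervals.

Precipitation aggregation defaults to the mean of monthly totals so
windows of unequal length are comparable; a cumulative-sum mode is provided
because per-cm effect statements imply totals. Monthly temperature extrema
use min/max modes. All covariates are z-scored (sample sd, n-1); the
(mean, sd) pair is retained and reused verbatim for prediction inputs.

## Two-stage variable and scale selection

The selection procedure is this package's own explicit, configurable
formulation of two-stage shrinkage selection:

1. candidates are partitioned by |pairwise r| >= 0.65 (graph components,
   so correlation chains merge transitively);
2. stage 1 fits one group at a time with all members' scale variants as
   alternatives under the shrinkage prior; each covariate keeps the scale
   with maximal pd (ties toward the smaller, more local scale) and is
   retained if pd >= 0.80; covariates whose sign flips between the group
   fit and a solo fit are flagged confounded and omitted;
3. stage 2 refits the retained set jointly under Laplace(Λ) priors with
   Λ ~ Uniform(0.01, 10).

The constants are consistent with a two-stage shrinkage description and
with fitted Λ posteriors in this problem class spanning roughly 4–10
(hence an upper prior bound near 10); all are config knobs and logged. Under an all-null
simulation the expected stage-1 retention rate per covariate is roughly
Pr(pd >= 0.8 | null) ≈ 0.4 — screening is deliberately permissive, with
stage 2 doing the shrinking. Spike-and-slab selection, model averaging,
and WAIC/LOO ranking are out of scope.

## Synthetic data

The generator is first-class, tested code. Defaults define the package's
study conditions at desk scale: 3 regions x 60 leks x 20 years of counts
(missingness 15%, a typical survey-gap rate for long lek series), and 300
nests / 200 broods / 400 adults. SSM truth defaults are `mu_alpha = 0.5`,
`theta = -0.1` (equilibrium ~148 males), `mu_beta = (0.05, -0.03, 0.02)`,
between-region sds 0.05/0.02, process sd 0.1 — effect sizes chosen so the
equilibrium matches the worked closed-form example and covariate effects
are of the few-percent-per-sd order seen in lek-count analyses. Survival
truths are the fitted field coefficient tables themselves (intercepts
3.460/4.470/6.350 etc.), so simulated hatch rates and cumulative survival
match the corresponding field-scale derived estimates. Nest visits are
every 4 days; brood and
adult relocation intervals are uniform on 1..14 days, echoing telemetry
revisit variability. Histories truncate at the first failure or the stage
horizon, and satisfy every encounter-history invariant by construction.

What the simulator does *not* emulate: spatially explicit rasters,
detection/attendance processes beyond Poisson observation error, nest-fate
misclassification, covariate measurement error, and real spatial
autocorrelation among leks. Passing recovery tests therefore demonstrate
correctness of the inference machinery under the stated generative
assumptions, not robustness to their violation in field data.

## Diagnostics and reporting

R-hat uses the classic two-stage (non-split) Gelman–Rubin formula by
default, with a split-chain option; the convergence gate is R-hat < 1.1.
pd (probability of direction) is the fraction of draws sharing the sign of
the posterior *median* (primary), with a mean-referenced variant for
table-style reporting — the two differ only in heavily skewed posteriors.
Credible intervals are equal-tailed draw quantiles with linear
interpolation (bit-stable). Evidence labels: "strong" when the 95% CRI
excludes 0; "moderate" when it overlaps 0 but pd > 0.85. Posterior-
predictive (Bayesian) p-values use a chi-square discrepancy for Poisson
counts and deviance for Bernoulli intervals; values near 0 or 1 indicate
lack of fit. pd of a positive-support parameter (e.g. Λ) is trivially 1
and is reported as NA-equivalent in prose.

## Numerical choices and problem sizes

Interval log-likelihoods use `log DSR = -log(1+exp(-eta))` and
`log(1-S) = log(-expm1(t log DSR))` so extreme survival probabilities stay
finite. Desk-scale MCMC defaults are 12,000 iterations (6,000 burn-in,
thin 4, 4 chains) for survival models and 10,000 (4,000 burn-in, thin 3, 4
chains) for the SSM; the field-scale profiles (50,000/25,000/thin-10, and
100,000/50,000/thin-20 for the selection SSM) are preserved as
`FIELD_PROFILE` constants and recommended for the 19-coefficient brood
design, whose shrunk near-zero coefficients mix slowest. Acceptance-style
recovery checks use 5 replicates at the default simulation scale; latent
log-abundance draws are extra-thinned (factor 5) to bound memory.

## Known limitations

* Single-site latent updates mix more slowly than gradient-based samplers;
  very long series or very sparse counts may need longer runs.
* The Laplace prior's spike at zero slows mixing of strongly shrunk
  coefficients; the R-hat gate reports this honestly rather than hiding it.
* The selection rule is one documented formulation among several
  defensible ones; its thresholds are conventions, not estimates.
* Lek-count inference inherits the constant-detection assumption; the
  model cannot separate attendance shifts from abundance change.
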