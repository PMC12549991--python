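# lekdemog

Hierarchical Bayesian demographic models for lek-breeding birds censused by
annual maximum male counts — the setting of greater sage-grouse
(*Centrocercus urophasianus*) monitoring, where population pattern comes
from lek-count time series and demographic process from telemetry-based
nest, brood, and adult survival.

The package implements, end to end:

* a **Gompertz state-space population model**: latent log-abundance follows
  `log N[i,t+1] = log N[i,t] + r[i,t]` with
  `r[i,t] ~ Normal(α_R + X'β_R + θ_R log N[i,t], σ²_r[i])` and Poisson
  observation `y[i,t] ~ Poisson(N[i,t])`; region-varying intercepts and
  covariate effects are hierarchical with common grand means, and `θ_R < 0`
  gives density-dependent (stationary) dynamics;
* **logistic-exposure survival models** for nest, brood, and adult life
  stages: `DSR = logit⁻¹(β₀ + x'β)`, interval survival `S = DSR^t`,
  `y ~ Bernoulli(S)`, with cumulative survival `DSR^horizon`
  (38/50/167 days) and Laplace (Bayesian-LASSO) shrinkage with rate
  `Λ ~ Uniform(0.01, 10)` on all non-intercept coefficients;
* **two-stage variable and scale selection**: correlation-graph grouping
  (|r| ≥ 0.65), per-group shrinkage screening with max-pd scale choice
  (retain pd ≥ 0.80), and a joint shrinkage refit of the retained set;
* **covariate engineering**: circular moving-window means at candidate
  radii (2.5/5/10 km population; 75–1451 m life-stage), exponential
  distance decay `exp(−d/α)`, seasonal and annual lag windows (water year,
  growing season, previous calendar year, seasons), and z-scoring;
* a **synthetic-data generator** that forward-simulates every input with
  known truth, making each stage verifiable by parameter recovery;
* **diagnostics**: Gelman–Rubin R-hat (convergence gate < 1.1),
  probability of direction, equal-tailed 95% credible intervals, and
  posterior-predictive (Bayesian) p-values.

All samplers are built in: blocked Metropolis-within-Gibbs for the
state-space model and mode-initialized adaptive Metropolis with exact
conjugate shrinkage-rate draws for the survival models. See
`docs/methods.md` for the model details, priors, and design choices.

## Worked example

Simulate encounter histories at the package's default study conditions
(300 nests whose generative daily survival is logit⁻¹(3.460) ≈ 0.969 at
reference covariates) and refit them:

```python
from lekdemog.exposure import build_stage_model, fit_stage_model
from lekdemog.mcmc import MCMCConfig
from lekdemog.synthetic import gen_encounter_histories

histories = gen_encounter_histories(stage="nest", seed=1)
model = build_stage_model("nest", histories)
fit = fit_stage_model(model, MCMCConfig(seed=2))
print(f"DSR {fit.survival.dsr_mean:.4f}  "
      f"38-day survival {fit.survival.cumulative_mean:.3f}  "
      f"converged {fit.converged}")
```

```
DSR 0.9682  38-day survival 0.294  converged True
```

The fitted daily survival rate (0.9682) recovers the generative 0.9695
within one posterior standard deviation, and the 38-day cumulative value
is `DSR^38`, held as a per-draw identity. The same pattern works for the
population model:

```python
from lekdemog.ssm import build_ssm, fit_ssm
from lekdemog.synthetic import gen_lek_counts

sim = gen_lek_counts(seed=7)                 # 3 regions x 60 leks x 20 yr
fit = fit_ssm(build_ssm(sim.data), MCMCConfig(seed=11))
print(fit.summarize().set_index("parameter").loc[
    ["mu_alpha", "theta[0]"], ["mean", "q2.5", "q97.5"]].round(3))
```

```
            mean   q2.5  q97.5
parameter
mu_alpha   0.529  0.050  1.050
theta[0]  -0.085 -0.119 -0.057
```

(`summarize()` refuses while any R-hat is >= 1.1; a different seed may
need a longer run.)

against generative truth `mu_alpha = 0.5`, `theta = -0.1`. A command-line
driver wraps the same functionality
(`lekdemog simulate|fit-ssm|fit-nest|fit-brood|fit-adult|select|diagnose`),
writing CSV summaries, a JSON report, and the resolved YAML run
configuration (seed included) next to every output.

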