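# Methods

## Model

`ipdnma` fits one-stage individual-participant-data (IPD) network
meta-analysis (NMA) models for time-to-event outcomes on the log cumulative
hazard scale. For patient *i* in trial *j*, with *q*+1 treatments and
treatment indicators `trt_k` coded within trial against the trial's own
baseline arm and mapped through the network consistency equations,

    ln H_j(t | x_ij) = s_j(ln t) + Σ_k β_k trt_kij + covariate terms,

where `s_j` is a restricted cubic spline in ln *t* with trial-specific
coefficients — a flexible parametric (Royston–Parmar) baseline on the
proportional-hazards scale. Writing x = ln t, each record contributes

    d_i · ( ln(dη/dx) − x_i + η_i ) − exp(η_i)

to the log likelihood (d the event indicator, η = ln H). A parameter state
must keep dη/dx > 0 at every observed event time; states violating this
monotonicity are flagged invalid and rejected by the sampler, never silently
propagated as NaN. With no internal knots the baseline is exactly Weibull,
which supplies the closed-form oracle used throughout the tests.

Treatment–covariate interactions (TCIs) for a patient-level covariate
`z_ij` come in two parameterisations:

* **separated** — within-trial terms `δ_Ak · trt_k · (z_ij − z̄_j)` and
  across-trial terms `δ_Bk · trt_k · z̄_j`, with the covariate main effect
  centred, `α_j (z_ij − z̄_j)`. The within-trial coefficient is protected by
  randomisation; the across-trial coefficient rests on observational
  between-trial contrasts. Their difference `δ_B − δ_A` measures ecological
  bias.
* **combined** — a single `δ_k · trt_k · z_ij` with raw `α_j z_ij`. The two
  coincide exactly when every `z̄_j` is zero (centring identity, asserted in
  the tests bit-for-bit on the design matrices).

The covariate main effect may be common, fixed per trial, or random per
trial (`α_j ~ N(α₀, σ_α²)`); interaction coefficients may be independent per
contrast, common across contrasts (equal regression coefficients — the
"common effects" structure, under which head-to-head contrasts of
non-reference treatments carry no interaction), or random at trial level
(`δ_{A,jk} ~ N(δ_Ak, σ_δ²)` with one σ_δ shared across contrasts). Random
treatment effects place trial-specific deviations `u_j ~ MVN(0, Σ)` on the
basic contrasts with a Wishart prior on `Σ⁻¹` (df = dimension, identity
scale). Inconsistency is modelled by adding a parameter ω to the closing
edge of a declared treatment loop, so that the loop's direct evidence
estimates (own contrast + ω) while the remainder of the network identifies
the indirect contrast; per draw, direct − indirect = ω by construction.
Proportional hazards are examined through treatment-ln(time) coefficients
φ_k and a global Wald test on their posterior mean and covariance.

## Priors and defaults

| parameter | prior | rationale |
|---|---|---|
| spline, β, α, δ, ω, φ | Normal(0, 10³) | conventional vague prior on logHR-scale locations; configurable via `PriorSpec` |
| random-effect SDs (σ_α, σ_δ) | Uniform(0, 2) | 2 logHR units is far beyond plausible between-trial spread |
| RTE precision Σ⁻¹ | Wishart(df = q, I) | weakly-informative conjugate form |
| missing covariate z_ij | Normal(μ_j, σ_j²) truncated to declared bounds | a trial-level truncated normal is a reasonable law for a bounded severity score |
| μ_j, σ_j | Normal(mid, range²); Half-Normal(range) | weakly informative on the covariate's own scale |

Credible intervals are equal-tailed 95% percentiles. Model comparison uses
the DIC with pD = D̄ − D(posterior means of the likelihood parameters); a
negative pD is reported as computed. DIC differences under ~5 are treated
as indifference, preferring the simpler model.

Default internal knots K = 2 per trial (overridable per trial), falling
back to K = 0 when a trial has fewer than four distinct event times, and to
boundary knots from all observed times when it has fewer than two distinct
event times (near-zero-event trials). Knots sit at equally spaced centiles
of the uncensored log event times. The basis is not orthogonalised and
ln t is not centred: time values in study-scale units keep the design well
conditioned, and the raw coding preserves the interpretability of the
spline coefficients (γ₀ + γ₁ ln t is exactly the Weibull form).

## Posterior computation

The posterior is sampled with a blocked, seeded scheme:

* **global block** (all design-column coefficients plus hierarchy and
  imputation hyper-parameters): Metropolis-corrected Hamiltonian Monte
  Carlo, preconditioned by the inverse Hessian of the log posterior at its
  mode (L-BFGS with analytic gradients; gradients are verified against
  finite differences in the test-suite). Leapfrog length is uniform on
  {1..10}; the step size adapts to a 0.75 acceptance rate during burn-in
  and is then frozen.
* **scalar hierarchies** are parameterised *non-centred*
  (coefficient = mean + sd·η, η ~ N(0,1)), which removes the funnel
  geometry when the between-trial SD is small; draws are recorded on the
  coefficient scale.
* **latent missing covariates** are conditionally independent given the
  global block and are updated by one vectorised Metropolis step per
  iteration (proposal scale ∝ the trial's current σ_j, adapted to 0.44
  acceptance).
* **RTE covariance**: conjugate Wishart Gibbs.

Chains initialise at the posterior mode plus per-chain seeded jitter; all
randomness derives from one integer seed, so identical settings give
bit-identical draws. Default chain geometry mirrors a conventional long
run (2 chains × 20 000 burn-in + 20 000 iterations); the bundled analyses
and tests use far smaller, explicitly passed settings (hundreds to a few
thousand iterations), which the preconditioned HMC makes adequate
(effective sample sizes near the draw count in the tested models).
Split-R̂ and effective sample size come from ArviZ (classic split method,
flag threshold 1.05).

Maximum-likelihood fits (per-trial forest-plot estimates, fast Wald tests,
pairwise pooling in `ml` mode) use L-BFGS on the same likelihood with
covariance from the inverse observed information.

## The nine-step workflow

`run_framework` executes, in order: (1) pairwise heterogeneity (Cochran Q,
I², DerSimonian–Laird τ²) and per-comparison PH tests; (2) reference
choice and consistency parameterisation; (3) FTE vs RTE comparison — RTE
is adopted when any pairwise Q has p < 0.10 (configurable; Q has low
power); (4) loop inconsistency splits; (5) covariate audit including the
summed per-trial 1-df Wald linearity test for a 3-level ordinal coding;
(6) covariate-mode choice by DIC with the indifference band; (7) the
covariate model; (8) the separated-interaction model with the
half-standard-error agreement criterion; (9) the combined model, flagged
"not recommended" whenever step 8 found disagreement, plus a complete-case
sensitivity comparison when values were imputed. A failing step truncates
the report at that point, preserving earlier steps. With missing covariate
values the separated fit uses the two-pass procedure: the combined model is
fitted first with truncated-normal imputation, effective trial means are
harvested (count-weighted average of observed and imputed means; imputed
means alone for a fully missing trial), and those means feed the separated
fit.

The agreement criterion declares a contrast's within- and across-trial
interactions in agreement when |δ̂_A − δ̂_B| ≤ 0.5 × SE, the SE backed out
of the across-trial estimate's 95% interval as (upper − lower)/(2×1.96);
the boundary counts as agreement, and `within`/`pooled` SE variants are
available. This criterion is deliberately strict: when both interaction
sources are precisely estimated, sampling noise alone makes disagreement
likely, so a "disagree" verdict is a prompt for inspection rather than a
hypothesis test with controlled error rates.

## Synthetic data

The generator emulates the structure of a four-treatment chemoradiation
network: two- and three-arm trials with trial-specific Weibull baselines
(shape 0.8–1.3, scale 4–9 study-time units), an ordinal severity covariate
coded 0/1/2 (a truncated normal rounded to the grid; a continuous option
exists for cleaner recovery studies) whose trial means vary — uniformly on
a configured range, or on a deterministic per-design grid ("even" spacing)
when a designed spread is wanted — administrative censoring at 5 time
units plus uniform dropout (~40–50% events by default), independently
configurable within- and across-trial interactions applied on the model's
own scale (the across term uses the realised trial mean), loop
inconsistency on a named design, PH violations via treatment-ln(time)
terms, and MCAR or arm-dependent covariate missingness including a fully
missing trial. Event times come from inverse-transform sampling of the
Weibull cumulative hazard scaled by the linear predictor — exactly the
model class fitted — so passing recovery tests demonstrate correct
inference *under the model*; they do not probe misspecification (real data
add non-PH, non-linear covariate effects, informative censoring and
frailty, none of which the generator produces unless explicitly
configured). Setting δ_A = δ_B makes the separated and combined generative
parameterisations bit-identical by construction.

## Numerical choices and edge cases

* Likelihood overflow in exp(η) is trapped; non-finite results invalidate
  the state rather than propagate.
* Ranking probabilities are exact empirical frequencies of ranks (ties
  broken stably); rows partition the draw count exactly.
* The degenerate zero-variance case of the PH Wald statistic uses a
  pseudo-inverse (χ² = 0, p = 1).
* Hierarchy SDs carry a numerical floor of 1e-4 inside the sampler's
  Uniform prior; the Hessian preconditioner assigns O(1) scales to
  hyper-SD coordinates whose mode sits on a bound.
* Multi-arm trials share one baseline spline under the default
  `share_control` policy, which induces the correct correlation between
  their contrasts in the one-stage likelihood; the `unconfounded_split`
  policy re-labels arms into two-arm pseudo-trials from a user-supplied
  assignment (design knowledge the data alone lack) and conserves patients
  exactly.
* Arm pooling (e.g. two variants of one regimen versus a shared control)
  is left to the user: no operation merges arms automatically.

## Known limitations

* Delayed entry/left truncation and competing risks are unsupported.
* Only the log cumulative hazard (proportional hazards) scale of the
  flexible-parametric family is implemented.
* The loop-ω route is the only inconsistency assessment; design-level Q
  statistics, node-splitting and design-by-treatment interaction models are
  out of scope and flagged to users.
* Exchangeable (hierarchically shared) interaction priors across contrasts
  are not implemented; interaction effects are independent, common, or
  random at trial level.
* The RTE deviations remain centred; with very small between-trial
  heterogeneity and few trials their hyper-covariance can mix more slowly
  than the non-centred scalar hierarchies — check the R̂ report on Σ-related
  quantities for small networks.
* Trials whose covariate is entirely unrecorded contribute little
  information to their own covariate-distribution hyper-parameters; their
  imputed means are driven by the prior midpoint and the outcome model, and
  the collective mean of such a trial's latent values mixes slowly.
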