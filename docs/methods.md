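# Methods

## Data model

The unit of analysis is the Lexis cell (worker type w, maternal age group
a, period p) with perinatal deaths D[w,a,p] and births B[w,a,p]. Exposure
is n = B + D throughout, because the perinatal mortality rate is defined as
deaths per 1,000 of (births + perinatal deaths). Cohorts index the grid
diagonals, k = p − a + (A − 1): with 7 age bands and 5 periods there are 11
cohorts; cohorts 0 and 10 are observed in a single cell each, cohorts 4-6
in five. The bundled CSV stores the published counts as plain integers;
rates are never stored, always derived. Whether the published "No. of
births" column itself includes stillbirths cannot be determined from the
table; the convention n = B + D reproduces every published crude rate to
one decimal, which settles the arithmetic but not the semantics.

## Descriptive rates

Crude rate = 1000·D/n; cells with n = 0 raise rather than return 0 (none
occur in the bundled data). Direct age standardization uses the *combined*
(both worker types) exposure distribution over age in the reference year
1995 as the standard population, applied to unrounded age-specific rates;
rounding happens only at display.

Limitation: 8 of the 10 published standardized values are reproduced
exactly at one decimal; the white-collar 2000 and 2010 values differ by one
rounding unit (we compute 5.46 and 3.64 against printed 5.4 and 3.7). No
weighting recoverable from the two published strata (births-only,
per-stratum, rounded-rate variants were all checked) reproduces those two
cells, indicating the original standard population included occupational
categories beyond the printed dichotomy. The convention above is the
closest one derivable from the data the package ships.

## The joint Bayesian APC model

For each stratum w:

    D[w,a,p] ~ Poisson(n[w,a,p] · exp(μ_w + α_w[a] + β_w[p] + γ_w[k]))

with any subset of the three effect vectors present (seven admissible
models: A, P, C, AP, AC, PC, APC). Identification:

* each included effect vector is constrained to sum to zero *exactly* for
  every posterior draw. Internally an effect of length L is parameterized
  by its L−1 random-walk increments; the vector is the mean-centered
  cumulative sum, so the constraint is structural, not penalized;
* RW1 prior: increments iid N(0, σ²_e) per effect, i.e. adjacent levels
  are smoothed. σ_e gets a half-normal(0, 1) hyperprior (on the log-rate
  scale, σ = 1 already allows order-of-magnitude level-to-level jumps, so
  this is weakly informative); intercepts get N(0, 10²). These hyperprior
  choices are this package's own (the analysis they reproduce names only
  the likelihood, the constraints, and the RW1 prior), and credible-interval
  widths are mildly sensitive to them — reproduction checks therefore use
  containment within published intervals, not digit matching;
* the two strata share no parameters; "jointly fitted" means one sampler
  over both likelihood blocks, which yields draw-aligned posteriors — the
  requirement for draw-wise rate ratios.

For the full APC model the likelihood is invariant to the classic linear
trend transfer α += t(a−ā), β −= t(p−p̄), γ += t(k−k̄); the RW1 priors and
constraints make the posterior proper but leave the trend split weakly
identified, so only DIC and fitted rates (not the individual APC effect
trends) should be interpreted for that model.

## Sampling

The posterior is sampled with a purpose-built blocked Gibbs scheme,
vectorized across chains:

1. **Effect blocks.** Given the scales, each stratum's (μ, increments)
   block has an exactly log-concave Poisson-GLM conditional. A
   deterministic damped-Newton pass (10 iterations from a fixed,
   MAP-derived start; steps capped so no cell log-rate moves more than 4)
   finds its mode and curvature, and the block is updated by independence
   Metropolis-Hastings from that Laplace (Gaussian) proposal. Acceptance on
   the study data is 0.84-0.96, so successive block draws are nearly
   independent; because the proposal adapts to the current conditional
   geometry, the slow trend trade-offs that defeat fixed-metric samplers on
   APC posteriors are absorbed into the proposal itself.
2. **Scales, centered.** p(σ | increments) has a closed algebraic form;
   it is drawn on a 1,400-point log-spaced grid spanning [1e-5, 10]
   (resolution ≈ 1% in σ; values below the grid floor are numerically
   indistinguishable from 0).
3. **Scales, non-centered.** Holding the standardized increments u = w/σ
   fixed, σ is slice-sampled from p(σ | u, data) and w rescaled. Steps 2
   and 3 interweave the two parameterizations of the hierarchy, which keeps
   mixing fast both when a scale is well identified and in the funnel
   regime σ → 0 (e.g. the blue-collar period effect in the PC model).

Chains (default 4) are MAP-initialized with small jitter; 500 warmup
iterations are discarded and 2,000 kept per chain (model comparison uses
4,000 thinned by 2, the budget the slowest member, full APC, needs). A fit
is flagged — never silently returned — unless split-R̂ < 1.01 and bulk
ESS ≥ 400 over all free parameters. All randomness flows from a single
integer seed. On one CPU a default fit takes roughly 10-30 s; the
seven-model comparison a few minutes.

Point estimates are posterior medians; intervals are equal-tailed 95%
quantiles (the convention adopted where the reproduced analysis says only
"95% credible interval").

## Model comparison

df = 70 − 2·(1 + Σ_included (L_e − 1)): data cells minus free parameters
under the constraints. DIC uses the classic decomposition
DIC = D̄ + p_D with p_D = D̄ − D(θ̄), the plug-in evaluated at the
posterior mean of the free (increment) parameterization. The deviance is
−2× the *full* Poisson log-likelihood including the log D! terms; the
constant convention cancels between models but fixes the absolute scale,
so only the DIC *ordering* (and the df column) is treated as exactly
reproducible — the published absolute DIC values depend on unstated prior
and constant conventions. On the bundled data the age-cohort model is the
DIC minimum, matching the published selection.

## Disparity

Rate ratios are computed draw-wise — exp of the difference of (intercept +
effect) between strata per posterior draw — never by dividing posterior
summaries, which would mis-state the interval. Period-level ratios exist
only for models that include a period effect. "Significant" is
operationalized as the 95% CrI excluding 1.

## Synthetic data and what the tests show

`simulate.default_truth` mimics the study's fitted structure: U-shaped age
risk (white-collar maximal at 15-19, blue-collar at 45-49), monotonically
declining cohort risk, a blue/white intercept gap of 1.4, and the published
exposure matrix, with RW scales (0.4 age, 0.15 period, 0.3 cohort) of the
magnitude recovered from the data. Births are stored as n − D so exposure
round-trips; a Poisson draw exceeding its cell exposure (probability ~0 at
realistic rates) is truncated.

The recovery experiment refits each simulated table and reports per-
parameter 95%-interval coverage, bias, and RMSE, excluding (and counting)
replicates that fail the convergence contract. Interpretation notes, all
verified empirically during development:

* **Coverage is summarized per effect vector** (mean over levels, per
  stratum and dimension). With a fixed, study-shaped truth the RW1 prior
  shrinks extreme single-cell levels (e.g. the oldest blue-collar cohort,
  true rate ratio 4.3); their *individual* frequentist coverage falls below
  nominal for any Bayesian smoother, while aggregate calibration stays in
  the expected band — at 50 replicates, within [0.85, 1.00].
* **Shrinkage is exposure-asymmetric.** Even with identical true
  parameters in both strata, the blue stratum's far smaller exposures
  shrink its weakly informed levels more, leaving replicate-median rate
  ratios slightly below 1 there. This is a generic property of hierarchical
  smoothing and the reason disparity estimates at the sparsest levels
  (ages 15-19/45-49, extreme cohorts) carry wide intervals and should not
  be over-read.
* **Zero-death cells carry one-sided information.** A cell with D = 0
  bounds its rate only from above at *any* exposure, so the affected
  effect level keeps a prior-determined lower tail, and through the
  sum-to-zero constraint the whole vector's interval widths plateau. The
  likelihood-dominance check (×100 exposure shrinks all widths) therefore
  holds on event-bearing synthetic tables, not on the bundled data, whose
  2015 white-collar 15-19 cell has zero deaths.
* The generator draws from exactly the model family being fitted; passing
  recovery tests show the pipeline is internally consistent, not that real
  registry data meet the Poisson or smoothness assumptions (no
  overdispersion, no occupational misclassification are simulated).

Problem sizes used by the shipped experiments: 50 replicates at published
exposure magnitudes (20 for the 100-fold-exposure contrast, whose RMSE gap
is an order of magnitude) with 2-chain fits of 300 warmup + 1,400 kept
iterations each — enough for the per-fit contract to pass in ≥ 80% of
replicates, with failures excluded and counted.

## Numerical conventions and degenerate inputs

* log-rate guard: |log λ| > 25 in the likelihood (or > 20 in the
  generator) is treated as overflow and rejected.
* A single-level effect (toy grids) contributes no free parameters and no
  scale; a single-cell table reduces the model to its intercepts (used by
  the quadrature oracle tests).
* Fixed scales can be supplied (`fixed_sigmas`) to make small-grid
  posteriors amenable to dense quadrature; the oracle tests compare MCMC
  moments against 1-D and 3-D grid quadrature within Monte-Carlo error.
* Ties/ordering: effect levels are reported in grid order; the comparison
  table preserves the conventional A, P, C, AP, AC, PC, APC order.
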