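# Methods

## Scientific setting

Juvenile *Daphnia pulex* respond to the kairomone of predatory *Chaoborus*
larvae by growing neckteeth (small dorsal head spines, counted 0–5) on a
pedestal (a bulge at their base, scored ordinally A = absent < B = small
< C = large). The package models two experiments on two clonal lineages
(UNI, P5): a **kairomone-effectivity trial** (kairomone medium exposed to
UV-A radiation, to photosynthetically active radiation, or a kairomone-free
dark control, for 2/4/6/8 h before mothers were introduced) and a **main
factorial experiment** (kairomone × UVR exposure of mothers and offspring),
scoring both defense traits and three morphometric traits (body length,
body width, tail-spine/spina length, mm) in instars 1 and 2.

Offspring of one mother are not independent: every model here is
hierarchical with per-mother random intercepts, with mothers identified by
a clone-by-treatment-by-index unique identifier.

## Models

### Bivariate defense-trait model

For juvenile *i* of mother *m(i)* with design row `x_i` (treatment-coded
factors, interactions up to a configurable order):

- neckteeth count: `k_i ~ Binomial(5, logit^-1(x_i' β_N + u_N,m(i)))`
- pedestal class: cumulative logit with two ordered thresholds,
  `P(class ≤ j) = logit^-1(τ_j − η_i)`, `η_i = x̃_i' β_P + u_P,m(i)`,

where `x̃_i` omits the intercept — in a cumulative model the thresholds
*are* the intercepts, and including both would leave their difference
unidentified. Mother effects are independent between the two responses,
`u ~ Normal(0, σ)`; a cross-response correlation is deliberately out of
scope. Both instars are fitted separately with the same structure, because
instar-1 neckteeth are canalized (present without kairomone) while
instar-2 neckteeth are inducible and may reflect different causal paths.

Priors: `Normal(0, 10)` on all coefficients and thresholds (subject to
`τ1 < τ2`), `half-Normal(0, 10)` on random-effect scales. These weakly
informative priors are what makes the weakly identified interaction
contrasts (for example a treatment cell that happens to produce a single
outcome category) proper and sampleable.

The per-instar defense models retain main effects and two-way
interactions; the clone:kairomone:UVR triple interaction is excluded from
the final models, consistent with the identifiability screen below. The
effectivity trial is modeled with the same bivariate structure but a
single pooled 3-level treatment factor (control/PAR/UVR), all exposure
durations pooled; contrasts of interest are kairomone-vs-control,
`(β_PAR + β_UVR)/2`, and UVR-vs-PAR, `β_UVR − β_PAR`.

### Trivariate morphometric model

The three length traits are jointly Gaussian with a zero-truncated
(positive-orthant) trivariate distribution: mean `X B + U[mother]`,
per-trait mother-effect scales `σ_u`, and residual covariance `Σ`
decomposed into standard deviations (half-Normal(0,10)) and a correlation
matrix (uniform over positive-definite matrices). One joint model covers
both instars and both clones with interactions up to order three (the
four-way interaction is excluded). `truncated_mvn_loglik` computes the
exact orthant-corrected density (deterministic Genz quadrature, absolute
tolerance 1e-6, fixed quadrature seed so likelihoods are reproducible);
fitting uses the `truncated=False` switch because at the measured scales
(means ≥ 0.36 mm, residual sd ≤ 0.05 mm) the orthant probability differs
from 1 by less than 1e-12 and the correction is numerically invisible.
Records missing some traits contribute the marginal density of the
observed sub-vector; records missing all three are dropped with a logged
count.

### Hypothesis testing and effect classification

Point-null evidence uses the Savage–Dickey density ratio: BF01 =
posterior/prior density at 0, the posterior density estimated from pooled
post-warmup draws by Gaussian KDE with Silverman bandwidth (at least 100
draws required; a normal-approximation fallback exists). An effect is
"strong" when its central 95% credible interval (linear-interpolation
empirical quantiles) excludes zero; an endpoint exactly at zero counts as
including it. These two rules, not p-values, are the package's inferential
outputs; forest plots show medians with 50%/95% intervals, strong effects
in red.

## Posterior computation

The sampler contract is diagnostics-based, not algorithm-based: any
sampler whose retained draws pass rank-normalized split-R̂ < 1.01 on a
standard-normal target and match conjugate closed forms within Monte Carlo
error satisfies it. Two implementations ship:

1. `sample_posterior` — generic coordinate-wise slice sampling (stepping
   out + shrinkage, per-coordinate widths adapted during warmup and frozen
   after) over any callable log posterior.
2. Blocked samplers inside the model classes, needed to reach R̂ < 1.01 on
   hierarchical posteriors within single-CPU budgets:
   - univariate slice updates for coefficients, thresholds, and log
     random-effect scales;
   - a vectorized slice update over the conditionally independent mother
     intercepts (per-mother likelihood segments via `reduceat`);
   - random-direction slice moves over the joint fixed-effect + threshold
     block, directions drawn from a warmup-adapted covariance Cholesky
     factor. These carry the chain along correlated coefficient ridges —
     e.g. when a design cell yields a single outcome category, the
     affected coefficient is bounded on one side only by its prior and
     trades off linearly against its interactions. Design-matrix
     projections along each direction are precomputed, so a line
     evaluation is elementwise. The axis-aligned coefficient sweep is
     largely redundant with these moves once adapted, and runs every third
     iteration after warmup;
   - exact Gibbs recentering (interweaving) moves along the
     likelihood-invariant directions intercept-vs-mother-effects and
     thresholds-vs-mother-effects, plus an ancillary rescaling step for
     each random-effect scale with the standardized effects held fixed —
     the standard cures for the location and funnel pathologies of
     hierarchical posteriors;
   - the Gaussian morphometric model instead uses conjugate Gibbs blocks:
     coefficients drawn with the mother effects analytically integrated
     out (Woodbury identity per mother), then mother effects given
     coefficients, Gibbs imputation of missing trait components
     (equivalent to the marginal sub-vector likelihood), and slice updates
     for `σ_u`, residual sds, and correlations.

All warmup adaptation (slice widths, direction covariance) is frozen when
warmup ends, so the retained chain is a fixed, valid MCMC kernel. Chains
are seeded by `SeedSequence([seed, chain])`; identical configurations give
bit-identical draws. The two samplers are cross-checked against each other
on a small dataset in the test suite, and against conjugate closed forms.

Chain configurations ship as presets: `full_effectivity` (5 chains ×
4,000 iterations, half warmup → 10,000 draws), `full_main` (4 × 2,000,
1,000 warmup → 4,000 draws), and scaled-down presets for continuous
testing (`ci` 4 × 1,200, `ci_fast` 4 × 400, `replicate` 2 × 600). The
reduced presets were sized so that the pipeline's identifiability screen
is comfortably passed by the final models on synthetic data; headline
results in the tests use the smallest preset whose credible intervals are
stable.

### Diagnostics and the identifiability screen

Rank-normalized split-R̂ and bulk effective sample size follow the
Vehtari et al. recommendations (computed by ArviZ). A parameter constant
across all draws is reported as R̂ = 1 and ESS = 0 with a warning rather
than NaN, so screening never crashes. `check_identifiability` flags a fit
when any parameter exceeds R̂ > 1.05 (strictly); the pipeline treats this
as evidence of an overfitted (unidentifiable) model variant — the remedy,
implemented in `fit_with_reduction`, is to drop the highest interaction
order and refit. A final reduced model failing the screen aborts the
pipeline with a nonzero exit.

## Synthetic-data generator

The generator is first-class, tested code: it emulates the two experiments
at their real design sizes so every downstream stage can be exercised and
calibrated without the archived field data.

Main experiment, per clone × kairomone × UVR cell: 6 mothers (the
emulated design allows 5–7), each with Uniform{5..10} offspring; each
mother carries instar- and response-specific defense intercepts and one
trivariate morphometric effect, shared by her offspring. Every juvenile
yields an instar-1 record; under +UVR it fails to reach instar 2 with
probability 0.55, reproducing the reported UVR mortality of at least 50%;
otherwise an instar-2 record follows. Traits are drawn from the defense and morphometric models
above using documented true parameters; morphometrics are rejection
sampled into the reported body-length ranges (instar 1: 0.55–0.80 mm,
instar 2: 0.75–1.00 mm) and the positive orthant. The clone-P5 instar-1
+kairomone/+UVR cell is dropped (no data existed for it); instar-2
survivors of those mothers are kept. Instar-2 records lose their
photograph with probability 0.10 (all lengths missing half the time,
spina only otherwise), exercising both missing-data paths. Randomness is
derived per cell from `SeedSequence(seed, spawn_key=cell)`, so adding
mothers or treatments leaves other cells' draws unchanged.

Effectivity trial: 3 treatments × 4 durations × 2 mothers × 5 offspring
(10 juveniles per cell, 120 records). PAR and UVR cells share identical
generating parameters — no kairomone-degradation effect is simulated — and
the control induces almost nothing. Exposure duration has no generative
effect and is not a model predictor (the analysis pools time points).

True parameter defaults encode the reported qualitative effect
structure: strong kairomone induction of instar-2 neckteeth and pedestals
(UNI modal count 2–3 without UVR), canalized instar-1 neckteeth (modal 1–3 regardless of
treatment), UVR suppression of pedestals (strongest in instar 1), UVR
shrinking every morphometric trait, and clone-dependent modulation.
Magnitudes were additionally chosen so that **every design cell keeps
non-negligible probability on at least two outcome categories**: a cell
that deterministically produces one category (e.g. all pedestals absent)
leaves its coefficient identified only by the prior, so no experiment of
this size could recover it and recovery tests would measure prior
behavior, not inference quality. Within that constraint the defaults are
configuration, not claims about the original data.

What the generator does not emulate: exposure-duration effects on
kairomone potency, instar-dependent residual covariance (spina length in
real instar-1 data is more variable than the common-Σ model allows),
food/light physics, and non-independent within-clutch mortality. Passing
tests therefore demonstrate correct inference under the stated model, not
robustness to those misspecifications.

## Numerical choices

- Ordinal tail probabilities use `log_expit` identities
  (`log[s(b)−s(a)] = log s(b) + log s(−a) + log1p(−e^{a−b})`), stable for
  extreme linear predictors.
- Threshold ordering is enforced by a −inf log density (slice sampling
  handles hard constraints by shrinkage) and an ordered initialization.
- Empirical quantiles use the linear-interpolation convention; this is
  documented because CI endpoints near zero decide strong-effect calls.
- Degenerate draws (a constant parameter) yield a point-mass density in
  Savage–Dickey (ratio 0 or ∞) rather than a KDE failure.
- The morphometric Gibbs sampler symmetrizes the Woodbury correction and
  falls back to a fixed correlation start if a proposed correlation matrix
  loses positive definiteness.
- CSV serialization writes lengths at six decimals; the pipeline fits from
  the written file in both simulate and ingest modes, so the two modes are
  byte-identical for the same seed.

## Problem sizes used by the tests and the acceptance script

Convergence and recovery checks run at the reference design size
(~580 records, 48 mothers per simulated dataset). The convergence gate
fits the instar-2 model with the 4 × 2,000 configuration; the recovery
study uses 20 seeded replicates with the two-chain `replicate` preset for
defense models and 2 × 400 for morphometrics — enough draws for stable
95% intervals, chosen so the full study stays a single-CPU job. Orthant
probabilities are checked against 10^6-sample Monte Carlo; density-ratio
oracles use 2×10^5 exact posterior draws.

## Known limitations

- The samplers are purpose-built for these model families; the generic
  slice sampler is not meant for high-dimensional external use.
- Savage–Dickey ratios for effects with posteriors far from zero
  underflow to 0 (the KDE tail vanishes); they are reported as 0 rather
  than extrapolated.
- The identifiability screen reproduces the workflow (drop highest-order
  interaction on R̂ > 1.05), not any particular historical fit.
- With heavy quasi-separation (a possible random outcome of small cells),
  one-sided coefficient posteriors extend to the prior scale; credible
  intervals are then prior-sensitive, as they are in any Bayesian GLMM
  with weak priors.
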