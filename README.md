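# neckteeth

Bayesian hierarchical analysis of how ultraviolet radiation (UVR) affects
kairomone-induced defense traits in juvenile *Daphnia pulex*.

When *Daphnia* detect the kairomone of predatory *Chaoborus* larvae, their
juveniles grow **neckteeth** (small dorsal head spines, 0–5) on a
**pedestal** (scored A = absent < B = small < C = large). This package
implements the statistical machinery to ask whether UVR interferes with
that inducible defense — either by degrading the kairomone itself or by
direct physiological stress on the animals — together with a synthetic
generator that emulates both experiments, so the entire pipeline runs and
is tested without any external data. It is aimed at ecologists and
biostatisticians analyzing clutch-structured trait data with ordinal,
count, and multivariate continuous responses.

## Models

Offspring of one mother are correlated, so every model carries per-mother
random intercepts (u ~ Normal(0, σ), σ ~ half-Normal(0, 10)); all fixed
coefficients and thresholds have Normal(0, 10) priors.

**Bivariate defense model** (fitted separately per instar; also fitted to
the effectivity trial with a pooled 3-level treatment factor):

    k_i   ~ Binomial(5, logit⁻¹(x_i' β_N + u_N,m(i)))            neckteeth
    P(c_i ≤ j) = logit⁻¹(τ_j − x̃_i' β_P − u_P,m(i)),  τ₁ < τ₂    pedestal

**Trivariate morphometric model** for body length, body width, and spina
length (mm), jointly zero-truncated Gaussian:

    y_i ~ N₃(x_i' B + U_m(i), Σ) truncated to y > 0

Inference is MCMC (blocked slice-within-Gibbs with interweaving moves; see
`docs/methods.md`), gated on rank-normalized split-R̂: a model variant with
any R̂ > 1.05 is treated as unidentifiable and its highest interaction
order is dropped. Hypotheses are tested with Savage–Dickey density-ratio
Bayes factors, and an effect is called **strong** when its 95% credible
interval excludes zero.

## Worked example

```python
import dataclasses
import neckteeth as nt

# synthetic main experiment: 2 clones x kairomone x UVR, 6 mothers/cell
records = nt.simulate_main_experiment(nt.GeneratorConfig(seed=0))

model = nt.DefenseTraitModel.from_records(records, instar=2)
res = model.fit(dataclasses.replace(nt.PRESETS["full_main"], seed=0))

print(f"max R-hat: {res.max_rhat():.4f}")
print(res.summary().head(4).to_string(index=False))
ev = res.savage_dickey("neckteeth.kairomone")
print(f"evidence ratio (H0: no kairomone effect): {ev.evidence_ratio:.2e}")
```

Output (about 75 s on one CPU):

```
max R-hat: 1.0064
           parameter    median  ci50_low  ci50_high  ci95_low  ci95_high  strong  evidence_ratio
 neckteeth.Intercept -2.544656 -2.766520  -2.329226 -3.274513  -1.908504    True    1.216117e-83
neckteeth.clone[UNI] -0.288715 -0.593667   0.012265 -1.196249   0.604915   False    1.791428e+01
 neckteeth.kairomone  1.844591  1.586024   2.119799  1.064490   2.708652    True    1.388809e-08
       neckteeth.uvr -0.718213 -1.077617  -0.354566 -1.838343   0.289968   False    8.111438e+00
evidence ratio (H0: no kairomone effect): 1.39e-08
```

Read: chains converged (R̂ < 1.01 on all 111 parameters). Without
kairomone, instar-2 neckteeth are essentially absent (intercept −2.5 on
the per-tooth logit scale, ≈ 7% per-tooth probability for the reference
clone P5). Kairomone raises the per-tooth log-odds by ≈ 1.8 — a strong
effect whose 95% CI excludes zero and whose Savage–Dickey evidence ratio
(≈ 1.4e−8) overwhelmingly rejects "no effect". The clone contrast and the
UVR main effect are not strong in this realization (their CIs span zero;
evidence ratios > 1 favor the null). The generating values for this
synthetic dataset were −3.0 (intercept), +2.4 (kairomone), and −0.3 (UVR)
plus interactions; each sits inside its 95% interval.

The same surfaces exist for `nt.MorphometricModel` (e.g.
`body_length.uvr`, the UVR shrinkage of body length in mm) and
`nt.EffectivityModel` (`contrast_savage_dickey("neckteeth",
"uvr_vs_par")` tests whether UVR-exposed kairomone medium induces less
than PAR-exposed medium).

An end-to-end run — simulate (or ingest CSVs), fit all three model
families, write draws, diagnostics, effect tables, forest plots, and a
report — is available from the shell:

```bash
neckteeth fit --which both --preset ci --seed 0 --out runs/demo
neckteeth report runs/demo
```

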