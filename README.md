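# nlmrsim

Simulation and diagnostics for bias in **stratified (non-linear)
Mendelian randomization**.

## The problem

Non-linear MR estimates how a causal effect varies across the exposure
distribution by splitting a cohort into exposure-related strata and
computing an instrumental-variable estimate in each.  Two
stratification methods dominate applied work:

* the **residual method** — stratify on the residuals of the exposure
  regressed on the genetic instrument; valid under a *constant genetic
  effect* (the instrument shifts everyone's exposure equally);
* the **doubly-ranked method** — rank by instrument into pre-strata of
  size S, then rank by exposure within each pre-stratum, the j-th
  lowest exposure in every pre-stratum forming stratum j; valid under
  the weaker *rank-preserving assumption* (each individual's exposure
  rank would be unchanged under any counterfactual instrument value).

Both assumptions fail under **genetic effect heterogeneity** — when
the instrument→exposure effect differs across individuals, e.g.
through a gene-by-environment interaction.  This package provides the
machinery to quantify what happens then: synthetic cohorts with
controllable interaction and confounding structure, both stratifiers,
stratum-specific Wald-ratio estimation, bias/heterogeneity metrics, a
direct counterfactual test of the rank-preserving assumption, and a
falsification test that can be run on real instrument/exposure data.

## The model

Cohorts follow

```
x = β_g·g + b_ux·u + b_gux·g·u [+ b_vx·v] + e_x
y = b_uy·u            [+ b_vy·v]          + e_y
```

with `g, u, v, e_x, e_y` independent normals (mean 2, SD 1 in the main
designs), β_g = 0.3 fixed, and **no causal effect of x on y** — so
every full-sample or stratum-specific MR estimate should be 0, and any
systematic departure is bias.  `b_gux ≠ 0` introduces genetic effect
heterogeneity.  Within each stratum (10 by default) the estimate is
the Wald ratio `θ̂ = β̂_gy / β̂_gx` with first-order delta SE
`se(β̂_gy)/|β̂_gx|`.  Scenario-level metrics: per-stratum means and
MSE about zero, Cochran's Q across strata with the proportion of
replicates at p < 0.05, and CI coverage.

The rank-preservation diagnostic fixes `g` at −1 SD / mean / +1 SD for
*everyone*, recomputes each individual's exposure holding their other
components fixed, re-ranks, and reports the proportion of identical
ranks and the normalized mean rank change.  For additive models
`x = f(g) + u + ε` the ranks are preserved exactly for any `f`; any
`g×u` interaction breaks them.

The falsification test takes a measured (or synthetic) polygenic score
and exposure, builds `x_s = exposure + b_ux·u`, `y_s = b_uy·u + e_y`
with simulated `u`, and runs both methods: the score is a valid
instrument for the simulated outcome by construction, so non-null
stratum estimates expose stratification-assumption violations caused
by heterogeneity in the real instrument-exposure relationship.

## Worked example

```python
from nlmrsim import run_scenario, simulation_a

cfg = simulation_a(n=20_000, n_replicates=50, b_gux=-0.1, seed=1)
summaries = run_scenario(cfg)
for method, s in summaries.items():
    print(method, s.per_stratum_mean.round(2), round(s.het_rate, 2))
```

prints

```
residual      [ 0.5   0.31  0.25  0.11  0.   -0.07 -0.14 -0.25 -0.25 -0.57] 0.78
doubly_ranked [ 0.4   0.23  0.24  0.15  0.01 -0.04 -0.14 -0.21 -0.35 -0.52] 0.66
```

Every number should be zero: with a g-by-u interaction (`b_gux=-0.1`)
and confounding (`b_ux=b_uy=0.3`), both methods instead report a
spurious positive-to-negative gradient across strata, and ~70-80% of
replicates show nominal Cochran-Q heterogeneity.  Re-running with
`b_gux=0.0` gives stratum means within Monte-Carlo noise of zero and a
heterogeneity rate at the nominal 5%.  The scripts under `examples/`
walk through this experiment, the rank-preservation suite, the
falsification test and covariate adjustment.

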