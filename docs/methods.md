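# Methods

This note records the models the package implements, the numerical and
design choices that were genuinely open, and what the synthetic-data
generators do and do not emulate.

## Data-generating processes

**Main designs.** The exposure and outcome follow

```
x = β_g·g + b_ux·u + b_gux·g·u [+ b_vx·v] + e_x
y = b_uy·u            [+ b_vy·v]          + e_y
```

with all structural variables drawn independently normal with mean
`mu` and SD `sigma` (defaults 2 and 1; the rank-preservation suite
uses mean 0).  β_g = 0.3 throughout.  There is never a causal effect
of `x` on `y`, so 0 is the known truth for every estimand.  Design A
uses `u` alone (modifier and confounder in one); design B adds an
independent confounder `v` while `u` only modifies the genetic effect
(`b_uy = 0`).  Mutual independence of `g, u, v, e_x, e_y` is the only
reading consistent with the causal diagrams the designs encode;
nothing in the package draws correlated structural variables.

**Exposure models M1-M13** cover linear, interaction, quadratic and
individual-effect forms (see `nlmrsim.dgp.MODEL_REGISTRY`).  Their
structural variables are standard normal except M10, where the
instrument has SD 0.25 (read from the source description "0.5^2"; the
`sigma_g` field makes the variance-0.25 reading a one-line change).
For M11-M13 the error (and `u`) is drawn first, then the
per-individual genetic effect `α ~ N(mean(ε, u), 0.1²)`, then
`x = α·g + u + ε` — the only sampling order under which the
conditional normals are well defined.  `α` is stored on the cohort and
reused unchanged in counterfactuals: it is an attribute of the
individual, not of the instrument value.

**Seeding contract.** A scenario owns one base seed; replicate `r`
uses `numpy.random.SeedSequence((base_seed, r))`.  Replicates are
therefore mutually independent, reconstructible in isolation, and
results are invariant to execution order.  Tie-breaking inside the
stratifiers uses a dedicated permutation drawn once per call from a
`tie_seed`, so assignments are deterministic and free of input-order
artifacts (for continuous data, ties are null sets and the permutation
is inert).

**Stand-in empirical cohort.** `generate_empirical_standin` builds a
polygenic score from biallelic dosages (Binomial(2, f), allele
frequencies uniform on [0.05, 0.95], positive half-normal weights) and
an exposure `x = (β_g + heterogeneity·m)·g_std + m + e_x` with a
latent standard-normal modifier `m`, optionally exponentiated for
right skew, with `x` and the score standardized.  Every one of those
choices is package plumbing chosen for plausibility: the cohort has no
linkage disequilibrium, no ancestry structure, no assortative mating,
no selection, and a single latent modifier, so passing tests on it
demonstrate the machinery and the qualitative bias mechanisms — not
performance on any particular real dataset.  Because the exposure is
re-standardized, fitted coefficients sit on the standardized scale;
the pre-scaling SD is kept in `cohort.meta["x_scale"]` so generator
parameters can be recovered on their original scale.

## Stratification

The residual method cuts OLS residuals of `x` on `g` into equal-count
(quantile) strata — sizes differ by at most 1 — with stratum 1 the
lowest residuals.  Equal-count rather than equal-width cuts are the
convention in the stratified-MR literature.  The doubly-ranked method
sorts by `g`, forms consecutive pre-strata of size S, and assigns the
j-th lowest exposure in each pre-stratum to stratum j; a final
remainder pre-stratum of size m < S maps its j-th member to stratum
`ceil(j·S/m)`, preserving monotonicity while spreading the remainder
(the reference n = 100,000 / S = 10 setting never hits this case).

Covariates can enter the residual regression, but stratification is by
default unadjusted; covariate adjustment belongs to estimation, where
it applies to both within-stratum regressions.

## Estimation

OLS slopes and classical (homoskedastic) SEs are computed in closed
form; these regressions run ~10⁴ times per scenario, which is why a
full modelling framework is not in the loop (tests verify agreement
with statsmodels to 1e-10).  The Wald SE defaults to the first-order
delta form `se_gy/|β_gx|`, the standard choice in stratified-MR
software; the second-order form adding the denominator's variance is a
flag (it widens CIs but moves no point estimate).  A stratum with
partial F < 10 is flagged weak but never dropped — dropping would
distort the bias patterns under study.  A zero IV-exposure slope
raises by default; a permissive flag converts it to a NaN estimate so
scenario sweeps survive degenerate strata.

## Performance metrics

Cochran's Q uses fixed-effect inverse-variance pooling (that is its
definition); heterogeneity "detection" is strictly `p < 0.05`; MSE is
taken about truth 0 per stratum and pooled as the mean over replicates
of the within-replicate across-strata mean (equal to the grand mean
for complete matrices, asserted in tests); CI coverage uses symmetric
normal quantiles.

## Rank-preservation diagnostics

Counterfactual instrument levels default to −1 SD, mean, +1 SD of the
*population* distribution of `g` (not sample moments).  Ranks are
computed per counterfactual column with one shared tie permutation, so
ties cannot manufacture spurious rank changes.  `norm_rank_diff`
averages all level pairs; the per-pair map is also reported since a
single-pair reading is equally defensible.  For additive models
`x = f(g) + u + ε` the counterfactual columns differ by a constant and
rank preservation is exact — the suite asserts equality, not
approximation.  Reference settings are n = 50,000 and 100 replicates;
tests and the acceptance script run n = 10,000 with 3-20 replicates,
which resolves every ordering the suite asserts.

## The falsification test

`x_s = exposure + b_ux·u`, `y_s = b_uy·u + e_y` with `u, e_y ~ N(2,1)`
and defaults `b_ux = −1`, `b_uy = 1`; the exposure is standardized
first (configurable).  `y_s` is independent of the score by
construction, so the core IV assumptions and a constant (zero)
causal dose-response hold exactly, and any stratum-level bias
isolates the stratification assumptions.

**Verdict rule.**  `bias_suspected` fires when any stratum's mean
estimate exceeds 3 times the *across-replicate SD* of that stratum's
estimates, or when the heterogeneity rate exceeds 0.5.  The SD scale
(rather than the SE of the mean) is deliberate: the measured exposure
is a single fixed realization shared by all replicates, which leaves a
small persistent offset of order 1/√(n/S) in the extreme strata even
under a perfectly homogeneous genetic effect (~±0.06 at n = 20,000,
S = 10).  Against the SE of the mean that offset would be flagged with
certainty as replicates grow; against the replicate SD the null stays
silent and heterogeneity-driven bias (an order of magnitude larger)
still fires.  The same shared-realization effect pulls full-sample CI
coverage slightly below nominal (~0.93-0.94 rather than 0.95).  Both
thresholds are configurable and echoed in the report, never silent.

## Illness scores

Generic forms of the two ill-health summaries: a point count (marker
strictly above its 80th / below its 20th percentile per its illness
direction, plus diagnosis flags) and a standardized per-participant
median of direction-aware marker ranks.  Quantiles are the inclusive
linear-interpolation kind with strict inequality at the threshold —
deterministic and tie-safe; constant markers are allowed, earn no
quantile points, and a fully degenerate median-rank score is returned
centered instead of standardized.  Marker direction is always
caller-specified via the `high_bad`/`low_bad` lists.

## Problem sizes and known limitations

Scenario experiments in the tests and acceptance script use n = 20,000
cohorts with 50 replicates (100 for the two-confounder design, whose
weaker patterns need the extra Monte-Carlo resolution; the sign-flip
scenario under `b_ux = +0.3` runs at the reference n = 100,000 because
its reversed bias is ~±0.1 and sits inside noise at n = 20,000).  The
reference scale (n = 100,000, 100 replicates) is one call away via
`paper_scale()`.

Extreme-stratum Wald ratios are heavy-tailed whenever the effective
instrument slope `β_g + b_gux·u` crosses zero for part of the
population; means across replicates are then noisy and sign-based
summaries are more stable than z-scores.  The simulations include no
non-zero causal effect, no pleiotropy, no selection, and no
model-misspecified dose-response; conclusions about bias mechanisms
transfer to real data only insofar as those additional complications
do not dominate.
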