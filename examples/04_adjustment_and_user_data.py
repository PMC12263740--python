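"""Covariate adjustment, and running the estimators on a user table.

Part 1: adjusting the within-stratum regressions for the exact
modifier u removes the interaction bias; adjusting for an error-prone
measurement of it (Pearson r = 0.8) does not.

Part 2: cohorts round-trip through plain TSV, the format in which
user-supplied individual-level data (id, instrument, exposure,
outcome) enters the stratified estimators.
"""

import tempfile

import numpy as np

from nlmrsim import (
    estimate_strata,
    run_scenario,
    simulation_a,
    stratify_doubly_ranked,
)
from nlmrsim.io import cohort_from_tsv, cohort_to_tsv
from nlmrsim.dgp import generate_cohort

cfg = simulation_a(n=20_000, n_replicates=50, seed=4)
for adjust, label in ((None, "unadjusted"), ("u", "adjusted for u"),
                      ("u_error", "adjusted for noisy u (r=0.8)")):
    s = run_scenario(cfg, methods=("doubly_ranked",), adjust=adjust)
    means = s["doubly_ranked"].per_stratum_mean
    print(f"{label:30s} max |stratum mean| = {np.max(np.abs(means)):.3f}")

print()
cohort = generate_cohort(simulation_a(n=2000, seed=4))
with tempfile.NamedTemporaryFile(suffix=".tsv") as tmp:
    cohort_to_tsv(cohort, tmp.name)
    back = cohort_from_tsv(tmp.name)
assignment = stratify_doubly_ranked(back, S=10)
full = estimate_strata(back, assignment)[0]
print(f"round-tripped cohort: full-sample Wald {full.wald:+.3f} "
      f"(SE {full.se_wald:.3f}), instrument F = {full.f_stat:.0f}")
print("""
Exact adjustment restores unbiased estimates (max stratum mean within
Monte-Carlo noise of 0); partial adjustment leaves a clear residual
bias.  The TSV round-trip shows the dialect for user-held data.""")
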