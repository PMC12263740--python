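"""Gene-by-environment interaction biases stratified MR estimates.

Simulates cohorts where a modifier u both scales the instrument's
effect on the exposure (b_gux) and confounds the exposure-outcome
relationship (b_ux, b_uy), with NO causal effect of exposure on
outcome.  Both stratification methods then produce spurious non-null
stratum-specific estimates: positive in low strata, negative in high
strata.  Setting b_gux = 0 removes the bias.
"""

import numpy as np

from nlmrsim import run_scenario, simulation_a

for b_gux in (-0.1, 0.0):
    cfg = simulation_a(n=20_000, n_replicates=50, b_gux=b_gux, seed=1)
    summaries = run_scenario(cfg)
    print(f"\nb_gux = {b_gux} (true causal effect is 0 everywhere)")
    for method, s in summaries.items():
        means = np.array2string(s.per_stratum_mean, precision=2,
                                floatmode="fixed")
        print(f"  {method:13s} stratum means {means}")
        print(f"  {'':13s} pooled MSE {s.pooled_mse:.4f}   "
              f"heterogeneity rate {s.het_rate:.2f}")

print("""
With the interaction (b_gux = -0.1) the stratum means sweep from
positive to negative across strata and the Cochran-Q heterogeneity
rate is far above the nominal 0.05; without it, every stratum mean is
within Monte-Carlo noise of zero.""")
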