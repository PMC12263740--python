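"""When does the rank-preserving assumption break?

For each exposure model, every individual's exposure is recomputed
with the instrument fixed at -1 SD, the mean, and +1 SD, and the
population is re-ranked.  Additive models (even the quadratic one)
preserve every rank exactly; any gene-by-environment interaction
shuffles ranks, in proportion to the interaction size.
"""

from nlmrsim import MODEL_REGISTRY, rank_preservation_test

print(f"{'model':6s} {'description':42s} {'prop same rank':>14s} "
      f"{'norm rank diff':>14s}")
for model_id in ("M1", "M9", "M8", "M3", "M4", "M7"):
    d = rank_preservation_test(model_id, n=10_000, n_replicates=5, seed=2)
    desc = MODEL_REGISTRY[model_id].description
    print(f"{model_id:6s} {desc:42s} {d.prop_identical:14.4f} "
          f"{d.norm_rank_diff:14.4f}")

print("""
'prop same rank' is the fraction of individuals keeping their exact
exposure rank across all three counterfactual instrument levels;
'norm rank diff' is the mean absolute rank change divided by n.  The
additive models (M1, M9) preserve ranks exactly; violation severity
grows with the interaction coefficient (M8: 0.05 < M3: 0.1 < M4: 0.2
< M7: 0.5).""")
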