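"""Boxplot visualisation of per-replicate stratum estimates.

Matplotlib is imported lazily so the simulation machinery has no hard
plotting dependency.
"""

from __future__ import annotations

from .metrics import ScenarioSummary


def plot_stratum_estimates(summaries: dict[str, ScenarioSummary],
                           path: str | None = None, truth: float = 0.0):
    """One panel per method: boxplots of the replicate stratum-specific
    Wald estimates, with the true effect marked.

    Returns the matplotlib figure; saves it when ``path`` is given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(summaries), sharey=True,
                             figsize=(5 * len(summaries), 4))
    if len(summaries) == 1:
        axes = [axes]
    for ax, (method, s) in zip(axes, summaries.items()):
        if s.estimates is None:
            raise ValueError("summary lacks per-replicate estimates")
        ax.boxplot([s.estimates[:, j] for j in range(s.estimates.shape[1])],
                   showfliers=False)
        ax.axhline(truth, color="grey", lw=0.8, ls="--")
        ax.set_title(method.replace("_", "-"))
        ax.set_xlabel("stratum")
    axes[0].set_ylabel("MR estimate")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
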