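"""Replicate loops, scenario grids and covariate-adjustment experiments.

:func:`run_scenario` is the workhorse: generate a cohort per replicate
from a deterministic child seed, stratify it with each requested
method, estimate the stratum-specific and full-sample Wald ratios,
compute Cochran's Q, and aggregate into one
:class:`~nlmrsim.metrics.ScenarioSummary` per method.  Results are
invariant to the order replicates are executed in, because replicate
``r`` always draws from the child generator of ``(seed, r)``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np

from .config import ScenarioConfig, child_rng
from .dgp import generate_cohort, generate_error_prone_confounder
from .estimation import estimate_strata
from .metrics import ScenarioSummary, cochran_q
from .stratification import stratify_doubly_ranked, stratify_residual

logger = logging.getLogger("nlmrsim")

METHODS = ("residual", "doubly_ranked")

_STRATIFIERS = {
    "residual": stratify_residual,
    "doubly_ranked": stratify_doubly_ranked,
}


def paper_scale(config: ScenarioConfig) -> ScenarioConfig:
    """Return the config at full published scale (n = 100,000 cohorts,
    100 replicates)."""
    return config.with_(n=100_000, n_replicates=100)


def run_scenario(config: ScenarioConfig,
                 methods: Sequence[str] = METHODS,
                 adjust: str | None = None,
                 u_error_r: float = 0.8,
                 second_order: bool = False,
                 max_failures: float = 0.05
                 ) -> dict[str, ScenarioSummary]:
    """Run one scenario end to end.

    Parameters
    ----------
    config : scenario settings (n, coefficients, replicates, seed).
    methods : stratification methods to apply.
    adjust : ``None`` (unadjusted, the default analysis), ``"u"``
        (within-stratum regressions adjust for the true modifier), or
        ``"u_error"`` (adjust for an error-prone measurement of it with
        correlation ``u_error_r``).  Stratification itself is never
        adjusted.
    max_failures : abort the scenario when more than this fraction of
        replicates fails.

    Returns one summary per method, each echoing the config.
    """
    unknown = set(methods) - set(_STRATIFIERS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if adjust not in (None, "u", "u_error"):
        raise ValueError(f"adjust must be None, 'u' or 'u_error', got {adjust!r}")
    R, S = config.n_replicates, config.n_strata
    est = {m: np.full((R, S), np.nan) for m in methods}
    ses = {m: np.full((R, S), np.nan) for m in methods}
    qp = {m: np.full(R, np.nan) for m in methods}
    full_est = {m: np.full(R, np.nan) for m in methods}
    full_se = {m: np.full(R, np.nan) for m in methods}
    failures = 0
    for r in range(R):
        rng = child_rng(config.seed, r)
        try:
            cohort = generate_cohort(config, rng=rng)
            covariates = None
            if adjust == "u":
                covariates = cohort.u
            elif adjust == "u_error":
                covariates = generate_error_prone_confounder(
                    cohort.u, u_error_r, rng=rng)
            tie_seed = int(rng.integers(2 ** 31))
            for m in methods:
                assignment = _STRATIFIERS[m](cohort, S, tie_seed=tie_seed)
                estimates = estimate_strata(cohort, assignment,
                                            covariates=covariates,
                                            second_order=second_order)
                full, strata = estimates[0], estimates[1:]
                est[m][r] = [e.wald for e in strata]
                ses[m][r] = [e.se_wald for e in strata]
                _, _, qp[m][r] = cochran_q(est[m][r], ses[m][r])
                full_est[m][r] = full.wald
                full_se[m][r] = full.se_wald
        except Exception:
            failures += 1
            logger.exception("replicate %d of scenario seed=%s failed "
                             "(child seed (%s, %d))",
                             r, config.seed, config.seed, r)
            if failures > max_failures * R:
                raise RuntimeError(
                    f"more than {max_failures:.0%} of replicates failed")
    ok = ~np.isnan(qp[methods[0]])
    summaries = {}
    for m in methods:
        summaries[m] = ScenarioSummary.from_replicates(
            m, est[m][ok], ses[m][ok], qp[m][ok],
            full_est[m][ok], full_se[m][ok],
            config_echo=config.to_dict())
    return summaries


@dataclass
class GridSpec:
    """A base scenario plus a Cartesian sweep over config fields."""

    base: ScenarioConfig
    sweep: dict[str, list[Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = set(self.base.to_dict())
        bad = set(self.sweep) - valid
        if bad:
            raise ValueError(f"swept fields not on ScenarioConfig: {sorted(bad)}")

    @property
    def size(self) -> int:
        out = 1
        for vals in self.sweep.values():
            out *= len(vals)
        return out

    def configs(self) -> Iterable[tuple[dict[str, Any], ScenarioConfig]]:
        """Yield (sweep-point, config) pairs; each point gets an
        independent child seed derived from its index."""
        keys = list(self.sweep)
        for i, combo in enumerate(itertools.product(
                *(self.sweep[k] for k in keys))):
            point = dict(zip(keys, combo))
            seed = int(np.random.SeedSequence(
                (self.base.seed, 10_000 + i)).generate_state(1)[0] % (2 ** 31))
            yield point, self.base.with_(**point, seed=seed)


def run_grid(grid: GridSpec, methods: Sequence[str] = METHODS,
             adjust: str | None = None
             ) -> list[dict[str, Any]]:
    """Run every scenario in the grid; failures are recorded and the
    remaining scenarios continue.

    Returns a list of ``{"point": ..., "config": ..., "summaries": ...}``
    records (``"error"`` replaces ``"summaries"`` on failure).
    """
    logger.info("running grid of %d scenarios", grid.size)
    results = []
    for point, cfg in grid.configs():
        rec: dict[str, Any] = {"point": point, "config": cfg.to_dict()}
        try:
            rec["summaries"] = run_scenario(cfg, methods, adjust=adjust)
        except Exception as err:  # keep sweeping
            logger.exception("scenario %s failed", point)
            rec["error"] = repr(err)
        results.append(rec)
    return results


def grid_frame(results: list[dict[str, Any]]):
    """Long-format table over grid results: one row per (sweep point,
    method, stratum)."""
    import pandas as pd
    rows = []
    for rec in results:
        if "summaries" not in rec:
            continue
        for m, s in rec["summaries"].items():
            df = s.to_frame()
            for k, v in rec["point"].items():
                df[k] = v
            df["pooled_mse"] = s.pooled_mse
            df["het_rate"] = s.het_rate
            rows.append(df)
    return pd.concat(rows, ignore_index=True)
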