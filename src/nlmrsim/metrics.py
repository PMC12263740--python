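"""Scenario-level performance measures.

All simulated scenarios have a true causal effect of zero, so stratum
estimates should center on 0 and show no between-stratum
heterogeneity.  Departures are summarized by:

* per-stratum and pooled mean squared error about the truth,
* Cochran's Q across strata (fixed-effect, inverse-variance weights)
  and the proportion of replicates with nominal heterogeneity
  (Q p-value < 0.05),
* the coverage of symmetric normal-quantile confidence intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats


def cochran_q(estimates, ses) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic across estimates.

    Fixed-effect inverse-variance pooling: with weights
    ``w_i = 1/se_i^2`` and pooled mean ``theta = sum(w theta)/sum(w)``,
    ``Q = sum w_i (theta_i - theta)^2`` is chi-square with ``k-1``
    degrees of freedom under homogeneity.  Returns ``(Q, df, p)``.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if len(est) < 2:
        raise ValueError("need at least 2 estimates")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be > 0")
    w = 1.0 / se ** 2
    pooled = float(np.sum(w * est) / np.sum(w))
    q = float(np.sum(w * (est - pooled) ** 2))
    df = len(est) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def stratum_mse(estimates_by_replicate, truth: float = 0.0,
                allow_missing: bool = False) -> tuple[np.ndarray, float]:
    """Per-stratum and pooled mean squared error over replicates.

    ``estimates_by_replicate`` is an R x S matrix (replicates by
    strata).  The pooled value is the mean over replicates of the
    within-replicate across-strata mean of squared deviations — for a
    complete matrix this equals the grand mean.
    """
    m = np.asarray(estimates_by_replicate, dtype=float)
    if m.ndim == 1:
        m = m[None, :]
    if np.isnan(m).any() and not allow_missing:
        raise ValueError("missing estimates; pass allow_missing=True "
                         "for complete-case averaging")
    sq = (m - truth) ** 2
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        per_stratum = np.nanmean(sq, axis=0)
        pooled = float(np.nanmean(np.nanmean(sq, axis=1)))
    return per_stratum, pooled


def heterogeneity_rate(p_values, alpha: float = 0.05) -> float:
    """Fraction of replicates with heterogeneity p strictly below
    ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return float(np.mean(p < alpha))


def coverage(estimates, ses, truth: float = 0.0,
             level: float = 0.95) -> float:
    """Fraction of symmetric normal CIs that contain ``truth``."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.shape != se.shape:
        raise ValueError("estimates and ses must have matching shapes")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be > 0")
    z = stats.norm.ppf(0.5 + level / 2)
    return float(np.mean(np.abs(est - truth) <= z * se))


@dataclass
class ScenarioSummary:
    """Aggregated results of one (scenario, method) pair.

    ``estimates`` and ``ses`` are the raw R x S per-replicate stratum
    Wald matrices; summary fields are derived from them at
    construction via :meth:`from_replicates`.
    """

    method: str
    per_stratum_mean: np.ndarray
    per_stratum_se: np.ndarray      # Monte-Carlo SE of the stratum mean
    per_stratum_mse: np.ndarray
    pooled_mse: float
    het_rate: float
    coverage: np.ndarray
    n_replicates: int
    full_sample_mean: float
    full_sample_coverage: float
    config_echo: dict[str, Any] = field(default_factory=dict)
    estimates: np.ndarray | None = None
    ses: np.ndarray | None = None
    q_pvalues: np.ndarray | None = None

    @classmethod
    def from_replicates(cls, method: str, estimates: np.ndarray,
                        ses: np.ndarray, q_pvalues: np.ndarray,
                        full_estimates: np.ndarray, full_ses: np.ndarray,
                        truth: float = 0.0, alpha: float = 0.05,
                        config_echo: dict[str, Any] | None = None
                        ) -> "ScenarioSummary":
        estimates = np.asarray(estimates, dtype=float)
        ses = np.asarray(ses, dtype=float)
        R, S = estimates.shape
        per_mse, pooled = stratum_mse(estimates, truth)
        cov = np.array([coverage(estimates[:, s], ses[:, s], truth)
                        for s in range(S)])
        return cls(
            method=method,
            per_stratum_mean=estimates.mean(axis=0),
            per_stratum_se=estimates.std(axis=0, ddof=1) / np.sqrt(R),
            per_stratum_mse=per_mse,
            pooled_mse=pooled,
            het_rate=heterogeneity_rate(q_pvalues, alpha),
            coverage=cov,
            n_replicates=R,
            full_sample_mean=float(np.mean(full_estimates)),
            full_sample_coverage=coverage(full_estimates, full_ses, truth),
            config_echo=config_echo or {},
            estimates=estimates,
            ses=ses,
            q_pvalues=np.asarray(q_pvalues, dtype=float),
        )

    def to_dict(self, include_replicates: bool = False) -> dict[str, Any]:
        d: dict[str, Any] = {
            "method": self.method,
            "per_stratum_mean": self.per_stratum_mean.tolist(),
            "per_stratum_se": self.per_stratum_se.tolist(),
            "per_stratum_mse": self.per_stratum_mse.tolist(),
            "pooled_mse": self.pooled_mse,
            "het_rate": self.het_rate,
            "coverage": self.coverage.tolist(),
            "n_replicates": self.n_replicates,
            "full_sample_mean": self.full_sample_mean,
            "full_sample_coverage": self.full_sample_coverage,
            "config": self.config_echo,
        }
        if include_replicates and self.estimates is not None:
            d["estimates"] = self.estimates.tolist()
            d["ses"] = self.ses.tolist()
            d["q_pvalues"] = self.q_pvalues.tolist()
        return d

    def to_json(self, path: str | None = None, **kw) -> str:
        s = json.dumps(self.to_dict(**kw), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def to_frame(self):
        """Long-format per-stratum table (method, stratum, mean, mse,
        coverage)."""
        import pandas as pd
        S = len(self.per_stratum_mean)
        return pd.DataFrame({
            "method": self.method,
            "stratum": np.arange(1, S + 1),
            "mean": self.per_stratum_mean,
            "mc_se": self.per_stratum_se,
            "mse": self.per_stratum_mse,
            "coverage": self.coverage,
        })
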