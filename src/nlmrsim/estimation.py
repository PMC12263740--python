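"""One-sample Mendelian-randomization estimation.

Within the full sample and within each stratum, the instrument-exposure
and instrument-outcome slopes are estimated by ordinary least squares
and combined into the Wald ratio

    theta = beta_gy / beta_gx,

the standard single-instrument MR estimator.  The default standard
error is the first-order delta approximation ``se_gy / |beta_gx|``; a
second-order version that propagates the uncertainty in ``beta_gx`` is
available by flag.

The OLS slope and its classical (homoskedastic) standard error are
computed in closed form with numpy — these regressions sit in the
Monte-Carlo hot loop, where a full modelling framework would dominate
the runtime.  Tests cross-check them against statsmodels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dgp import Cohort
from .stratification import StratumAssignment

#: Strata with a partial F below this are flagged as weakly instrumented.
WEAK_F_THRESHOLD = 10.0


class UndefinedRatioError(ZeroDivisionError):
    """Wald ratio undefined because the IV-exposure slope is zero."""

    def __init__(self, stratum: int | None = None):
        self.stratum = stratum
        where = f" in stratum {stratum}" if stratum is not None else ""
        super().__init__(f"beta_gx = 0{where}: Wald ratio undefined")


@dataclass
class StratumEstimate:
    """IV-exposure, IV-outcome and Wald-ratio estimates for one stratum
    (stratum 0 denotes the full sample)."""

    stratum: int
    n: int
    beta_gx: float
    se_gx: float
    beta_gy: float
    se_gy: float
    wald: float
    se_wald: float
    f_stat: float
    weak_flag: bool

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        return self.wald - z * self.se_wald, self.wald + z * self.se_wald


def ols_beta(response, predictor, covariates=None) -> tuple[float, float]:
    """OLS slope of ``response`` on ``predictor`` (plus optional
    covariates) with its classical standard error."""
    y = np.asarray(response, dtype=float)
    g = np.asarray(predictor, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    cols = [np.ones(n), g]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == n and cov.shape[1] != n:
            cov = cov.T
        cols.extend(list(cov))
    X = np.column_stack(cols)
    p = X.shape[1]
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"singular design: {err}") from err
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("singular design (rank-deficient)")
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    se = math.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0))
    return float(beta[1]), se


def wald_ratio(beta_gx: float, se_gx: float, beta_gy: float, se_gy: float,
               second_order: bool = False,
               stratum: int | None = None) -> tuple[float, float]:
    """Wald ratio and its delta-method standard error.

    First order (default): ``se = se_gy / |beta_gx|``.  With
    ``second_order=True`` the uncertainty in the denominator is added:
    ``se = sqrt(se_gy^2/beta_gx^2 + beta_gy^2 se_gx^2 / beta_gx^4)``.
    """
    if beta_gx == 0:
        raise UndefinedRatioError(stratum)
    wald = beta_gy / beta_gx
    if second_order:
        se = math.sqrt(se_gy ** 2 / beta_gx ** 2
                       + beta_gy ** 2 * se_gx ** 2 / beta_gx ** 4)
    else:
        se = se_gy / abs(beta_gx)
    return wald, se


def _fast_slope_se(y: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    """Simple-regression slope and classical SE without building a
    design matrix (covariate-free hot path)."""
    n = len(y)
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = float(gc @ gc)
    if sxx == 0.0:
        raise np.linalg.LinAlgError("singular design: constant predictor")
    beta = float(gc @ yc) / sxx
    resid = yc - beta * gc
    sigma2 = float(resid @ resid) / (n - 2)
    return beta, math.sqrt(max(sigma2, 0.0) / sxx)


def estimate_strata(cohort: Cohort, assignment: StratumAssignment,
                    covariates=None, second_order: bool = False,
                    permissive: bool = False,
                    f_threshold: float = WEAK_F_THRESHOLD
                    ) -> list[StratumEstimate]:
    """Wald-ratio estimates for every stratum and for the full sample.

    Returns one :class:`StratumEstimate` per stratum ``1..S`` plus a
    stratum-0 entry for the full sample, in stratum order.  Optional
    covariates are adjusted for in both within-stratum regressions
    (stratification itself is never re-run here).  A zero IV-exposure
    slope raises :class:`UndefinedRatioError` unless ``permissive`` is
    set, in which case the estimate is returned with NaN Wald fields
    and ``weak_flag`` set.
    """
    g = np.asarray(cohort.g, dtype=float)
    x = np.asarray(cohort.x, dtype=float)
    y = np.asarray(cohort.y, dtype=float)
    cov = None
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == len(g) and cov.shape[1] != len(g):
            cov = cov.T  # -> (k, n)
    out: list[StratumEstimate] = []
    groups = [(0, np.arange(len(g)))]
    groups += [(s, assignment.indices(s)) for s in range(1, assignment.S + 1)]
    for s, idx in groups:
        if len(idx) < 3:
            raise ValueError(f"stratum {s} has {len(idx)} members; need >= 3")
        if cov is None:
            bgx, segx = _fast_slope_se(x[idx], g[idx])
            bgy, segy = _fast_slope_se(y[idx], g[idx])
        else:
            bgx, segx = ols_beta(x[idx], g[idx], cov[:, idx])
            bgy, segy = ols_beta(y[idx], g[idx], cov[:, idx])
        f_stat = (bgx / segx) ** 2 if segx > 0 else math.inf
        try:
            wald, se_wald = wald_ratio(bgx, segx, bgy, segy,
                                       second_order=second_order, stratum=s)
            weak = f_stat < f_threshold
        except UndefinedRatioError:
            if not permissive:
                raise
            wald, se_wald, weak = math.nan, math.nan, True
        out.append(StratumEstimate(stratum=s, n=len(idx), beta_gx=bgx,
                                   se_gx=segx, beta_gy=bgy, se_gy=segy,
                                   wald=wald, se_wald=se_wald,
                                   f_stat=f_stat, weak_flag=weak))
    return out
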