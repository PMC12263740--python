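"""Stratum assignment: the residual and doubly-ranked methods.

Both methods slice a cohort into ``S`` equal-count strata related to
the exposure, so that an instrumental-variable estimate can be formed
within each stratum.

* The *residual* method regresses the exposure on the instrument and
  cuts the residuals into quantile groups.  It assumes the genetic
  effect on the exposure is the same for everyone.
* The *doubly-ranked* method first ranks by the instrument into
  consecutive pre-strata of size ``S``, then ranks by the exposure
  within each pre-stratum; the j-th lowest exposure in every
  pre-stratum lands in stratum j.  It relies on the weaker assumption
  that an individual's exposure rank would be unchanged under any
  counterfactual instrument value.

Ties are broken by a random permutation drawn once per call from a
dedicated tie seed, so assignments are deterministic, independent of
input row order in the tied values, and free of input-order artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dgp import Cohort


@dataclass
class StratumAssignment:
    """Per-individual stratum labels in ``1..S`` plus method metadata."""

    stratum: np.ndarray
    method: str
    S: int
    pre_stratum: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.stratum = np.asarray(self.stratum, dtype=int)
        labels = np.unique(self.stratum)
        if labels.min() < 1 or labels.max() > self.S:
            raise ValueError(f"stratum labels must lie in 1..{self.S}")

    def __len__(self) -> int:
        return len(self.stratum)

    def indices(self, s: int) -> np.ndarray:
        return np.flatnonzero(self.stratum == s)


def _tie_broken_order(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Argsort of ``values`` with ties broken by a random permutation."""
    perm = rng.permutation(len(values))
    return np.lexsort((perm, values))


def ols_residuals(response, predictor, covariates=None):
    """OLS residuals of ``response`` on ``predictor`` (plus optional
    covariate columns), with the fitted slope and intercept.

    Returns ``(residuals, slope, intercept)`` where ``slope`` is the
    coefficient on ``predictor``.
    """
    y = np.asarray(response, dtype=float)
    g = np.asarray(predictor, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    cols = [np.ones_like(g), g]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == len(g) and cov.shape[1] != len(g):
            cov = cov.T
        cols.extend(list(cov))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "singular design: predictor (or a covariate) is constant or collinear")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return resid, float(beta[1]), float(beta[0])


def stratify_residual(cohort: Cohort, S: int, covariates=None,
                      tie_seed: int = 0) -> StratumAssignment:
    """Residual-method strata: quantile groups of the exposure
    residualized on the instrument (and optional covariates).

    Stratum 1 holds the lowest residuals.  Strata are equal-count
    (sizes differ by at most 1 when ``S`` does not divide ``n``).
    """
    _check_sizes(len(cohort), S)
    resid, _, _ = ols_residuals(cohort.x, cohort.g, covariates)
    rng = np.random.default_rng(tie_seed)
    order = _tie_broken_order(resid, rng)
    n = len(resid)
    sizes = np.full(S, n // S)
    sizes[: n % S] += 1
    labels = np.repeat(np.arange(1, S + 1), sizes)
    stratum = np.empty(n, dtype=int)
    stratum[order] = labels
    return StratumAssignment(stratum=stratum, method="residual", S=S)


def stratify_doubly_ranked(cohort: Cohort, S: int,
                           tie_seed: int = 0) -> StratumAssignment:
    """Doubly-ranked strata.

    Individuals are sorted by the instrument and cut into consecutive
    pre-strata of size ``S`` (the final pre-stratum may hold ``m < S``
    members).  Within each pre-stratum, the j-th lowest exposure is
    assigned stratum ``j`` (for the size-``m`` remainder,
    ``ceil(j*S/m)``), so every complete pre-stratum contributes exactly
    one member to each stratum.
    """
    n = len(cohort)
    _check_sizes(n, S)
    rng = np.random.default_rng(tie_seed)
    g_order = _tie_broken_order(np.asarray(cohort.g, dtype=float), rng)
    x = np.asarray(cohort.x, dtype=float)
    perm_x = rng.permutation(n)  # tie-break permutation for the exposure
    stratum = np.empty(n, dtype=int)
    pre_stratum = np.empty(n, dtype=int)
    n_full, m = divmod(n, S)
    # complete pre-strata, vectorized: reshape into (n_full, S) blocks
    if n_full:
        block = g_order[: n_full * S].reshape(n_full, S)
        within = np.lexsort((perm_x[block].T, x[block].T), axis=0).T
        ranks = np.empty_like(within)
        rows = np.arange(n_full)[:, None]
        ranks[rows, within] = np.arange(1, S + 1)
        stratum[block] = ranks
        pre_stratum[block] = np.repeat(np.arange(1, n_full + 1), S).reshape(n_full, S)
    if m:
        tail = g_order[n_full * S:]
        order = tail[np.lexsort((perm_x[tail], x[tail]))]
        j = np.arange(1, m + 1)
        stratum[order] = np.ceil(j * S / m).astype(int)
        pre_stratum[tail] = n_full + 1
    return StratumAssignment(stratum=stratum, method="doubly_ranked", S=S,
                             pre_stratum=pre_stratum)


def _check_sizes(n: int, S: int) -> None:
    if S < 2:
        raise ValueError(f"S must be >= 2, got {S}")
    if n < 2 * S:
        raise ValueError(f"n={n} too small for S={S}: need n >= 2*S")
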