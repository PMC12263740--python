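"""Delimited-text round-trips for cohorts, assignments and estimates.

Cohorts travel as TSV with a header (id, g, u, v, e_x, e_y, x, y,
alpha, modifier columns); optional columns are simply absent.  This is
also the dialect for user-supplied individual-level tables fed to the
falsification test (id, prs/instrument, exposure, outcome, covariates).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dgp import Cohort
from .estimation import StratumEstimate
from .stratification import StratumAssignment

_CORE = ("g", "u", "v", "e_x", "e_y", "x", "y", "alpha")


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    data: dict[str, np.ndarray] = {"id": cohort.id}
    for name in _CORE:
        v = getattr(cohort, name)
        if v is not None:
            data[name] = v
    for name, v in cohort.modifiers.items():
        if name not in data:
            data[name] = v
    return pd.DataFrame(data)


def cohort_to_tsv(cohort: Cohort, path: str) -> None:
    cohort_to_frame(cohort).to_csv(path, sep="\t", index=False)


def cohort_from_frame(df: pd.DataFrame, model_id: str | None = None) -> Cohort:
    if "x" not in df or "g" not in df:
        raise ValueError("cohort table needs at least 'g' and 'x' columns")
    n = len(df)
    get = lambda c: df[c].to_numpy(dtype=float) if c in df else None
    modifiers = {c: df[c].to_numpy(dtype=float) for c in df.columns
                 if c not in _CORE and c != "id"}
    return Cohort(
        g=get("g"),
        u=get("u") if "u" in df else np.zeros(n),
        v=get("v"),
        e_x=get("e_x") if "e_x" in df else np.zeros(n),
        e_y=get("e_y") if "e_y" in df else np.zeros(n),
        x=get("x"),
        y=get("y") if "y" in df else np.zeros(n),
        alpha=get("alpha"),
        modifiers=modifiers,
        id=df["id"].to_numpy() if "id" in df else None,
        model_id=model_id,
    )


def cohort_from_tsv(path: str, model_id: str | None = None) -> Cohort:
    df = pd.read_csv(path, sep="\t")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()[:10]
        raise ValueError(f"missing values in rows {bad}")
    return cohort_from_frame(df, model_id=model_id)


def assignment_to_frame(assignment: StratumAssignment,
                        ids=None) -> pd.DataFrame:
    n = len(assignment)
    df = pd.DataFrame({
        "id": ids if ids is not None else np.arange(1, n + 1),
        "method": assignment.method,
        "stratum": assignment.stratum,
    })
    if assignment.pre_stratum is not None:
        df.insert(2, "pre_stratum", assignment.pre_stratum)
    return df


def estimates_to_frame(estimates: list[StratumEstimate],
                       method: str = "", replicate: int = 0) -> pd.DataFrame:
    return pd.DataFrame([{
        "method": method, "replicate": replicate, "stratum": e.stratum,
        "n": e.n, "beta_gx": e.beta_gx, "se_gx": e.se_gx,
        "beta_gy": e.beta_gy, "se_gy": e.se_gy, "wald": e.wald,
        "se_wald": e.se_wald, "f_stat": e.f_stat, "weak_flag": e.weak_flag,
    } for e in estimates])
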