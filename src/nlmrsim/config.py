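"""Scenario configuration and the seeding contract.

A :class:`ScenarioConfig` fully parameterizes one Monte-Carlo scenario:
the structural coefficients of the exposure/outcome model, the cohort
size, the replicate count and the base seed.  Replicate ``r`` of a
scenario always uses the child generator returned by
:func:`child_rng`, so any single replicate can be regenerated without
running the ones before it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

#: Table-style model identifiers for the rank-preservation suite.
RANK_MODEL_IDS = tuple(f"M{i}" for i in range(1, 14))

_VALID_MODEL_IDS = ("A", "B") + RANK_MODEL_IDS


class ConfigError(ValueError):
    """A configuration field failed validation; the message names it."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete parameterization of one simulation scenario.

    The exposure and outcome follow::

        x = beta_g*g + b_ux*u + b_gux*g*u + b_vx*v + e_x
        y = b_uy*u + b_vy*v + e_y

    with ``g, u, v, e_x, e_y`` independent normals of mean ``mu`` and
    SD ``sigma`` (``g`` uses ``sigma_g``).  ``b_gux != 0`` introduces
    genetic effect heterogeneity (a gene-by-environment interaction).

    Parameters
    ----------
    n : cohort size per replicate.
    n_replicates : Monte-Carlo replicates per scenario.
    n_strata : number of strata used by both stratification methods.
    beta_g : homogeneous part of the instrument->exposure effect.
    b_ux, b_gux, b_uy : effects of the modifier/confounder ``u``.
    b_vx, b_vy : effects of the second confounder ``v`` (model B only).
    mu, sigma : mean and SD shared by ``g, u, v`` and the error terms
        (2 and 1 in the main simulations; 0 and 1 in the
        rank-preservation simulations).
    sigma_g : SD of ``g``; defaults to ``sigma``.
    seed : base seed; replicates derive child seeds from it.
    model_id : "A" (single modifier ``u``) or "B" (adds the independent
        exposure-outcome confounder ``v``).
    """

    n: int
    n_replicates: int = 100
    n_strata: int = 10
    beta_g: float = 0.3
    b_ux: float = 0.0
    b_gux: float = 0.0
    b_uy: float = 0.0
    b_vx: float = 0.0
    b_vy: float = 0.0
    mu: float = 2.0
    sigma: float = 1.0
    sigma_g: float | None = None
    seed: int = 0
    model_id: str = "A"

    def __post_init__(self) -> None:
        if self.sigma_g is None:
            object.__setattr__(self, "sigma_g", self.sigma)
        for name in ("n", "n_replicates", "n_strata"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.n < 2 * self.n_strata:
            raise ConfigError(
                f"n={self.n} too small for n_strata={self.n_strata}: "
                "every stratum needs at least 2 members (n >= 2*n_strata)"
            )
        if self.sigma <= 0:
            raise ConfigError(f"sigma must be > 0, got {self.sigma}")
        if self.sigma_g <= 0:
            raise ConfigError(f"sigma_g must be > 0, got {self.sigma_g}")
        if self.model_id not in _VALID_MODEL_IDS:
            raise ConfigError(
                f"model_id must be one of {_VALID_MODEL_IDS}, got {self.model_id!r}"
            )
        if self.model_id == "A" and (self.b_vx != 0.0 or self.b_vy != 0.0):
            raise ConfigError(
                "model_id 'A' has no confounder v: b_vx and b_vy must be 0 "
                f"(got b_vx={self.b_vx}, b_vy={self.b_vy}); use model_id='B'"
            )

    # -- derived helpers -------------------------------------------------

    def with_(self, **updates: Any) -> "ScenarioConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **updates)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config fields: {sorted(extra)}")
        if "b_v" in d:  # single-b_v shorthand
            raise ConfigError("use b_vx/b_vy (or simulation_b(..., b_v=...))")
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def simulation_a(
    n: int = 100_000,
    b_ux: float = 0.3,
    b_gux: float = -0.1,
    b_uy: float = 0.3,
    **kw: Any,
) -> ScenarioConfig:
    """Scenario-A config (single modifier ``u``, means of 2)."""
    return ScenarioConfig(
        n=n, b_ux=b_ux, b_gux=b_gux, b_uy=b_uy, model_id="A", **kw
    )


def simulation_b(
    n: int = 100_000,
    b_ux: float = -0.3,
    b_gux: float = -0.1,
    b_v: float | None = 1.0,
    b_vx: float | None = None,
    b_vy: float | None = None,
    **kw: Any,
) -> ScenarioConfig:
    """Scenario-B config: ``u`` modifies the genetic effect only
    (b_uy = 0) while ``v`` confounds exposure and outcome.

    A single ``b_v`` sets both ``b_vx`` and ``b_vy``; pass them
    explicitly to decouple.
    """
    if b_vx is None:
        b_vx = b_v
    if b_vy is None:
        b_vy = b_v
    return ScenarioConfig(
        n=n, b_ux=b_ux, b_gux=b_gux, b_uy=0.0,
        b_vx=b_vx, b_vy=b_vy, model_id="B", **kw
    )


def child_seed_sequence(base_seed: int, replicate: int) -> np.random.SeedSequence:
    """Deterministic child seed for one replicate of a scenario."""
    return np.random.SeedSequence((int(base_seed), int(replicate)))


def child_rng(base_seed: int, replicate: int) -> np.random.Generator:
    """Generator for replicate ``replicate`` under ``base_seed``."""
    return np.random.default_rng(child_seed_sequence(base_seed, replicate))
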