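"""Synthetic cohort generators.

Three families of cohorts are produced here:

* :func:`generate_cohort` — the Monte-Carlo cohorts of the two main
  simulation designs (a modifier/confounder ``u``, optionally a second
  confounder ``v``), with every structural variable normal of mean
  ``mu`` and SD ``sigma``.
* :func:`generate_model_cohort` — the thirteen exposure models (M1-M13)
  used to probe the rank-preserving assumption, with means 0.
* :func:`generate_empirical_standin` — a dosage-based polygenic-score
  cohort standing in for real biobank data in the falsification test.
  Its design (allele-frequency range, weight distribution, skew
  mechanism) is package plumbing, not taken from any study.

All generators are deterministic given their seed, and every cohort
stores the components (``g, u, v, e_x, e_y, alpha``) from which its
exposure and outcome can be recomputed bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .config import RANK_MODEL_IDS, ConfigError, ScenarioConfig


@dataclass
class Cohort:
    """Per-individual arrays for one simulated cohort.

    ``x`` and ``y`` are deterministic functions of the stored
    components under the generating model; :meth:`recompute_x`
    re-evaluates the exposure formula for verification or for
    counterfactual instrument levels.
    """

    g: np.ndarray
    u: np.ndarray
    e_x: np.ndarray
    e_y: np.ndarray
    x: np.ndarray
    y: np.ndarray
    v: np.ndarray | None = None
    alpha: np.ndarray | None = None
    modifiers: dict[str, np.ndarray] = field(default_factory=dict)
    id: np.ndarray | None = None
    config: ScenarioConfig | None = None
    model_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.g)
        vectors = {"u": self.u, "e_x": self.e_x, "e_y": self.e_y,
                   "x": self.x, "y": self.y}
        if self.v is not None:
            vectors["v"] = self.v
        if self.alpha is not None:
            vectors["alpha"] = self.alpha
        vectors.update(self.modifiers)
        for name, vec in vectors.items():
            if len(vec) != n:
                raise ValueError(f"cohort vector {name!r} has length "
                                 f"{len(vec)}, expected {n}")
        if self.id is None:
            self.id = np.arange(1, n + 1)

    def __len__(self) -> int:
        return len(self.g)

    def recompute_x(self, g: np.ndarray | None = None) -> np.ndarray:
        """Re-evaluate the exposure formula, optionally at a
        counterfactual instrument vector ``g`` (same length), reusing
        this cohort's stored ``u``, errors and ``alpha``."""
        gg = self.g if g is None else np.asarray(g, dtype=float)
        if self.model_id in RANK_MODEL_IDS:
            spec = MODEL_REGISTRY[self.model_id]
            return spec.formula(gg, self.u, self.e_x, self.alpha)
        c = self.config
        if c is None:
            raise ValueError("cohort has no config; cannot recompute x")
        x = c.beta_g * gg + c.b_ux * self.u + c.b_gux * gg * self.u + self.e_x
        if self.v is not None:
            x = x + c.b_vx * self.v
        return x

    def recompute_y(self) -> np.ndarray:
        c = self.config
        if c is None:
            raise ValueError("cohort has no config; cannot recompute y")
        y = c.b_uy * self.u + self.e_y
        if self.v is not None:
            y = y + c.b_vy * self.v
        return y


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, (np.random.Generator, np.random.SeedSequence)):
        return np.random.default_rng(seed)
    return np.random.default_rng(int(seed))


def generate_cohort(config: ScenarioConfig,
                    rng: np.random.Generator | None = None) -> Cohort:
    """Draw one cohort under the main simulation design.

    ``g, u, v, e_x, e_y`` are mutually independent ``N(mu, sigma)``
    (``g`` uses ``sigma_g``); the confounder ``v`` is only drawn for
    model "B" (and omitted when both its coefficients are zero).
    """
    c = config
    if c.model_id not in ("A", "B"):
        raise ConfigError(f"generate_cohort handles model_id 'A'/'B'; "
                          f"got {c.model_id!r} (use generate_model_cohort)")
    r = rng if rng is not None else _rng(c.seed)
    n = c.n
    g = r.normal(c.mu, c.sigma_g, n)
    u = r.normal(c.mu, c.sigma, n)
    use_v = c.model_id == "B" and not (c.b_vx == 0.0 and c.b_vy == 0.0)
    v = r.normal(c.mu, c.sigma, n) if use_v else None
    e_x = r.normal(c.mu, c.sigma, n)
    e_y = r.normal(c.mu, c.sigma, n)
    x = c.beta_g * g + c.b_ux * u + c.b_gux * g * u + e_x
    y = c.b_uy * u + e_y
    if v is not None:
        x = x + c.b_vx * v
        y = y + c.b_vy * v
    return Cohort(g=g, u=u, v=v, e_x=e_x, e_y=e_y, x=x, y=y,
                  config=c, model_id=c.model_id)


# ---------------------------------------------------------------------
# Rank-preservation exposure models M1-M13
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One exposure model: a formula x = f(g, u, eps[, alpha]) plus the
    distributional settings it requires."""

    model_id: str
    description: str
    formula: Callable[..., np.ndarray]
    sigma_g: float = 1.0
    has_alpha: bool = False
    # conditional mean of the per-individual genetic effect alpha given
    # (eps, u); alpha ~ N(alpha_mean(eps, u), 0.1^2)
    alpha_mean: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    has_interaction: bool = False


_ALPHA_SD = 0.1


def _alpha_formula(g, u, e, alpha):
    return alpha * g + u + e


MODEL_REGISTRY: dict[str, ModelSpec] = {
    "M1": ModelSpec("M1", "linear, full U effect",
                    lambda g, u, e, a=None: 0.3 * g + u + e),
    "M2": ModelSpec("M2", "linear, reduced U effect",
                    lambda g, u, e, a=None: 0.3 * g + 0.1 * u + e),
    "M3": ModelSpec("M3", "small GxU interaction",
                    lambda g, u, e, a=None: 0.3 * g + u + 0.1 * g * u + e,
                    has_interaction=True),
    "M4": ModelSpec("M4", "large GxU interaction",
                    lambda g, u, e, a=None: 0.3 * g + u + 0.2 * g * u + e,
                    has_interaction=True),
    "M5": ModelSpec("M5", "GxU interaction without a main U effect",
                    lambda g, u, e, a=None: 0.3 * g + 0.1 * g * u + e,
                    has_interaction=True),
    "M6": ModelSpec("M6", "negative GxU interaction",
                    lambda g, u, e, a=None: 0.3 * g + u - 0.2 * g * u + e,
                    has_interaction=True),
    "M7": ModelSpec("M7", "large GxU, small U effect",
                    lambda g, u, e, a=None: 0.3 * g + 0.1 * u + 0.5 * g * u + e,
                    has_interaction=True),
    "M8": ModelSpec("M8", "very small GxU interaction",
                    lambda g, u, e, a=None: 0.3 * g + u + 0.05 * g * u + e,
                    has_interaction=True),
    "M9": ModelSpec("M9", "quadratic instrument effect, additive U",
                    lambda g, u, e, a=None: 0.3 * g + 0.1 * g ** 2 + u + e),
    "M10": ModelSpec("M10", "affine-in-U slope on (G+5), narrow G",
                     lambda g, u, e, a=None:
                     -10.0 + (1.5 + 0.4 * u) * (g + 5.0) + u + e,
                     sigma_g=0.25, has_interaction=True),
    "M11": ModelSpec("M11", "individual effect tracking the error term",
                     _alpha_formula, has_alpha=True,
                     alpha_mean=lambda e, u: 0.3 + 0.1 * e,
                     has_interaction=True),
    "M12": ModelSpec("M12", "individual effect tracking error and U equally",
                     _alpha_formula, has_alpha=True,
                     alpha_mean=lambda e, u: 0.3 + 0.1 / np.sqrt(2) * (e + u),
                     has_interaction=True),
    "M13": ModelSpec("M13", "individual effect tracking U only",
                     _alpha_formula, has_alpha=True,
                     alpha_mean=lambda e, u: 0.3 + 0.1 * u,
                     has_interaction=True),
}


def generate_model_cohort(model_id: str, n: int, seed=0,
                          rng: np.random.Generator | None = None,
                          *, _components: dict | None = None) -> Cohort:
    """Draw a cohort under one of the thirteen rank-test exposure models.

    ``g``, ``u`` and the error term are standard normal (mean 0, SD 1),
    except that M10 uses SD(g) = 0.25.  For the individual-effect
    models (M11-M13) the error is drawn first, then the per-individual
    genetic effect ``alpha`` from its conditional normal, then the
    exposure; ``alpha`` is stored on the cohort.

    ``_components`` is a test hook injecting explicit ``g``/``u``/``e``
    (and optionally ``alpha``) vectors in place of random draws.
    """
    if model_id not in MODEL_REGISTRY:
        raise ConfigError(f"unknown model_id {model_id!r}; "
                          f"valid ids: {', '.join(MODEL_REGISTRY)}")
    if n < 2:
        raise ConfigError(f"n must be >= 2, got {n}")
    spec = MODEL_REGISTRY[model_id]
    r = rng if rng is not None else _rng(seed)
    if _components is not None:
        g = np.asarray(_components["g"], dtype=float)
        u = np.asarray(_components["u"], dtype=float)
        e = np.asarray(_components["e"], dtype=float)
        alpha = _components.get("alpha")
    else:
        g = r.normal(0.0, spec.sigma_g, n)
        u = r.normal(0.0, 1.0, n)
        e = r.normal(0.0, 1.0, n)
        alpha = None
    if spec.has_alpha:
        if alpha is None:
            alpha = r.normal(spec.alpha_mean(e, u), _ALPHA_SD)
        else:
            alpha = np.asarray(alpha, dtype=float)
        x = spec.formula(g, u, e, alpha)
    else:
        x = spec.formula(g, u, e)
    # outcome is pure noise here: the rank suite studies the exposure
    # model only, and the "violation without bias" check needs an
    # outcome free of u
    e_y = np.zeros(len(g)) if _components is not None else r.normal(0.0, 1.0, len(g))
    return Cohort(g=g, u=u, e_x=e, e_y=e_y, x=x, y=e_y.copy(),
                  alpha=alpha if spec.has_alpha else None, model_id=model_id)


# ---------------------------------------------------------------------
# Error-prone confounder measurement
# ---------------------------------------------------------------------

def generate_error_prone_confounder(u: np.ndarray, target_correlation: float,
                                    seed=0,
                                    rng: np.random.Generator | None = None
                                    ) -> np.ndarray:
    """Return a noisy measurement of ``u`` with a chosen correlation.

    Constructs ``u_error = r*u + sd(u)*sqrt(1-r^2)*z`` with ``z``
    independent standard normal, so the population correlation with
    ``u`` equals ``target_correlation`` and the variance matches
    ``u``'s.  Used to emulate adjusting for an imperfectly measured
    confounder.
    """
    u = np.asarray(u, dtype=float)
    sd_u = u.std(ddof=1)
    if sd_u == 0:
        raise ValueError("u is constant: correlation with it is undefined")
    r_target = float(target_correlation)
    if not 0 < r_target <= 1:
        raise ValueError(f"target_correlation must be in (0, 1], got {r_target}")
    if r_target == 1.0:
        return u.copy()
    gen = rng if rng is not None else _rng(seed)
    z = gen.normal(0.0, 1.0, len(u))
    return r_target * u + sd_u * np.sqrt(1.0 - r_target ** 2) * z


# ---------------------------------------------------------------------
# Stand-in "empirical" cohort for the falsification test
# ---------------------------------------------------------------------

def generate_empirical_standin(n: int, n_variants: int = 50,
                               heterogeneity: float = 0.0,
                               skew: bool = False, seed=0,
                               beta_g: float = 0.3,
                               rng: np.random.Generator | None = None
                               ) -> Cohort:
    """Synthetic polygenic-score cohort for exercising the
    falsification test when no real data are at hand.

    The score ``g`` is a weighted sum of ``n_variants`` biallelic
    dosages (Binomial(2, f), allele frequencies uniform on
    [0.05, 0.95], positive half-normal weights drawn once per call).
    A latent illness-like modifier ``m ~ N(0,1)`` scales the genetic
    effect: with the standardized score ``g_std``,

        x = (beta_g + heterogeneity*m) * g_std + m + e_x

    optionally exponentiated and re-standardized to give the exposure a
    right skew.  Both ``x`` and ``g`` are returned scaled to mean 0 /
    SD 1, and ``m`` is stored under ``modifiers['m']``.

    Every design choice here (frequency range, weight law, skew
    mechanism) is synthetic plumbing chosen for plausibility, not an
    emulation of any particular dataset.
    """
    if n_variants < 1:
        raise ConfigError(f"n_variants must be >= 1, got {n_variants}")
    r = rng if rng is not None else _rng(seed)
    freqs = r.uniform(0.05, 0.95, n_variants)
    weights = np.abs(r.normal(0.0, 1.0, n_variants))
    dosages = r.binomial(2, freqs, size=(n, n_variants)).astype(float)
    g_raw = dosages @ weights
    g_std = (g_raw - g_raw.mean()) / g_raw.std(ddof=1)
    m = r.normal(0.0, 1.0, n)
    e_x = r.normal(0.0, 1.0, n)
    x = (beta_g + heterogeneity * m) * g_std + m + e_x
    if skew:
        x = np.exp((x - x.mean()) / x.std(ddof=1))
    x_scale = x.std(ddof=1)  # raw-scale coefficients = fitted * x_scale
    x = (x - x.mean()) / x_scale
    e_y = np.zeros(n)
    return Cohort(g=g_std, u=m, e_x=e_x, e_y=e_y, x=x, y=e_y.copy(),
                  modifiers={"m": m}, model_id="standin",
                  meta={"x_scale": float(x_scale), "beta_g": beta_g,
                        "heterogeneity": heterogeneity, "skew": bool(skew)})
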