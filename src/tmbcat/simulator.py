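"""Synthetic oncology-trial cohorts with correlated binary/survival endpoints.

The generator draws, per patient, a latent true burden ``TMB*`` from a
lognormal law, correlated random effects ``(u, v)``, a Bernoulli tumor
response through a logit link, a proportional-hazards event time by
inverse transform of the cumulative hazard, an independent censoring
time (exponential with an administrative cap), and an observed
``TMB = TMB* + N(0, sigma_e^2)`` truncated at zero.

TMB effects on the two endpoint scales are declarative piecewise
functions so that scenario presets can live in versioned YAML files:

* ``consistent`` — both effects change in the same direction at one
  planted cutpoint; a single threshold (k = 1) is optimal.
* ``inconsistent`` — the response and hazard effects disagree over a
  middle TMB band; two thresholds (k = 2) are optimal.
* ``null`` — no TMB effect on either endpoint, with realistic
  patient-level heterogeneity retained.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import yaml

from .data_model import Cohort

__all__ = [
    "SimulationConfig",
    "EffectSpec",
    "simulate_cohort",
    "scenario_presets",
    "true_joint_probabilities",
]

_PRESET_NAMES = ("consistent", "inconsistent", "null")


def _make_effect(spec: Mapping | Callable[[np.ndarray], np.ndarray]):
    """Build a vectorized TMB-effect function from a declarative spec."""
    if callable(spec):
        return spec
    kind = spec.get("kind", "constant")
    if kind == "constant":
        value = float(spec.get("value", 0.0))
        return lambda x: np.full_like(np.asarray(x, dtype=float), value)
    if kind == "linear":
        slope = float(spec["slope"])
        ref = float(spec.get("ref", 0.0))
        return lambda x: slope * (np.asarray(x, dtype=float) - ref)
    if kind == "step":
        breaks = np.asarray(spec["breaks"], dtype=float)
        values = np.asarray(spec["values"], dtype=float)
        if len(values) != len(breaks) + 1:
            raise ValueError("step effect needs len(values) == len(breaks) + 1")
        return lambda x: values[
            np.searchsorted(breaks, np.asarray(x, dtype=float), side="right")
        ]
    if kind == "pwlinear":
        knots = np.asarray(spec["knots"], dtype=float)
        values = np.asarray(spec["values"], dtype=float)
        return lambda x: np.interp(np.asarray(x, dtype=float), knots, values)
    raise ValueError(f"unknown effect kind {kind!r}")


@dataclass(frozen=True)
class EffectSpec:
    """Declarative TMB-effect description (see :func:`_make_effect`)."""

    spec: Mapping | Callable

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return _make_effect(self.spec)(x)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated study condition.

    Units: months for times, mut/Mb for TMB; ``beta0`` on the logit
    scale, ``effect_T`` on the log-hazard scale relative to the
    exponential/Weibull baseline.
    """

    n: int = 150
    tmb_median: float = 8.0
    tmb_sigma: float = 0.6
    beta0: float = -0.85
    effect_R: Mapping | Callable = field(default_factory=lambda: {"kind": "constant", "value": 0.0})
    effect_T: Mapping | Callable = field(default_factory=lambda: {"kind": "constant", "value": 0.0})
    re_structure: str = "shared"  # "shared" or "bivariate"
    sigma_u: float = 1.0
    gamma: float = -0.8
    sigma_v: float = 0.0
    rho: float = 0.0
    baseline_dist: str = "exponential"
    baseline_rate: float = 0.115  # per month; median survival ~6 months
    baseline_shape: float = 1.0
    censor_rate: float = 0.04
    admin_censor: float = 36.0
    sigma_e: float = 0.0
    scenario: str = "custom"
    true_cuts: tuple[float, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_u < 0 or self.sigma_v < 0 or self.sigma_e < 0:
            raise ValueError("standard deviations must be >= 0")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "true_cuts" in d:
            d["true_cuts"] = tuple(float(c) for c in d["true_cuts"])
        return cls(**d)


def _draw_effects(config: SimulationConfig, n: int, rng: np.random.Generator):
    if config.re_structure == "shared":
        u = rng.normal(0.0, config.sigma_u, n)
        return u, config.gamma * u
    cov = np.array(
        [
            [config.sigma_u**2, config.rho * config.sigma_u * config.sigma_v],
            [config.rho * config.sigma_u * config.sigma_v, config.sigma_v**2],
        ]
    )
    uv = rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
    return uv[:, 0], uv[:, 1]


def _draw_once(config: SimulationConfig, rng: np.random.Generator):
    n = config.n
    fR = _make_effect(config.effect_R)
    fT = _make_effect(config.effect_T)
    x_true = rng.lognormal(np.log(config.tmb_median), config.tmb_sigma, n)
    u, v = _draw_effects(config, n, rng)
    eta = config.beta0 + fR(x_true) + u
    R = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
    lp = fT(x_true) + v
    E = rng.exponential(1.0, n)
    scale = config.baseline_rate * np.exp(lp)
    if config.baseline_dist == "exponential":
        T_star = E / scale
    elif config.baseline_dist == "weibull":
        T_star = (E / scale) ** (1.0 / config.baseline_shape)
    else:
        raise ValueError(f"unknown baseline_dist {config.baseline_dist!r}")
    if config.censor_rate > 0:
        C = np.minimum(rng.exponential(1.0 / config.censor_rate, n), config.admin_censor)
    else:
        C = np.full(n, config.admin_censor)
    T = np.minimum(T_star, C)
    delta = (T_star <= C).astype(int)
    T = np.maximum(T, 1e-8)
    tmb_obs = np.maximum(x_true + rng.normal(0.0, config.sigma_e, n), 0.0) \
        if config.sigma_e > 0 else x_true.copy()
    return x_true, u, v, R, T_star, C, T, delta, tmb_obs


def simulate_cohort(
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
    strict: bool = False,
    max_retries: int = 100,
) -> tuple[Cohort, pd.DataFrame]:
    """Draw one cohort; returns ``(Cohort, latent-truth table)``.

    The latent table records ``tmb_true, u, v, T_star, C`` alongside the
    observed columns, for oracle checks.  Fully reproducible from the
    seed (``seed`` argument overrides ``config.seed``).  Degenerate
    draws (single response class or zero events) are redrawn with a
    warning, or rejected when ``strict=True``.
    """
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    for attempt in range(max_retries):
        x_true, u, v, R, T_star, C, T, delta, tmb_obs = _draw_once(config, rng)
        degenerate = R.min() == R.max() or delta.sum() == 0
        if not degenerate:
            break
        if strict:
            raise ValueError(
                "degenerate cohort (single response class or all censored); "
                "adjust the configuration"
            )
        if attempt == 0:
            warnings.warn(
                "degenerate cohort draw (single response class or all "
                "censored); regenerating",
                stacklevel=2,
            )
    else:
        raise ValueError("could not draw a non-degenerate cohort")

    ids = [f"S{i + 1:05d}" for i in range(config.n)]
    cohort = Cohort.from_arrays(ids, R, T, delta, tmb_obs)
    latent = pd.DataFrame(
        {
            "id": ids,
            "tmb_true": x_true,
            "tmb_obs": tmb_obs,
            "u": u,
            "v": v,
            "R": R,
            "T_star": T_star,
            "C": C,
            "T": T,
            "delta": delta,
        }
    )
    return cohort, latent


def true_joint_probabilities(
    config: SimulationConfig, latent: pd.DataFrame, T0: float
) -> pd.DataFrame:
    """Latent-truth joint probabilities ``Pr(R=1, T*>T0)`` per patient.

    Computed from the generative parameters and the latent draws
    ``(tmb_true, u, v)`` — the oracle counterpart of the model-estimated
    probabilities, used for calibration studies of the discrepancy
    tests.  Under a null scenario these are independent of TMB.
    """
    fR = _make_effect(config.effect_R)
    fT = _make_effect(config.effect_T)
    x = latent["tmb_true"].to_numpy(dtype=float)
    u = latent["u"].to_numpy(dtype=float)
    v = latent["v"].to_numpy(dtype=float)
    p_R = 1.0 / (1.0 + np.exp(-(config.beta0 + fR(x) + u)))
    scale = config.baseline_rate * np.exp(fT(x) + v)
    if config.baseline_dist == "exponential":
        H = scale * T0
    else:
        H = scale * T0**config.baseline_shape
    p_T = np.exp(-H)
    return pd.DataFrame(
        {"id": latent["id"], "p": p_R * p_T, "p_R": p_R, "p_T": p_T}
    )


def scenario_presets(name: str) -> SimulationConfig:
    """Load a named scenario preset from the packaged YAML files."""
    if name not in _PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {_PRESET_NAMES}")
    ref = importlib.resources.files("tmbcat").joinpath(f"presets/{name}.yaml")
    with ref.open() as fh:
        d = yaml.safe_load(fh)
    return SimulationConfig.from_dict(d)
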