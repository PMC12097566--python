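"""The ten fixed-effect structures for cycle magnitude, as pure functions.

Cycle magnitudes y (degrees, > 0) are modelled with a Gamma likelihood and a
log link,

    y_i ~ Gamma(k, mu_i / k),        E[y_i] = mu_i,  Var[y_i] = mu_i^2 / k
    log mu_i = fixed(position_i, length_i) + alpha_n[nod_i] + alpha_p[part_i]

with nod- and participant-level random intercepts alpha_n ~ N(0, sigma_n),
alpha_p ~ N(0, sigma_p).  The fixed part combines up to three terms:

    fixed = a-term + b-term * g(position) + c-term * final

where ``a`` is the (log) magnitude of first cycles, ``b`` the per-position
declination slope with g(position) = position - 1 (linear models 1-8) or
position^2 - 1 (quadratic models 9-10), and ``c`` the extra final-cycle
lowering (``final`` = 1 iff position == length).  For single nods
(length == 1) only the a-term applies.  Each of a, b, c is either constant
across lengths or re-parameterized as a power law of length,

    a_length = alpha_a + beta_a * (length - 1)^gamma_a        (base 1)
    b_length = alpha_b + beta_b * (length - 2)^gamma_b        (base 2)
    c_length = alpha_c + beta_c * (length - 2)^gamma_c        (base 2)

with gamma >= 0 so that beta keeps its direction; alpha is the value at the
smallest admissible length and (0)^gamma is taken as 0 for every gamma >= 0
so that property holds exactly.  The ten members of the family are every
combination of constant/varying a, b, c (models 1-8, linear g) plus the two
quadratic variants of model 5 and 6's structures (models 9-10).

Priors: Normal(0, 10) on a, b, c, alpha, beta; half-Normal(0, 10) on the
gamma exponents (the zero-truncation of the same normal); half-Cauchy(0, 5)
on the Gamma shape k and the random-effect standard deviations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ModelSpec",
    "FixedParams",
    "RandomEffects",
    "reparam_power",
    "fixed_effect",
    "linear_predictor",
    "gamma_loglik",
    "log_prior",
    "model_catalog",
    "PARAM_ORDER",
]

#: Canonical parameter naming/order (Table-style row order).
PARAM_ORDER = [
    "a", "alpha_a", "beta_a", "gamma_a",
    "b", "alpha_b", "beta_b", "gamma_b",
    "c", "alpha_c", "beta_c", "gamma_c",
    "sigma_n", "sigma_p", "k",
]

#: Hard clip on the log-scale linear predictor to keep exp() finite.
LOG_MU_CLIP = 30.0


@dataclass(frozen=True)
class ModelSpec:
    """Which of a/b/c vary with length and whether g(position) is quadratic."""

    model_id: int
    a_varying: bool
    b_varying: bool
    c_varying: bool
    position_term: str = "linear"  # "linear" | "quadratic"

    def __post_init__(self) -> None:
        if self.position_term not in ("linear", "quadratic"):
            raise ValueError(f"bad position_term {self.position_term!r}")

    @property
    def n_fixed_params(self) -> int:
        """Number of fixed-effect scalars (the Occam count for selection)."""
        return sum(3 if v else 1 for v in
                   (self.a_varying, self.b_varying, self.c_varying))

    @property
    def param_names(self) -> list[str]:
        """Fixed-effect parameter names in canonical order."""
        names = []
        for letter, varying in (("a", self.a_varying), ("b", self.b_varying),
                                ("c", self.c_varying)):
            if varying:
                names += [f"alpha_{letter}", f"beta_{letter}", f"gamma_{letter}"]
            else:
                names.append(letter)
        return names

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class FixedParams:
    """Fixed-effect scalars; exactly one of the plain/greek triple per letter."""

    a: float | None = None
    alpha_a: float | None = None
    beta_a: float | None = None
    gamma_a: float | None = None
    b: float | None = None
    alpha_b: float | None = None
    beta_b: float | None = None
    gamma_b: float | None = None
    c: float | None = None
    alpha_c: float | None = None
    beta_c: float | None = None
    gamma_c: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {k: v for k, v in asdict(self).items() if v is not None}

    def to_json(self) -> str:
        return json.dumps(self.as_dict())

    @classmethod
    def from_json(cls, s: str) -> "FixedParams":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class RandomEffects:
    """Per-nod and per-participant log-scale offsets and their scales."""

    alpha_n: np.ndarray
    alpha_p: np.ndarray
    sigma_n: float
    sigma_p: float

    def __post_init__(self) -> None:
        if self.sigma_n <= 0 or self.sigma_p <= 0:
            raise ValueError("random-effect standard deviations must be > 0")


def reparam_power(alpha: float, beta: float, gamma: float,
                  x: np.ndarray | float, base: int) -> np.ndarray | float:
    """Power-law re-parameterization ``alpha + beta * (x - base)**gamma``.

    ``alpha`` is exactly the value at ``x == base`` for every ``gamma >= 0``
    because (0)**gamma is defined as 0 (including gamma == 0).
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    x = np.asarray(x, dtype=float)
    if np.any(x < base):
        raise ValueError(f"length {x} below base {base}")
    d = x - base
    out = alpha + beta * np.where(d > 0, np.power(np.maximum(d, 1e-300), gamma), 0.0)
    return out if out.ndim else float(out)


def _term(letter: str, varying: bool, p: dict[str, float],
          length: np.ndarray, base: int) -> np.ndarray:
    if varying:
        return np.asarray(reparam_power(
            p[f"alpha_{letter}"], p[f"beta_{letter}"], p[f"gamma_{letter}"],
            np.maximum(length, base), base))
    return np.full_like(np.asarray(length, dtype=float), p[letter])


def fixed_effect(spec: ModelSpec, params: FixedParams | dict,
                 position: np.ndarray | int, length: np.ndarray | int,
                 is_final: np.ndarray | bool) -> np.ndarray | float:
    """Evaluate the fixed part of log(mu) for one model, vectorized.

    For length-1 rows only the a-term applies; otherwise
    a-term + b-term * g(position) + c-term * final with g per the spec.
    """
    p = params.as_dict() if isinstance(params, FixedParams) else dict(params)
    scalar = (np.ndim(position) == 0 and np.ndim(length) == 0
              and np.ndim(is_final) == 0)
    position = np.atleast_1d(np.asarray(position, dtype=float))
    length = np.atleast_1d(np.asarray(length, dtype=float))
    final = np.atleast_1d(np.asarray(is_final, dtype=float))
    position, length, final = np.broadcast_arrays(position, length, final)

    a_term = _term("a", spec.a_varying, p, length, base=1)
    if spec.position_term == "quadratic":
        g = position**2 - 1.0
    else:
        g = position - 1.0
    b_term = _term("b", spec.b_varying, p, length, base=2)
    c_term = _term("c", spec.c_varying, p, length, base=2)

    out = np.where(length <= 1, a_term, a_term + b_term * g + c_term * final)
    return float(out[0]) if scalar else out


def linear_predictor(fixed: np.ndarray | float, alpha_n: np.ndarray | float,
                     alpha_p: np.ndarray | float) -> np.ndarray | float:
    """mu = exp(fixed + alpha_n + alpha_p), clipped on the log scale."""
    eta = np.clip(np.asarray(fixed, dtype=float) + alpha_n + alpha_p,
                  -LOG_MU_CLIP, LOG_MU_CLIP)
    out = np.exp(eta)
    return out if np.ndim(out) else float(out)


def gamma_loglik(y: np.ndarray | float, k: float,
                 mu: np.ndarray | float) -> np.ndarray | float:
    """Log density of Gamma(shape k, scale mu/k) at y; mean mu, variance mu^2/k."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if k <= 0 or np.any(y <= 0) or np.any(mu <= 0):
        raise ValueError("y, k and mu must all be positive")
    out = (k * np.log(k) - gammaln(k) - k * np.log(mu)
           + (k - 1.0) * np.log(y) - k * y / mu)
    return out if out.ndim else float(out)


_NORMAL_SD = 10.0
_CAUCHY_SCALE = 5.0
_LOG_NORM_CONST = -0.5 * np.log(2 * np.pi) - np.log(_NORMAL_SD)


def _normal_lp(x: float) -> float:
    return _LOG_NORM_CONST - 0.5 * (x / _NORMAL_SD) ** 2


def _half_normal_lp(x: float) -> float:
    if x < 0:
        return -np.inf
    return np.log(2.0) + _normal_lp(x)


def _half_cauchy_lp(x: float) -> float:
    if x <= 0:
        return -np.inf
    return (np.log(2.0) - np.log(np.pi) - np.log(_CAUCHY_SCALE)
            - np.log1p((x / _CAUCHY_SCALE) ** 2))


def log_prior(params: FixedParams | dict, k: float,
              sigma_n: float, sigma_p: float) -> float:
    """Joint log prior of the fixed-effect scalars and the scale parameters.

    Normal(0, 10) on a/b/c/alpha/beta; half-Normal(0, 10) on the gamma
    exponents (truncation of the same normal to [0, inf)); half-Cauchy(0, 5)
    on k, sigma_n and sigma_p.  Out-of-support values give -inf.
    """
    p = params.as_dict() if isinstance(params, FixedParams) else dict(params)
    total = 0.0
    for name, value in p.items():
        if name.startswith("gamma_"):
            total += _half_normal_lp(value)
        else:
            total += _normal_lp(value)
    total += _half_cauchy_lp(k)
    total += _half_cauchy_lp(sigma_n)
    total += _half_cauchy_lp(sigma_p)
    return float(total)


_CATALOG = [
    # (model_id, a_varying, b_varying, c_varying, position_term)
    (1, False, False, False, "linear"),
    (2, False, True, False, "linear"),
    (3, False, False, True, "linear"),
    (4, False, True, True, "linear"),
    (5, True, False, False, "linear"),
    (6, True, True, False, "linear"),
    (7, True, False, True, "linear"),
    (8, True, True, True, "linear"),
    (9, True, False, False, "quadratic"),
    (10, True, True, False, "quadratic"),
]


def model_catalog() -> list[ModelSpec]:
    """The ten candidate fixed-effect structures."""
    return [ModelSpec(*row) for row in _CATALOG]


def get_model(model_id: int) -> ModelSpec:
    for row in _CATALOG:
        if row[0] == model_id:
            return ModelSpec(*row)
    raise ValueError(f"unknown model_id {model_id}")
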