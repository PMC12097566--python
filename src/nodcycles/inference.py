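"""MCMC fitting of the Gamma mixed-effects magnitude models.

The sampler is a Gibbs sweep of univariate slice-sampling updates:

* each fixed-effect scalar and the Gamma shape ``k`` from its full
  conditional (``k`` and the random-effect scales on the log scale, the
  power-law exponents ``gamma_*`` bounded below at 0);
* all nod intercepts ``alpha_n`` in one vectorized pass (they are
  conditionally independent given the globals), likewise the participant
  intercepts ``alpha_p``;
* the random-effect scales from their conditionals given the intercepts;
* a conjugate Gaussian "translation" move that shifts the model intercept
  and all intercepts of one grouping in opposite directions.  The likelihood
  is invariant along that line, so the move is sampled exactly from the
  priors' 1-D Gaussian conditional; it decorrelates the intercept from the
  random-effect means, which plain coordinate-wise Gibbs mixes slowly.

Draw bookkeeping mirrors the convention of thinning-era samplers: with
``iterations`` total sweeps, a ``warmup`` burn-in and a ``thin`` stride, the
retained draws per chain are ``(iterations - warmup) // thin`` (the defaults
give 1000 per chain and 8000 in total across 8 chains).
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._slicesampler import slice_sample_many, slice_sample_scalar
from .model_family import (
    LOG_MU_CLIP,
    ModelSpec,
    PARAM_ORDER,
    _half_cauchy_lp,
    _half_normal_lp,
    _normal_lp,
)

__all__ = [
    "MCMCConfig",
    "PosteriorResult",
    "fit_mcmc",
    "check_convergence",
    "summarize_posterior",
    "ConvergenceError",
]

#: Models that need the longer paper-profile runs for convergence.
_LONG_RUN_MODELS = {3, 8, 9, 10}


class ConvergenceError(RuntimeError):
    """Raised when a fit fails the Rhat < 1.05 criterion and abort is requested."""


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; defaults follow the study's reported configuration."""

    chains: int = 8
    warmup: int = 1000
    iterations: int = 4000
    thin: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= self.warmup:
            raise ValueError("iterations must exceed warmup")
        if self.thin < 1 or self.chains < 1:
            raise ValueError("thin and chains must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.warmup) // self.thin

    @property
    def total_retained(self) -> int:
        return self.retained_per_chain * self.chains

    @classmethod
    def paper(cls, model_id: int = 5, seed: int = 0) -> "MCMCConfig":
        """The published settings: 8 chains, 1000 burn-in, 4000 iterations /
        thin 3 (5000 / 4 for models 3, 8, 9 and 10)."""
        if model_id in _LONG_RUN_MODELS:
            return cls(chains=8, warmup=1000, iterations=5000, thin=4, seed=seed)
        return cls(chains=8, warmup=1000, iterations=4000, thin=3, seed=seed)

    @classmethod
    def fast(cls, seed: int = 0) -> "MCMCConfig":
        """Desk-scale profile: 4 chains, 1000 warmup + 1000 retained, thin 1."""
        return cls(chains=4, warmup=1000, iterations=2000, thin=1, seed=seed)


@dataclass
class PosteriorResult:
    """Posterior draws and per-observation log-likelihood for one model fit."""

    spec: ModelSpec
    config: MCMCConfig
    param_names: list[str]
    draws: dict[str, np.ndarray]  # name -> (chains, draws)
    loglik: np.ndarray  # (chains, draws, n_obs), float32
    alpha_n: np.ndarray  # (chains, draws, n_nods), float32
    alpha_p: np.ndarray  # (chains, draws, n_participants), float32
    nod_levels: np.ndarray
    participant_levels: np.ndarray

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def median(self, name: str) -> float:
        return float(np.median(self.stacked(name)))

    @property
    def medians(self) -> dict[str, float]:
        return {name: self.median(name) for name in self.param_names}

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        lo, hi = np.quantile(self.stacked(name),
                             [(1 - level) / 2, (1 + level) / 2])
        return float(lo), float(hi)

    def to_arviz(self) -> az.InferenceData:
        posterior = {name: self.draws[name] for name in self.param_names}
        return az.from_dict(
            posterior=posterior,
            log_likelihood={"y": self.loglik.astype(np.float64)},
        )

    def rhat(self) -> dict[str, float]:
        if self.config.chains < 2:
            raise ValueError("Rhat requires at least 2 chains")
        ds = az.rhat(az.from_dict(posterior={n: self.draws[n]
                                             for n in self.param_names}))
        return {n: float(ds[n].values) for n in self.param_names}

    def ess_bulk(self) -> dict[str, float]:
        ds = az.ess(az.from_dict(posterior={n: self.draws[n]
                                            for n in self.param_names}),
                    method="bulk")
        return {n: float(ds[n].values) for n in self.param_names}

    def export_draws_csv(self, path) -> None:
        pd.DataFrame({n: self.stacked(n) for n in self.param_names}).to_csv(
            path, index=False)


# ---------------------------------------------------------------------------
# model-specific design bundle
# ---------------------------------------------------------------------------


class _Design:
    """Preprocessed arrays and conditional log-densities for one fit."""

    def __init__(self, spec: ModelSpec, table: pd.DataFrame):
        if len(table) == 0:
            raise ValueError("empty cycle table")
        y = table["magnitude_deg"].to_numpy(float)
        if np.any(~np.isfinite(y)) or np.any(y <= 0):
            raise ValueError("magnitudes must be positive and finite")
        length = table["length"].to_numpy(int)
        if length.min() < 1 or length.max() > 5:
            raise ValueError("lengths must lie in 1..5")
        position = table["position"].to_numpy(int)
        final = table["is_final"].to_numpy(bool).astype(float)

        self.spec = spec
        self.y = y
        self.log_y = np.log(y)
        self.n = len(y)
        multi = (length > 1).astype(float)
        g = (position.astype(float) ** 2 - 1.0
             if spec.position_term == "quadratic"
             else position.astype(float) - 1.0)
        self.g_eff = g * multi          # b-term regressor, zeroed for singles
        self.f_eff = final * multi      # c-term regressor, zeroed for singles
        self.d_a = np.maximum(length - 1, 0).astype(float)
        self.d_bc = np.maximum(length - 2, 0).astype(float)

        def _geomean_positive(d: np.ndarray) -> float | None:
            pos = d[d > 0]
            return float(np.exp(np.mean(np.log(pos)))) if len(pos) else None

        # pivot points for the ridge move (see _run_chain step 1c)
        self.d_ref_a = _geomean_positive(self.d_a)
        self.d_ref_bc = _geomean_positive(self.d_bc)

        nods, self.nod_idx = np.unique(table["nod_id"].to_numpy(), return_inverse=True)
        parts, self.part_idx = np.unique(table["participant_id"].to_numpy(),
                                         return_inverse=True)
        self.nod_levels = nods
        self.part_levels = parts
        self.n_nods = len(nods)
        self.n_parts = len(parts)

    def _letter_term(self, letter: str, varying: bool, p: dict,
                     d: np.ndarray) -> np.ndarray | float:
        if varying:
            gamma = p[f"gamma_{letter}"]
            powed = np.where(d > 0, np.power(np.maximum(d, 1e-300), gamma), 0.0)
            return p[f"alpha_{letter}"] + p[f"beta_{letter}"] * powed
        return p[letter]

    def fixed(self, p: dict) -> np.ndarray:
        """Fixed part of log(mu) for all observations."""
        a = self._letter_term("a", self.spec.a_varying, p, self.d_a)
        b = self._letter_term("b", self.spec.b_varying, p, self.d_bc)
        c = self._letter_term("c", self.spec.c_varying, p, self.d_bc)
        return np.broadcast_to(a, (self.n,)) + b * self.g_eff + c * self.f_eff

    def eta(self, p: dict, alpha_n: np.ndarray, alpha_p: np.ndarray) -> np.ndarray:
        return np.clip(self.fixed(p) + alpha_n[self.nod_idx]
                       + alpha_p[self.part_idx], -LOG_MU_CLIP, LOG_MU_CLIP)

    def loglik_obs(self, k: float, eta: np.ndarray) -> np.ndarray:
        """Full per-observation Gamma log density at the current state."""
        return (k * np.log(k) - gammaln(k) - k * eta
                + (k - 1.0) * self.log_y - k * self.y * np.exp(-eta))

    def loglik_sum_eta_terms(self, k: float, eta: np.ndarray) -> float:
        """Data terms that depend on eta (up to constants in eta-updates)."""
        return float(-k * eta.sum() - k * np.dot(self.y, np.exp(-eta)))


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


def _prior_lp(name: str, value: float) -> float:
    if name.startswith("gamma_"):
        return _half_normal_lp(value)
    return _normal_lp(value)


def _run_chain(design: _Design, config: MCMCConfig, chain: int,
               prior_only: bool) -> dict:
    spec = design.spec
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed % (2**31), spawn_key=(chain,)))
    fixed_names = spec.param_names

    # --- overdispersed initial state -------------------------------------
    p: dict[str, float] = {}
    for name in fixed_names:
        if name.startswith("gamma_"):
            p[name] = abs(0.5 + 0.3 * rng.standard_normal())
        elif name in ("a", "alpha_a"):
            p[name] = float(np.log(design.y.mean())) + 0.3 * rng.standard_normal()
        else:
            p[name] = 0.2 * rng.standard_normal()
    k = float(1.5 * np.exp(0.3 * rng.standard_normal()))
    sigma_n = float(0.5 * np.exp(0.3 * rng.standard_normal()))
    sigma_p = float(0.3 * np.exp(0.3 * rng.standard_normal()))
    alpha_n = 0.1 * rng.standard_normal(design.n_nods)
    alpha_p = 0.1 * rng.standard_normal(design.n_parts)

    intercept = "alpha_a" if spec.a_varying else "a"
    lik_w = 0.0 if prior_only else 1.0

    n_keep = config.retained_per_chain
    kept = {name: np.empty(n_keep) for name in
            [*fixed_names, "sigma_n", "sigma_p", "k"]}
    kept_ll = np.empty((n_keep, design.n), dtype=np.float32)
    kept_an = np.empty((n_keep, design.n_nods), dtype=np.float32)
    kept_ap = np.empty((n_keep, design.n_parts), dtype=np.float32)

    re_total = alpha_n[design.nod_idx] + alpha_p[design.part_idx]

    def data_term(params: dict, kk: float) -> float:
        if prior_only:
            return 0.0
        eta = np.clip(design.fixed(params) + re_total,
                      -LOG_MU_CLIP, LOG_MU_CLIP)
        return design.loglik_sum_eta_terms(kk, eta)

    keep_slot = 0
    for it in range(config.iterations):
        # 1. fixed-effect scalars -----------------------------------------
        for name in fixed_names:
            def logf(v: float, _name=name) -> float:
                trial = {**p, _name: v}
                return data_term(trial, k) + _prior_lp(_name, v)

            lower = 0.0 if name.startswith("gamma_") else -np.inf
            width = 10.0 if prior_only else 0.5
            p[name] = slice_sample_scalar(p[name], logf, rng,
                                          width=width, lower=lower)

        # 1b. joint moves inside each power-law triple: its (alpha, beta,
        #     gamma) conditional posterior is ridge-shaped, which coordinate
        #     updates traverse slowly; slice along random directions instead.
        if not prior_only:
            for letter, varying in (("a", spec.a_varying),
                                    ("b", spec.b_varying),
                                    ("c", spec.c_varying)):
                if not varying:
                    continue
                triple = [f"alpha_{letter}", f"beta_{letter}", f"gamma_{letter}"]
                for _rep in range(2):
                    u = rng.standard_normal(3)
                    u /= np.linalg.norm(u)
                    base = np.array([p[nm] for nm in triple])

                    def logf_dir(t: float, _b=base, _u=u, _t=triple) -> float:
                        vals = _b + t * _u
                        if vals[2] < 0:  # gamma out of support
                            return -np.inf
                        trial = {**p, **dict(zip(_t, vals))}
                        return data_term(trial, k) + sum(
                            _prior_lp(nm, v) for nm, v in zip(_t, vals))

                    t_new = slice_sample_scalar(0.0, logf_dir, rng, width=0.5)
                    for nm, v in zip(triple, base + t_new * u):
                        p[nm] = float(v)

        # 1c. ridge move: the (beta, gamma) conditional concentrates on the
        #     curve beta * d^gamma ~ const over the observed length offsets
        #     d.  Reparameterize to (r, gamma) with r = beta * d_ref^gamma
        #     (d_ref the geometric-mean positive offset; Jacobian
        #     d_ref^-gamma) and slice-sample gamma with r held fixed, which
        #     pivots the power curve about d_ref instead of crawling along it.
        if not prior_only:
            for letter, varying, d_ref in (
                    ("a", spec.a_varying, design.d_ref_a),
                    ("b", spec.b_varying, design.d_ref_bc),
                    ("c", spec.c_varying, design.d_ref_bc)):
                if not varying or d_ref is None or d_ref == 1.0:
                    continue
                beta_nm, gamma_nm = f"beta_{letter}", f"gamma_{letter}"
                r = p[beta_nm] * d_ref ** p[gamma_nm]
                log_dref = np.log(d_ref)

                def logf_ridge(g: float, _r=r, _bn=beta_nm, _gn=gamma_nm) -> float:
                    beta = _r * d_ref ** (-g)
                    trial = {**p, _bn: beta, _gn: g}
                    return (data_term(trial, k) + _prior_lp(_bn, beta)
                            + _prior_lp(_gn, g) - g * log_dref)

                g_new = slice_sample_scalar(p[gamma_nm], logf_ridge, rng,
                                            width=0.5, lower=0.0)
                p[gamma_nm] = g_new
                p[beta_nm] = r * d_ref ** (-g_new)

        fixed_now = design.fixed(p)
        eta_now = np.clip(fixed_now + re_total, -LOG_MU_CLIP, LOG_MU_CLIP)

        # 2. Gamma shape k (log scale) ------------------------------------
        if prior_only:
            def logf_k(z: float) -> float:
                return _half_cauchy_lp(np.exp(z)) + z
        else:
            s_eta = float(eta_now.sum())
            s_ye = float(np.dot(design.y, np.exp(-eta_now)))
            s_logy = float(design.log_y.sum())
            n = design.n

            def logf_k(z: float) -> float:
                kk = np.exp(z)
                ll = (n * (kk * z - gammaln(kk)) - kk * s_eta
                      + (kk - 1.0) * s_logy - kk * s_ye)
                return ll + _half_cauchy_lp(kk) + z

        k = float(np.exp(slice_sample_scalar(np.log(k), logf_k, rng, width=0.3)))

        # 3. nod intercepts (vectorized) ----------------------------------
        if prior_only:
            # ancestral draws: with hundreds of groups the sigma | alpha
            # conditional is nearly degenerate, so Gibbs would barely move
            sigma_n = 5.0 * abs(rng.standard_cauchy())
            alpha_n = sigma_n * rng.standard_normal(design.n_nods)
        else:
            base_n = fixed_now + alpha_p[design.part_idx]

            def logf_an(x: np.ndarray) -> np.ndarray:
                eta = np.clip(base_n + x[design.nod_idx],
                              -LOG_MU_CLIP, LOG_MU_CLIP)
                per_obs = -k * eta - k * design.y * np.exp(-eta)
                grouped = np.bincount(design.nod_idx, weights=per_obs,
                                      minlength=design.n_nods)
                return grouped - 0.5 * (x / sigma_n) ** 2

            alpha_n = slice_sample_many(alpha_n, logf_an, rng, width=1.0)

        # 4. sigma_n ------------------------------------------------------
        if not prior_only:
            ssq_n = float(np.dot(alpha_n, alpha_n))
            sigma_n = _update_sigma(sigma_n, ssq_n, design.n_nods, rng)

        # 5. participant intercepts ---------------------------------------
        if prior_only:
            sigma_p = 5.0 * abs(rng.standard_cauchy())
            alpha_p = sigma_p * rng.standard_normal(design.n_parts)
        else:
            base_p = fixed_now + alpha_n[design.nod_idx]

            def logf_ap(x: np.ndarray) -> np.ndarray:
                eta = np.clip(base_p + x[design.part_idx],
                              -LOG_MU_CLIP, LOG_MU_CLIP)
                per_obs = -k * eta - k * design.y * np.exp(-eta)
                grouped = np.bincount(design.part_idx, weights=per_obs,
                                      minlength=design.n_parts)
                return grouped - 0.5 * (x / sigma_p) ** 2

            alpha_p = slice_sample_many(alpha_p, logf_ap, rng, width=1.0)

        # 6. sigma_p ------------------------------------------------------
        if not prior_only:
            ssq_p = float(np.dot(alpha_p, alpha_p))
            sigma_p = _update_sigma(sigma_p, ssq_p, design.n_parts, rng)

        # 7. translation moves: likelihood-invariant shift between the
        #    intercept and each random-effect block (exact Gaussian step).
        if not prior_only:
            for vec, sigma in ((alpha_n, sigma_n), (alpha_p, sigma_p)):
                prec = len(vec) / sigma**2 + 1.0 / 100.0
                mean = (vec.sum() / sigma**2 - p[intercept] / 100.0) / prec
                delta = mean + rng.standard_normal() / np.sqrt(prec)
                vec -= delta
                p[intercept] += delta
        re_total = alpha_n[design.nod_idx] + alpha_p[design.part_idx]

        # 8. retain -------------------------------------------------------
        if it >= config.warmup and (it - config.warmup) % config.thin == 0:
            if keep_slot < n_keep:
                for name in fixed_names:
                    kept[name][keep_slot] = p[name]
                kept["sigma_n"][keep_slot] = sigma_n
                kept["sigma_p"][keep_slot] = sigma_p
                kept["k"][keep_slot] = k
                eta = np.clip(design.fixed(p) + re_total,
                              -LOG_MU_CLIP, LOG_MU_CLIP)
                kept_ll[keep_slot] = design.loglik_obs(k, eta)
                kept_an[keep_slot] = alpha_n
                kept_ap[keep_slot] = alpha_p
                keep_slot += 1

    return {"params": kept, "loglik": kept_ll,
            "alpha_n": kept_an, "alpha_p": kept_ap}


def _update_sigma(sigma: float, ssq: float, m: int,
                  rng: np.random.Generator) -> float:
    """Slice update of a random-effect scale from its conditional (log scale)."""

    def logf(z: float) -> float:
        s = np.exp(z)
        return (-m * z - 0.5 * ssq / s**2) + _half_cauchy_lp(s) + z

    return float(np.exp(slice_sample_scalar(np.log(sigma), logf, rng, width=0.3)))


def fit_mcmc(spec: ModelSpec, table: pd.DataFrame, config: MCMCConfig,
             prior_only: bool = False) -> PosteriorResult:
    """Fit one fixed-effect structure to a cycle table by MCMC.

    Returns posterior draws for the global parameters, the per-draw random
    intercepts and the (draws x observations) log-likelihood matrix needed
    for LOO.  Runs are bit-for-bit reproducible for a given seed.
    """
    design = _Design(spec, table)
    chains = [
        _run_chain(design, config, chain, prior_only)
        for chain in range(config.chains)
    ]
    names = [*spec.param_names, "sigma_n", "sigma_p", "k"]
    draws = {
        name: np.stack([c["params"][name] for c in chains]) for name in names
    }
    return PosteriorResult(
        spec=spec,
        config=config,
        param_names=names,
        draws=draws,
        loglik=np.stack([c["loglik"] for c in chains]),
        alpha_n=np.stack([c["alpha_n"] for c in chains]),
        alpha_p=np.stack([c["alpha_p"] for c in chains]),
        nod_levels=design.nod_levels,
        participant_levels=design.part_levels,
    )


def check_convergence(result: PosteriorResult, threshold: float = 1.05,
                      abort: bool = False) -> tuple[bool, dict[str, float]]:
    """Check the all-Rhat-below-1.05 criterion; list offending parameters.

    With ``abort=True`` a failed check raises :class:`ConvergenceError` so a
    pipeline can refuse to use the fit downstream.
    """
    rhats = result.rhat()
    offending = {n: r for n, r in rhats.items()
                 if not np.isfinite(r) or r >= threshold}
    passed = len(offending) == 0
    if abort and not passed:
        raise ConvergenceError(f"Rhat >= {threshold} for: {sorted(offending)}")
    return passed, offending


def summarize_posterior(result: PosteriorResult,
                        level: float = 0.95) -> pd.DataFrame:
    """Posterior summary table: median, central CI, Rhat, bulk ESS, significance.

    A parameter is flagged significant when its central credible interval
    excludes zero.  Rows follow the canonical parameter ordering.
    """
    rhats = result.rhat() if result.config.chains >= 2 else {}
    ess = result.ess_bulk()
    rows = []
    order = {n: i for i, n in enumerate(PARAM_ORDER)}
    for name in sorted(result.param_names, key=lambda n: order.get(n, 99)):
        lo, hi = result.credible_interval(name, level)
        rows.append({
            "parameter": name,
            "median": result.median(name),
            "ci_low": lo,
            "ci_high": hi,
            "significant": bool(lo > 0 or hi < 0),
            "rhat": rhats.get(name, np.nan),
            "ess_bulk": ess.get(name, np.nan),
        })
    return pd.DataFrame(rows)
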