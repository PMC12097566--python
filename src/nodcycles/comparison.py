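"""PSIS-LOO model comparison and the significance + Occam selection rule.

Models are ranked by expected log pointwise predictive density (elpd)
estimated with Pareto-smoothed importance-sampling leave-one-out
cross-validation.  For every model the difference from the best model
(``elpd_diff``) and its standard error (``se_diff``, computed from the
pointwise elpd differences as ``sd * sqrt(n)``) are reported.  A model is not
significantly worse than the best when ``elpd_diff +/- 1.96 * se_diff``
straddles zero; among the best model and all models not significantly worse,
the one with the fewest fixed-effect scalars is selected (ties going to the
lower model id).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .inference import PosteriorResult
from .model_family import gamma_loglik

__all__ = [
    "LooResult",
    "LooComparison",
    "pointwise_loglik",
    "loo_elpd",
    "compare_models",
]

Z_95 = 1.96
PARETO_K_WARN = 0.7


@dataclass(frozen=True)
class LooResult:
    """PSIS-LOO estimate for one model on one data set."""

    elpd_loo: float
    se: float
    pointwise: np.ndarray  # per-observation elpd contributions
    pareto_k: np.ndarray

    @property
    def n_obs(self) -> int:
        return len(self.pointwise)

    @property
    def n_high_pareto_k(self) -> int:
        return int(np.sum(self.pareto_k > PARETO_K_WARN))


@dataclass(frozen=True)
class LooComparison:
    """Per-model comparison table plus the selected model."""

    table: pd.DataFrame  # model_id, elpd_loo, elpd_diff, se_diff, significant, n_params, selected
    best_model_id: int
    selected_model_id: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def pointwise_loglik(result: PosteriorResult, table: pd.DataFrame) -> np.ndarray:
    """Recompute the (draws x observations) log-likelihood from stored draws.

    Entry (s, i) is the Gamma log density of observation i at draw s,
    including that draw's nod and participant intercepts.  ``fit_mcmc``
    stores the same matrix; this recomputation exists as an independent
    route for cross-checking and for evaluating a fit on a permuted or
    duplicated table.
    """
    y = table["magnitude_deg"].to_numpy(float)
    n = len(y)
    nod_map = {v: i for i, v in enumerate(result.nod_levels)}
    part_map = {v: i for i, v in enumerate(result.participant_levels)}
    try:
        nod_idx = np.array([nod_map[v] for v in table["nod_id"]])
        part_idx = np.array([part_map[v] for v in table["participant_id"]])
    except KeyError as e:  # pragma: no cover - defensive
        raise ValueError(f"table row references unknown group level {e}") from None

    from .model_family import fixed_effect  # local import avoids cycle

    position = table["position"].to_numpy(int)
    length = table["length"].to_numpy(int)
    final = table["is_final"].to_numpy(bool)

    chains, draws = result.loglik.shape[:2]
    out = np.empty((chains * draws, n))
    s = 0
    for ch in range(chains):
        for d in range(draws):
            params = {name: result.draws[name][ch, d]
                      for name in result.spec.param_names}
            k = result.draws["k"][ch, d]
            fixed = fixed_effect(result.spec, params, position, length, final)
            eta = (np.asarray(fixed)
                   + result.alpha_n[ch, d].astype(float)[nod_idx]
                   + result.alpha_p[ch, d].astype(float)[part_idx])
            out[s] = gamma_loglik(y, float(k), np.exp(eta))
            s += 1
    return out


def loo_elpd(loglik: np.ndarray | PosteriorResult,
             min_draws_warn: int = 100) -> LooResult:
    """PSIS-LOO elpd from a log-likelihood matrix or a fitted result.

    Accepts a :class:`PosteriorResult` (uses its stored per-draw matrix and
    chain structure) or an array of shape ``(chains, draws, n_obs)`` /
    ``(draws, n_obs)``.  Observations whose Pareto-k diagnostic exceeds 0.7
    are flagged in the result.
    """
    if isinstance(loglik, PosteriorResult):
        ll = loglik.loglik.astype(np.float64)
        posterior = {n: loglik.draws[n] for n in loglik.param_names}
    else:
        ll = np.asarray(loglik, dtype=np.float64)
        if ll.ndim == 2:
            ll = ll[None, :, :]
        if ll.ndim != 3:
            raise ValueError("loglik must be (chains, draws, n_obs) or (draws, n_obs)")
        posterior = {"_dummy": ll.mean(axis=2)}
    if not np.all(np.isfinite(ll)):
        bad = np.unique(np.nonzero(~np.isfinite(ll))[2])
        raise ValueError(f"non-finite log-likelihoods for observations {bad[:10]}")
    n_draws = ll.shape[0] * ll.shape[1]
    if n_draws < min_draws_warn:
        warnings.warn(f"only {n_draws} draws for PSIS-LOO; estimates may be "
                      "unstable", stacklevel=2)
    idata = az.from_dict(posterior=posterior, log_likelihood={"y": ll})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    return LooResult(
        elpd_loo=float(res.elpd_loo),
        se=float(res.se),
        pointwise=np.asarray(res.loo_i.values, dtype=float),
        pareto_k=np.asarray(res.pareto_k.values, dtype=float),
    )


def compare_models(loo_results: dict[int, LooResult],
                   n_params: dict[int, int]) -> LooComparison:
    """Apply the elpd-difference significance rule and Occam selection.

    ``loo_results`` maps model id to its :class:`LooResult` computed on the
    *same* observations; ``n_params`` maps model id to its count of
    fixed-effect scalars.  Returns the comparison table with the best
    (highest elpd) and selected (fewest parameters among candidates not
    significantly worse than the best) model ids.
    """
    if len(loo_results) < 2:
        raise ValueError("need at least two models to compare")
    ids = sorted(loo_results)
    n_obs = {m: loo_results[m].n_obs for m in ids}
    if len(set(n_obs.values())) != 1:
        raise ValueError(f"models evaluated on different observation sets: {n_obs}")

    best = max(ids, key=lambda m: (loo_results[m].elpd_loo, -m))
    rows = []
    candidates = []
    for m in ids:
        diff_point = loo_results[m].pointwise - loo_results[best].pointwise
        elpd_diff = float(diff_point.sum())
        if m == best:
            se_diff = 0.0
            significant = False
        else:
            se_diff = float(np.std(diff_point, ddof=1) * np.sqrt(len(diff_point)))
            significant = abs(elpd_diff) > Z_95 * se_diff
        if not significant:
            candidates.append(m)
        rows.append({
            "model_id": m,
            "elpd_loo": loo_results[m].elpd_loo,
            "elpd_diff": elpd_diff,
            "se_diff": se_diff,
            "significant": significant,
            "n_params": n_params[m],
        })
    selected = min(candidates, key=lambda m: (n_params[m], m))
    table = pd.DataFrame(rows)
    table["selected"] = table["model_id"] == selected
    return LooComparison(table=table, best_model_id=best,
                         selected_model_id=selected)
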