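"""End-to-end orchestration: segment -> fit -> compare, with report tables.

``run_analysis`` composes the other modules into one reproducible run: build
(or load) a cycle table, fit the requested fixed-effect structures, compare
them by PSIS-LOO, and write report tables — the per-model posterior
summaries, the comparison table, and the per-(length, position) magnitude
profile — together with a machine-readable run log.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comparison import LooComparison, compare_models, loo_elpd
from .inference import (MCMCConfig, PosteriorResult, check_convergence,
                        fit_mcmc, summarize_posterior)
from .kinematics import (apply_exclusions, build_cycle_table, read_annotations,
                         read_openface_csv, segment_nods, write_cycle_table,
                         write_exclusion_log)
from .model_family import fixed_effect, get_model
from .synthetic import SimConfig, simulate_cycle_table

__all__ = ["RunConfig", "RunResult", "run_analysis", "magnitude_profile_table",
           "fixed_effect_profile"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end analysis run."""

    outdir: str = "nodcycles_run"
    seed: int = 0
    # data source: either paths (pose CSV + annotation TSV) or simulation
    pose_csv: str | None = None
    annotations_tsv: str | None = None
    cycle_table_csv: str | None = None  # pre-built table, skips segmentation
    n_nods: int = 3000
    n_participants: int = 36
    # segmentation
    window: int = 5
    # modelling
    model_ids: tuple[int, ...] = tuple(range(1, 11))
    profile: str = "fast"  # "paper" | "fast"

    def __post_init__(self) -> None:
        if self.profile not in ("paper", "fast"):
            raise ValueError(f"profile must be 'paper' or 'fast', got {self.profile}")
        for p in (self.pose_csv, self.annotations_tsv, self.cycle_table_csv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "model_ids" in raw:
            raw["model_ids"] = tuple(raw["model_ids"])
        return cls(**raw)


@dataclass
class RunResult:
    """In-memory bundle of a run's outputs."""

    cycle_table: pd.DataFrame
    fits: dict[int, PosteriorResult]
    summaries: dict[int, pd.DataFrame]
    comparison: LooComparison | None
    magnitude_profile: pd.DataFrame
    exclusion_log: dict | None
    run_log: dict


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the input."""


def magnitude_profile_table(cycle_table: pd.DataFrame) -> pd.DataFrame:
    """Mean cycle magnitude per (length, position), with standard errors.

    One row per (length, position) with position <= length; SE = sd/sqrt(n),
    reported as missing when n == 1.
    """
    if len(cycle_table) == 0:
        raise ValueError("empty cycle table")
    grouped = cycle_table.groupby(["length", "position"])["magnitude_deg"]
    out = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] == 1, "se"] = np.nan
    return out[["length", "position", "mean", "se", "n"]]


def fixed_effect_profile(result: PosteriorResult,
                         max_length: int = 5) -> pd.DataFrame:
    """Posterior magnitude of the fixed effect per (length, position).

    For each admissible (length, position) cell this evaluates
    exp(fixed(position, length)) over the posterior draws and reports the
    median and central 95% interval — the model-based counterpart of the
    observed magnitude profile.
    """
    spec = result.spec
    names = spec.param_names
    flat = {n: result.stacked(n) for n in names}
    rows = []
    for length in range(1, max_length + 1):
        for position in range(1, length + 1):
            vals = fixed_effect_draws(spec, flat, position, length,
                                      position == length)
            draws = np.exp(vals)
            lo, med, hi = np.quantile(draws, [0.025, 0.5, 0.975])
            rows.append({"length": length, "position": position,
                         "median": med, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def fixed_effect_draws(spec, flat_params: dict[str, np.ndarray],
                       position: int, length: int,
                       is_final: bool) -> np.ndarray:
    """Vector of fixed-effect values across posterior draws for one cell."""
    n = len(next(iter(flat_params.values())))
    out = np.empty(n)
    # vectorize over draws by evaluating the closed form directly
    p = flat_params
    if spec.a_varying:
        d = max(length - 1, 0)
        a = p["alpha_a"] + p["beta_a"] * (d ** p["gamma_a"] if d > 0 else 0.0)
    else:
        a = p["a"]
    if length <= 1:
        out[:] = a
        return out
    g = position**2 - 1 if spec.position_term == "quadratic" else position - 1
    d2 = max(length - 2, 0)
    if spec.b_varying:
        b = p["alpha_b"] + p["beta_b"] * (d2 ** p["gamma_b"] if d2 > 0 else 0.0)
    else:
        b = p["b"]
    if spec.c_varying:
        c = p["alpha_c"] + p["beta_c"] * (d2 ** p["gamma_c"] if d2 > 0 else 0.0)
    else:
        c = p["c"]
    out[:] = a + b * g + (c if is_final else 0.0)
    return out


def _build_table(cfg: RunConfig) -> tuple[pd.DataFrame, dict | None]:
    if cfg.cycle_table_csv is not None:
        return pd.read_csv(cfg.cycle_table_csv), None
    if cfg.pose_csv is not None:
        if cfg.annotations_tsv is None:
            raise StageError("segment: pose_csv given without annotations_tsv")
        trace = read_openface_csv(cfg.pose_csv)
        segments = read_annotations(cfg.annotations_tsv)
        nods = segment_nods(trace, segments, window=cfg.window)
        retained, log = apply_exclusions(nods)
        return build_cycle_table(retained), log
    sim = SimConfig(n_nods=cfg.n_nods, n_participants=cfg.n_participants,
                    seed=cfg.seed)
    table, _ = simulate_cycle_table(sim)
    return table, None


def run_analysis(cfg: RunConfig) -> RunResult:
    """Run the full analysis and write its report bundle to ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": {**asdict(cfg), "model_ids": list(cfg.model_ids)},
                 "versions": {"nodcycles": __version__,
                              "python": platform.python_version(),
                              "numpy": np.__version__},
                 "stages": {}}

    try:
        table, excl_log = _build_table(cfg)
    except StageError:
        raise
    except Exception as e:
        raise StageError(f"data: {e}") from e
    if len(table) == 0:
        raise StageError("data: produced an empty cycle table")
    write_cycle_table(table, outdir / "cycle_table.csv")
    if excl_log is not None:
        write_exclusion_log(excl_log, outdir / "exclusion_log.json")
    log["stages"]["data"] = {"n_cycles": int(len(table)),
                             "n_nods": int(table["nod_id"].nunique())}

    profile = magnitude_profile_table(table)
    profile.to_csv(outdir / "magnitude_profile.csv", index=False)

    fits: dict[int, PosteriorResult] = {}
    summaries: dict[int, pd.DataFrame] = {}
    for mid in cfg.model_ids:
        spec = get_model(mid)
        config = (MCMCConfig.paper(mid, seed=cfg.seed) if cfg.profile == "paper"
                  else MCMCConfig.fast(seed=cfg.seed))
        try:
            fit = fit_mcmc(spec, table, config)
        except Exception as e:
            raise StageError(f"fit model {mid}: {e}") from e
        passed, offending = check_convergence(fit)
        summary = summarize_posterior(fit)
        summary.to_csv(outdir / f"summary_model{mid}.csv", index=False)
        (outdir / f"summary_model{mid}.json").write_text(
            summary.to_json(orient="records"))
        fits[mid] = fit
        summaries[mid] = summary
        log["stages"][f"fit_model{mid}"] = {
            "n_draws": config.total_retained,
            "converged": bool(passed),
            "offending_rhat": sorted(offending),
        }

    comparison = None
    if len(fits) >= 2:
        try:
            loos = {mid: loo_elpd(fit) for mid, fit in fits.items()}
            comparison = compare_models(
                loos, {mid: fits[mid].spec.n_fixed_params for mid in fits})
        except Exception as e:
            raise StageError(f"compare: {e}") from e
        comparison.to_csv(outdir / "comparison.csv")
        log["stages"]["compare"] = {
            "best": comparison.best_model_id,
            "selected": comparison.selected_model_id,
        }
        profile_model = comparison.selected_model_id
    else:
        (outdir / "comparison.csv").write_text(
            "# model comparison requires at least two fitted models\n")
        profile_model = next(iter(fits), None)

    if profile_model is not None:
        fixed_effect_profile(fits[profile_model]).to_csv(
            outdir / "fixed_effect_profile.csv", index=False)

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return RunResult(cycle_table=table, fits=fits, summaries=summaries,
                     comparison=comparison, magnitude_profile=profile,
                     exclusion_log=excl_log, run_log=log)
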