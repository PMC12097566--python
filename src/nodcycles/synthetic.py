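"""Synthetic nod corpora with known ground truth.

Two layers of simulation make the whole pipeline testable without any
recorded data:

* :func:`simulate_cycle_table` draws cycle magnitudes directly from the
  generative model (Gamma likelihood, log link, power-law fixed effects,
  nod and participant random intercepts).  Defaults reproduce the best
  published parameterization (varying ``a``, constant ``b`` and ``c``) and a
  length distribution with a 42% share of single nods and a geometric tail.
* :func:`render_pitch_trace` / :func:`render_corpus` turn simulated
  magnitudes into frame-level pitch traces built from half-cosine
  half-cycles, with optional Gaussian jitter, flat rest gaps between nods
  and exact ground-truth inflection frames — the inverse of the kinematics
  module, used for round-trip and window-selection tests.

The half-cosine waveform is a deliberate idealization: real nod traces are
irregular, and waveform realism is not a goal here; what matters is that the
rendered extremes and inflection structure are exactly known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import CYCLE_TABLE_COLUMNS, PitchTrace
from .model_family import FixedParams, ModelSpec, fixed_effect, get_model

__all__ = [
    "SimConfig",
    "SimTruth",
    "TraceRenderConfig",
    "default_length_probs",
    "sample_nod_lengths",
    "simulate_cycle_table",
    "render_pitch_trace",
    "render_corpus",
    "make_annotation_fixture",
]

#: Best-model posterior medians used as the default simulation truth.
DEFAULT_PARAMS = FixedParams(alpha_a=1.087, beta_a=0.093, gamma_a=0.865,
                             b=-0.098, c=-0.509)
DEFAULT_SIGMA_N = 0.492
DEFAULT_SIGMA_P = 0.297
DEFAULT_K = 1.976


def default_length_probs(p1: float = 0.42, ratio: float = 0.5,
                         max_length: int = 5) -> np.ndarray:
    """Length distribution: P(1) fixed, geometric tail over 2..max_length."""
    tail = ratio ** np.arange(max_length - 1)
    tail = (1.0 - p1) * tail / tail.sum()
    return np.concatenate([[p1], tail])


@dataclass(frozen=True)
class SimConfig:
    """Generative settings for a synthetic cycle table."""

    n_nods: int = 3000
    n_participants: int = 36
    length_probs: np.ndarray = field(default_factory=default_length_probs)
    params: FixedParams = DEFAULT_PARAMS
    spec: ModelSpec = field(default_factory=lambda: get_model(5))
    sigma_n: float = DEFAULT_SIGMA_N
    sigma_p: float = DEFAULT_SIGMA_P
    k: float = DEFAULT_K
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.length_probs, dtype=float)
        object.__setattr__(self, "length_probs", p)
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValueError("length_probs must be a probability vector")
        if self.sigma_n < 0 or self.sigma_p < 0 or self.k <= 0:
            raise ValueError("scales must be positive")


@dataclass
class SimTruth:
    """Complete bookkeeping for one simulated corpus."""

    nods: pd.DataFrame           # nod_id, participant_id, length, alpha_n
    participants: pd.DataFrame   # participant_id, alpha_p
    mu: np.ndarray               # per cycle-table row, E[y]
    config: SimConfig
    # filled by rendering:
    half_cycle_counts: dict[str, int] = field(default_factory=dict)
    inflection_frames: dict[str, list[int]] = field(default_factory=dict)
    trailing_single: dict[str, bool] = field(default_factory=dict)

    def to_json(self) -> str:
        import json

        return json.dumps({
            "nods": self.nods.to_dict(orient="list"),
            "participants": self.participants.to_dict(orient="list"),
            "mu": self.mu.tolist(),
            "half_cycle_counts": self.half_cycle_counts,
            "trailing_single": self.trailing_single,
        })


@dataclass(frozen=True)
class TraceRenderConfig:
    """Frame-level rendering of simulated nods as half-cosine half-cycles."""

    frame_rate: float = 30.0
    half_cycle_s: tuple[float, float] = (0.15, 0.45)  # uniform duration range
    down_start_prob: float = 0.5
    jitter_sd_deg: float = 0.0
    trailing_single_prob: float = 0.1
    gap_s: float = 0.5  # flat rest between consecutive nods of a participant

    def __post_init__(self) -> None:
        lo = self.half_cycle_s[0]
        if int(round(lo * self.frame_rate)) < 3:
            raise ValueError("shortest half-cycle must span at least 3 frames")


def sample_nod_lengths(cfg: SimConfig,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw nod lengths 1..L from the configured distribution."""
    rng = rng or np.random.default_rng(cfg.seed)
    support = np.arange(1, len(cfg.length_probs) + 1)
    return rng.choice(support, size=cfg.n_nods, p=cfg.length_probs)


def simulate_cycle_table(cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a long-format cycle table from the generative model.

    Nods are assigned to participants uniformly at random; each nod gets a
    length, a nod intercept alpha_n ~ N(0, sigma_n), and each cycle a
    magnitude y ~ Gamma(k, mu/k) with
    log mu = fixed(position, length) + alpha_n + alpha_p.
    """
    rng = np.random.default_rng(cfg.seed)
    lengths = sample_nod_lengths(cfg, rng)
    part_of_nod = rng.integers(0, cfg.n_participants, size=cfg.n_nods)
    alpha_p = rng.normal(0.0, cfg.sigma_p, size=cfg.n_participants)
    alpha_n = rng.normal(0.0, cfg.sigma_n, size=cfg.n_nods)

    nod_ids = np.array([f"nod{i:06d}" for i in range(cfg.n_nods)])
    part_ids = np.array([f"p{j:03d}" for j in range(cfg.n_participants)])

    row_nod = np.repeat(np.arange(cfg.n_nods), lengths)
    position = np.concatenate([np.arange(1, L + 1) for L in lengths])
    length_row = np.repeat(lengths, lengths)
    final = position == length_row

    fixed = fixed_effect(cfg.spec, cfg.params, position, length_row, final)
    mu = np.exp(np.asarray(fixed) + alpha_n[row_nod] + alpha_p[part_of_nod][row_nod])
    y = rng.gamma(shape=cfg.k, scale=mu / cfg.k)

    table = pd.DataFrame({
        "nod_id": nod_ids[row_nod],
        "participant_id": part_ids[part_of_nod][row_nod],
        "length": length_row,
        "position": position,
        "is_final": final,
        "magnitude_deg": y,
    })[CYCLE_TABLE_COLUMNS]

    truth = SimTruth(
        nods=pd.DataFrame({"nod_id": nod_ids,
                           "participant_id": part_ids[part_of_nod],
                           "length": lengths, "alpha_n": alpha_n}),
        participants=pd.DataFrame({"participant_id": part_ids,
                                   "alpha_p": alpha_p}),
        mu=mu,
        config=cfg,
    )
    return table, truth


def _render_nod(magnitudes: np.ndarray, cfg: TraceRenderConfig,
                rng: np.random.Generator, start_value: float,
                trailing_single: bool) -> tuple[np.ndarray, list[int]]:
    """Render one nod; returns samples (first frame = start baseline) and
    nod-local boundary indices (start, each inflection, end)."""
    n_half = 2 * len(magnitudes) - (1 if trailing_single else 0)
    sign = -1.0 if rng.uniform() < cfg.down_start_prob else 1.0
    durations = rng.uniform(*cfg.half_cycle_s, size=n_half)
    frames = np.maximum(np.round(durations * cfg.frame_rate).astype(int), 3)

    samples = [np.array([start_value])]
    boundaries = [0]
    pos = 0
    v = start_value
    h = 0
    for ci, mag in enumerate(magnitudes):
        targets = [v + sign * mag, v]
        if trailing_single and ci == len(magnitudes) - 1:
            targets = targets[:1]
        for tgt in targets:
            d = frames[h]
            tau = np.arange(1, d + 1) / d
            samples.append(v + (tgt - v) * (1 - np.cos(np.pi * tau)) / 2)
            v = tgt
            pos += d
            boundaries.append(pos)
            h += 1
    return np.concatenate(samples), boundaries


def render_pitch_trace(
    magnitudes: np.ndarray | list[float],
    cfg: TraceRenderConfig = TraceRenderConfig(),
    seed: int | np.random.Generator = 0,
    participant_id: str = "p000",
    trailing_single: bool = False,
) -> tuple[PitchTrace, dict]:
    """Render a single nod's magnitudes as a pitch trace.

    Returns the trace and a ground-truth dict with the inflection frame
    indices and half-cycle count.  Magnitudes must be positive; half-cycles
    shorter than 3 frames are rejected by the config.
    """
    mags = np.asarray(magnitudes, dtype=float)
    if np.any(mags <= 0):
        raise ValueError("magnitudes must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    samples, boundaries = _render_nod(mags, cfg, rng, 0.0, trailing_single)
    if cfg.jitter_sd_deg > 0:
        samples = samples + rng.normal(0.0, cfg.jitter_sd_deg, size=len(samples))
    t = np.arange(len(samples)) / cfg.frame_rate
    trace = PitchTrace(participant_id, cfg.frame_rate, t, samples)
    truth = {"inflection_frames": boundaries[1:-1],
             "half_cycle_count": len(boundaries) - 1}
    return trace, truth


def render_corpus(
    table: pd.DataFrame,
    truth: SimTruth,
    cfg: TraceRenderConfig = TraceRenderConfig(),
    seed: int = 0,
) -> tuple[list[PitchTrace], pd.DataFrame]:
    """Render every simulated nod into per-participant traces with rest gaps.

    Returns one trace per participant plus an annotation table
    (participant_id, start_s, end_s, label, half_cycles, nod_id) whose rows
    follow the nod order of the simulated table.  Ground-truth half-cycle
    counts and trailing-single flags are recorded on ``truth``.
    """
    rng = np.random.default_rng(seed)
    fps = cfg.frame_rate
    gap_frames = max(int(round(cfg.gap_s * fps)), 1)
    ann_rows = []
    traces = []
    for pid, nods in truth.nods.groupby("participant_id", sort=True):
        chunks = []
        pos = 0
        v = 0.0
        for _, nod in nods.iterrows():
            mags = table.loc[table["nod_id"] == nod["nod_id"],
                             "magnitude_deg"].to_numpy()
            trailing = bool(rng.uniform() < cfg.trailing_single_prob)
            samples, boundaries = _render_nod(mags, cfg, rng, v, trailing)
            start_f = pos
            end_f = pos + len(samples) - 1
            ann_rows.append({
                "participant_id": pid,
                "start_s": start_f / fps,
                "end_s": (end_f + 0.5) / fps,
                "label": "nod",
                "half_cycles": len(boundaries) - 1,
                "nod_id": nod["nod_id"],
            })
            truth.half_cycle_counts[nod["nod_id"]] = len(boundaries) - 1
            truth.inflection_frames[nod["nod_id"]] = \
                [b + start_f for b in boundaries[1:-1]]
            truth.trailing_single[nod["nod_id"]] = trailing
            v = samples[-1]
            chunks.append(samples)
            chunks.append(np.full(gap_frames, v))
            pos = end_f + 1 + gap_frames
        x = np.concatenate(chunks)
        if cfg.jitter_sd_deg > 0:
            x = x + rng.normal(0.0, cfg.jitter_sd_deg, size=len(x))
        t = np.arange(len(x)) / fps
        traces.append(PitchTrace(str(pid), fps, t, x))
    ann = pd.DataFrame(ann_rows)
    return traces, ann


def make_annotation_fixture(annotations: pd.DataFrame,
                            path: str | Path | None = None) -> str:
    """Serialize an annotation table to the TSV dialect the kinematics
    module reads (participant_id, start_s, end_s, label, half_cycles)."""
    cols = ["participant_id", "start_s", "end_s", "label"]
    if "half_cycles" in annotations.columns:
        cols.append("half_cycles")
    out = annotations[cols] if len(annotations) else \
        pd.DataFrame(columns=cols)
    text = out.to_csv(sep="\t", index=False)
    if path is not None:
        Path(path).write_text(text)
    return text
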