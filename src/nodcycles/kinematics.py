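"""Segmentation of head-pitch traces into nod cycles.

A *nod* is one or more continuous vertical (pitch) head movements; a
*half-cycle* is a single monotone upward or downward movement; a *cycle* is a
pair of consecutive opposite-direction half-cycles (an odd trailing half-cycle
also counts as a cycle).  The *magnitude* of a cycle is the difference, in
degrees, between the highest and lowest head position within the cycle; the
*length* of a nod is its number of cycles and *position* the 1-based index of
a cycle within its nod.

This module turns raw head-pitch time series (OpenFace ``pose_Rx``
convention: radians, downward-positive) plus nod-segment annotations into a
validated long-format cycle table ready for modelling, applying moving-average
smoothing, inflection detection, cycle assembly and outlier exclusion.

Conventions: frames are 0-based; segments are half-open ``[start_s, end_s)``;
pitch is in degrees with upward head motion positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PitchTrace",
    "NodSegment",
    "HalfCycle",
    "Cycle",
    "NodRecord",
    "SmoothingConfig",
    "TooShortError",
    "preprocess_pitch",
    "smooth_trace",
    "detect_inflections",
    "segment_into_cycles",
    "cycle_magnitude",
    "select_window_size",
    "apply_exclusions",
    "build_cycle_table",
    "segment_nods",
    "read_openface_csv",
    "read_annotations",
    "write_cycle_table",
    "write_exclusion_log",
    "CYCLE_TABLE_COLUMNS",
]

CYCLE_TABLE_COLUMNS = [
    "nod_id",
    "participant_id",
    "length",
    "position",
    "is_final",
    "magnitude_deg",
]

#: Exclusion reasons, in precedence order (earlier wins).
EXCLUSION_REASONS = ("too_short", "magnitude_gt_90", "zero_magnitude", "length_gt_5")


class TooShortError(ValueError):
    """Raised when a nod segment is too short to segment (a single frame)."""


@dataclass(frozen=True)
class PitchTrace:
    """A frame-indexed head-pitch series in degrees, up-positive."""

    participant_id: str
    frame_rate: float
    t: np.ndarray
    pitch_deg: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        p = np.asarray(self.pitch_deg, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "pitch_deg", p)
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        if t.shape != p.shape or t.ndim != 1:
            raise ValueError("t and pitch_deg must be 1-D arrays of equal length")
        if len(t) == 0:
            raise ValueError("empty trace")
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.frame_rate) > 1e-6):
                raise ValueError("frame spacing inconsistent with frame_rate")

    def __len__(self) -> int:
        return len(self.t)

    def slice_seconds(self, start_s: float, end_s: float) -> "PitchTrace":
        """Return the sub-trace covering the half-open interval [start_s, end_s)."""
        mask = (self.t >= start_s - 1e-9) & (self.t < end_s - 1e-9)
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            raise ValueError(f"segment [{start_s}, {end_s}) contains no frames")
        return PitchTrace(
            self.participant_id, self.frame_rate, self.t[idx], self.pitch_deg[idx]
        )


@dataclass(frozen=True)
class NodSegment:
    """A half-open [start_s, end_s) annotation of one nod on a trace."""

    participant_id: str
    start_s: float
    end_s: float
    label: str = "nod"

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"end_s ({self.end_s}) must exceed start_s ({self.start_s})"
            )


@dataclass(frozen=True)
class HalfCycle:
    """A single monotone movement: frames [start_idx, end_idx), direction up/down."""

    start_idx: int
    end_idx: int
    direction: str

    def __post_init__(self) -> None:
        if self.end_idx <= self.start_idx:
            raise ValueError("end_idx must exceed start_idx")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction}")


@dataclass(frozen=True)
class Cycle:
    """One cycle of a nod: a half-cycle pair, or an odd trailing half-cycle."""

    position: int
    start_idx: int
    end_idx: int  # inclusive of the closing boundary frame
    composed_of: str  # "pair" | "trailing_single"
    magnitude_deg: float = float("nan")


@dataclass
class NodRecord:
    """A segmented nod: ordered cycles plus exclusion bookkeeping."""

    nod_id: str
    participant_id: str
    cycles: list[Cycle] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str | None = None
    start_direction: str | None = None  # recorded but unused by the models

    @property
    def length(self) -> int:
        return len(self.cycles)


@dataclass(frozen=True)
class SmoothingConfig:
    """Centered moving-average window (odd, in frames; 0 = no smoothing).

    At the edges the window shrinks to the available frames, so the series
    keeps its length.
    """

    window: int = 5

    def __post_init__(self) -> None:
        if self.window < 0 or (self.window > 0 and self.window % 2 == 0):
            raise ValueError(f"window must be 0 or odd positive, got {self.window}")


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------


def preprocess_pitch(
    raw_pose_rx: Sequence[float] | np.ndarray,
    frame_rate: float,
    participant_id: str = "",
    t: np.ndarray | None = None,
) -> PitchTrace:
    """Convert raw OpenFace pitch (radians, downward-positive) to degrees, up-positive.

    ``pitch_deg = -pose_Rx * 180 / pi``: the sign is inverted so that upward
    head motion increases the value, and radians are converted to degrees.
    """
    rx = np.asarray(raw_pose_rx, dtype=float)
    bad = np.nonzero(~np.isfinite(rx))[0]
    if len(bad):
        raise ValueError(f"non-finite pose_Rx at frame index {bad[0]}")
    pitch_deg = -np.degrees(rx)
    if t is None:
        t = np.arange(len(rx)) / frame_rate
    return PitchTrace(participant_id, frame_rate, t, pitch_deg)


def smooth_trace(trace: PitchTrace, cfg: SmoothingConfig) -> PitchTrace:
    """Centered moving average with the window shrinking at the edges.

    A window of 0 or 1 returns the trace unchanged.
    """
    w = cfg.window
    if w <= 1:
        return trace
    x = trace.pitch_deg
    n = len(x)
    half = w // 2
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return PitchTrace(trace.participant_id, trace.frame_rate, trace.t, smoothed)


def _diff_signs(x: np.ndarray) -> np.ndarray:
    """Signs of first differences; zeros inherit the most recent nonzero sign.

    A leading run of zero differences takes the sign of the first nonzero
    difference, so plateaus never produce spurious inflections.  An all-flat
    series yields all zeros.
    """
    d = np.diff(x)
    s = np.sign(d)
    nz = np.nonzero(s)[0]
    if len(nz) == 0:
        return s  # flat: no direction at all
    # forward-fill nonzero signs; leading zeros take the first nonzero sign
    filled = s.copy()
    filled[: nz[0]] = s[nz[0]]
    last = s[nz[0]]
    for i in range(nz[0], len(s)):
        if filled[i] == 0:
            filled[i] = last
        else:
            last = filled[i]
    return filled


def detect_inflections(smoothed: PitchTrace) -> list[int]:
    """Frame indices where the first-difference polarity changes.

    The number of half-cycles in the segment equals the number of inflection
    points plus one.  A single-frame segment cannot be differenced and raises
    :class:`TooShortError`.
    """
    x = smoothed.pitch_deg
    if len(x) < 2:
        raise TooShortError("segment has a single frame; cannot difference")
    s = _diff_signs(x)
    flips = np.nonzero(s[1:] != s[:-1])[0] + 1
    return [int(i) for i in flips]


def _half_cycles_from_boundaries(
    x: np.ndarray, boundaries: list[int]
) -> list[HalfCycle]:
    out = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        direction = "up" if x[b] >= x[a] else "down"
        out.append(HalfCycle(a, b, direction))
    return out


def segment_into_cycles(half_cycles: Sequence[HalfCycle]) -> list[Cycle]:
    """Pair consecutive half-cycles into cycles.

    N half-cycles yield ``ceil(N/2)`` cycles; an odd trailing half-cycle is
    itself regarded as a cycle.  Boundary frames are shared: each cycle's span
    includes both its opening and closing inflection frames.
    """
    if not half_cycles:
        raise ValueError("no half-cycles to segment")
    cycles: list[Cycle] = []
    for m in range(0, len(half_cycles), 2):
        pair = half_cycles[m : m + 2]
        composed = "pair" if len(pair) == 2 else "trailing_single"
        cycles.append(
            Cycle(
                position=m // 2 + 1,
                start_idx=pair[0].start_idx,
                end_idx=pair[-1].end_idx,
                composed_of=composed,
            )
        )
    return cycles


def cycle_magnitude(pitch_deg: np.ndarray, cycle: Cycle) -> float:
    """Highest minus lowest pitch over the cycle span, boundary frames included."""
    span = pitch_deg[cycle.start_idx : cycle.end_idx + 1]
    if len(span) == 0:
        raise ValueError("empty cycle span")
    return float(span.max() - span.min())


def _segment_one(
    trace: PitchTrace, nod_id: str, window: int
) -> NodRecord:
    """Segment one nod's (already sliced) trace into cycles with magnitudes."""
    rec = NodRecord(nod_id=nod_id, participant_id=trace.participant_id)
    try:
        smoothed = smooth_trace(trace, SmoothingConfig(window))
        inflections = detect_inflections(smoothed)
    except TooShortError:
        rec.excluded = True
        rec.exclusion_reason = "too_short"
        return rec
    x = smoothed.pitch_deg
    boundaries = [0, *inflections, len(x) - 1]
    # degenerate single-frame half-cycle guard (inflection at the last frame)
    boundaries = sorted(set(boundaries))
    halves = _half_cycles_from_boundaries(x, boundaries)
    cycles = segment_into_cycles(halves)
    rec.cycles = [
        Cycle(c.position, c.start_idx, c.end_idx, c.composed_of,
              cycle_magnitude(x, c))
        for c in cycles
    ]
    rec.start_direction = halves[0].direction
    return rec


def segment_nods(
    trace: PitchTrace,
    segments: Iterable[NodSegment],
    window: int = 5,
    nod_id_prefix: str = "",
) -> list[NodRecord]:
    """Slice a trace by nod annotations and segment each nod into cycles.

    Magnitudes are computed on the smoothed series so that extremes stay
    consistent with the detected cycle boundaries.
    """
    records = []
    for i, seg in enumerate(segments):
        sub = trace.slice_seconds(seg.start_s, seg.end_s)
        nod_id = f"{nod_id_prefix}{trace.participant_id}_{i:05d}"
        records.append(_segment_one(sub, nod_id, window))
    return records


def estimate_half_cycle_count(trace: PitchTrace, window: int) -> int:
    """Number of half-cycles of a (sliced) nod trace at a given window size."""
    smoothed = smooth_trace(trace, SmoothingConfig(window))
    return len(detect_inflections(smoothed)) + 1


def select_window_size(
    traces: Sequence[PitchTrace],
    annotated_half_cycles: Sequence[int],
    candidate_windows: Sequence[int] = (0, 3, 5, 7, 9),
) -> tuple[SmoothingConfig, dict[int, float]]:
    """Pick the moving-average window minimising half-cycle-count MAE.

    For every candidate window the number of half-cycles of each annotated
    nod is estimated from the smoothed trace and compared with the manual
    annotation; the window with the smallest mean absolute error wins, ties
    going to the smaller window.  Returns the chosen config and the per-window
    MAE table.
    """
    if len(traces) == 0 or len(traces) != len(annotated_half_cycles):
        raise ValueError("need matching non-empty traces and annotated counts")
    truth = np.asarray(annotated_half_cycles, dtype=float)
    maes: dict[int, float] = {}
    for w in candidate_windows:
        est = np.array(
            [estimate_half_cycle_count(tr, w) for tr in traces], dtype=float
        )
        maes[w] = float(np.mean(np.abs(est - truth)))
    best = min(sorted(maes), key=lambda w: maes[w])
    return SmoothingConfig(best), maes


def apply_exclusions(
    nods: Sequence[NodRecord], max_length: int = 5
) -> tuple[list[NodRecord], dict]:
    """Drop outlier nods and over-long nods; return retained nods and a log.

    A nod is excluded as a whole if it was too short to segment, if any cycle
    exceeds 90 degrees (head-pose misestimation), if any cycle has magnitude
    exactly 0 (undetectable motion or segmentation slack), or if its length
    exceeds ``max_length``.  Reasons are assigned with precedence
    too_short > magnitude_gt_90 > zero_magnitude > length_gt_5.
    """
    retained: list[NodRecord] = []
    counts = {r: 0 for r in EXCLUSION_REASONS}
    excluded_records = []
    for nod in nods:
        reason = None
        if nod.excluded and nod.exclusion_reason == "too_short":
            reason = "too_short"
        elif any(c.magnitude_deg > 90.0 for c in nod.cycles):
            reason = "magnitude_gt_90"
        elif any(c.magnitude_deg == 0.0 for c in nod.cycles):
            reason = "zero_magnitude"
        elif nod.length > max_length:
            reason = "length_gt_5"
        if reason is None:
            retained.append(nod)
        else:
            nod.excluded = True
            nod.exclusion_reason = reason
            counts[reason] += 1
            excluded_records.append(
                {"nod_id": nod.nod_id, "participant_id": nod.participant_id,
                 "length": nod.length, "reason": reason}
            )
    log = {
        "n_input": len(nods),
        "n_retained": len(retained),
        "reason_counts": counts,
        "excluded": excluded_records,
    }
    return retained, log


def build_cycle_table(nods: Sequence[NodRecord]) -> pd.DataFrame:
    """Long-format observation table: one row per cycle of each retained nod."""
    rows = []
    for nod in nods:
        n = nod.length
        for c in nod.cycles:
            rows.append(
                (nod.nod_id, nod.participant_id, n, c.position,
                 c.position == n, c.magnitude_deg)
            )
    return pd.DataFrame(rows, columns=CYCLE_TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# file I/O (OpenFace dialect and annotation TSV)
# ---------------------------------------------------------------------------


def read_openface_csv(
    path: str | Path, participant_id: str | None = None
) -> PitchTrace:
    """Read an OpenFace FeatureExtraction CSV into a :class:`PitchTrace`.

    Requires columns ``frame``, ``timestamp`` and ``pose_Rx`` (radians);
    any other columns are ignored.  OpenFace writes headers with a leading
    space, which is stripped.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    for col in ("frame", "timestamp", "pose_Rx"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    ts = df["timestamp"].to_numpy(float)
    if len(ts) > 1:
        frame_rate = 1.0 / np.median(np.diff(ts))
    else:
        frame_rate = 30.0
    pid = participant_id if participant_id is not None else Path(path).stem
    return preprocess_pitch(df["pose_Rx"].to_numpy(float), frame_rate, pid, t=ts)


def read_annotations(path: str | Path) -> list[NodSegment]:
    """Read a nod-annotation TSV; only rows labelled ``nod`` are kept.

    Expected header: ``participant_id  start_s  end_s  label`` (tab separated);
    an optional ``half_cycles`` column carries manual half-cycle counts for
    window selection and is preserved on the returned segments as an attribute
    dictionary entry.
    """
    df = pd.read_csv(path, sep="\t")
    segments = []
    for _, row in df.iterrows():
        if str(row["label"]) != "nod":
            continue
        segments.append(
            NodSegment(str(row["participant_id"]), float(row["start_s"]),
                       float(row["end_s"]))
        )
    return segments


def read_annotation_half_cycles(path: str | Path) -> list[int]:
    """Manual half-cycle counts from an annotation TSV with a half_cycles column."""
    df = pd.read_csv(path, sep="\t")
    if "half_cycles" not in df.columns:
        raise ValueError(f"{path}: no half_cycles column")
    return [int(v) for v in df.loc[df["label"] == "nod", "half_cycles"]]


def write_cycle_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_exclusion_log(log: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(log, indent=2))
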