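"""Unit tests for pitch preprocessing, smoothing, inflection detection,
cycle assembly, magnitude computation and exclusion rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nodcycles.kinematics import (
    Cycle,
    HalfCycle,
    NodRecord,
    PitchTrace,
    SmoothingConfig,
    TooShortError,
    apply_exclusions,
    build_cycle_table,
    cycle_magnitude,
    detect_inflections,
    preprocess_pitch,
    read_annotations,
    read_openface_csv,
    segment_into_cycles,
    select_window_size,
    smooth_trace,
)
from nodcycles.synthetic import TraceRenderConfig, render_pitch_trace


def make_trace(values, fps=30.0):
    values = np.asarray(values, dtype=float)
    return PitchTrace("p0", fps, np.arange(len(values)) / fps, values)


class TestPreprocess:
    @pytest.mark.parametrize(
        "rad, expected_deg",
        [(0.0, 0.0), (0.1745, -9.99817), (-np.pi / 2, 90.0)],
    )
    def test_sign_inversion_and_degrees(self, rad, expected_deg):
        trace = preprocess_pitch([rad], frame_rate=30.0)
        assert trace.pitch_deg[0] == pytest.approx(expected_deg, abs=1e-4)

    def test_non_finite_rejected_with_frame_index(self):
        with pytest.raises(ValueError, match="frame index 2"):
            preprocess_pitch([0.0, 0.1, np.nan, 0.2], frame_rate=30.0)

    def test_timestamps_follow_frame_rate(self):
        trace = preprocess_pitch(np.zeros(5), frame_rate=25.0)
        assert np.allclose(np.diff(trace.t), 0.04)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        trace = make_trace(np.full(10, 3.5))
        out = smooth_trace(trace, SmoothingConfig(7))
        assert np.allclose(out.pitch_deg, 3.5)

    @pytest.mark.parametrize("window", [0, 1])
    def test_trivial_window_is_identity(self, window):
        trace = make_trace([1.0, -2.0, 3.0, 0.5])
        out = smooth_trace(trace, SmoothingConfig(window))
        assert np.array_equal(out.pitch_deg, trace.pitch_deg)

    def test_shrinking_edge_rule(self):
        # hand computation: center mean 1.0, first value = mean of first 3
        trace = make_trace([0, 0, 5, 0, 0])
        out = smooth_trace(trace, SmoothingConfig(5))
        assert out.pitch_deg[2] == pytest.approx(1.0)
        assert out.pitch_deg[0] == pytest.approx(5 / 3)
        assert out.pitch_deg[1] == pytest.approx(5 / 4)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            SmoothingConfig(4)


class TestInflections:
    def test_monotone_has_none(self):
        assert detect_inflections(make_trace([0, 1, 2, 3, 4])) == []

    def test_single_peak(self):
        assert detect_inflections(make_trace([0, 1, 0])) == [1]

    def test_sampled_sine_three_half_periods(self):
        # brute force over sampled first differences of 3 half-periods
        t = np.arange(0, 0.9, 1 / 30)
        x = np.cos(np.pi * t / 0.3)  # extrema at 0, 0.3, 0.6 s
        infl = detect_inflections(make_trace(x))
        assert len(infl) == 2  # 3 half-cycles

    def test_single_frame_raises_too_short(self):
        with pytest.raises(TooShortError):
            detect_inflections(make_trace([1.0]))

    def test_plateau_does_not_create_inflection(self):
        assert detect_inflections(make_trace([0, 1, 1, 2])) == []
        assert detect_inflections(make_trace([0, 1, 1, 0])) == [2]

    def test_leading_plateau_takes_first_nonzero_sign(self):
        assert detect_inflections(make_trace([1, 1, 2, 3])) == []


class TestCycleAssembly:
    @staticmethod
    def alternating_halves(n):
        return [
            HalfCycle(i, i + 1, "down" if i % 2 == 0 else "up") for i in range(n)
        ]

    @pytest.mark.parametrize(
        "n_halves, n_cycles, last_kind",
        [(4, 2, "pair"), (5, 3, "trailing_single"), (1, 1, "trailing_single")],
    )
    def test_pairing_rule(self, n_halves, n_cycles, last_kind):
        cycles = segment_into_cycles(self.alternating_halves(n_halves))
        assert len(cycles) == n_cycles
        assert cycles[-1].composed_of == last_kind
        assert [c.position for c in cycles] == list(range(1, n_cycles + 1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            segment_into_cycles([])

    @given(st.integers(min_value=1, max_value=40))
    @settings(max_examples=30, deadline=None)
    def test_ceil_rule_and_full_coverage(self, n_halves):
        cycles = segment_into_cycles(self.alternating_halves(n_halves))
        assert len(cycles) == -(-n_halves // 2)
        assert cycles[0].start_idx == 0
        assert cycles[-1].end_idx == n_halves

    def test_alternation_enforced_by_type(self):
        with pytest.raises(ValueError):
            HalfCycle(3, 3, "down")


class TestMagnitude:
    def test_peak_to_trough(self):
        c = Cycle(1, 0, 2, "pair")
        assert cycle_magnitude(np.array([0.0, -8.0, -2.0]), c) == pytest.approx(8.0)

    def test_half_cosine_dip_amplitude(self):
        tau = np.linspace(0, 1, 21)
        dip = -5.0 * (1 - np.cos(2 * np.pi * tau)) / 2  # 0 -> -5 -> 0
        c = Cycle(1, 0, 20, "pair")
        assert cycle_magnitude(dip, c) == pytest.approx(5.0)

    def test_flat_span_is_zero(self):
        c = Cycle(1, 0, 3, "pair")
        assert cycle_magnitude(np.full(4, 2.0), c) == 0.0

    @pytest.mark.parametrize("d", [8, 12, 20])
    @pytest.mark.parametrize("window", [3, 5])
    def test_smoothing_attenuation_bound(self, d, window):
        # half-cosine dip of amplitude A over d-frame half-cycles: after a
        # window-w moving average the magnitude stays within a loose band
        A = 6.0
        tau = np.arange(2 * d + 1) / d
        x = -A * (1 - np.cos(np.pi * np.minimum(tau, 2 - tau))) / 2
        out = smooth_trace(make_trace(x), SmoothingConfig(window))
        c = Cycle(1, 0, 2 * d, "pair")
        m = cycle_magnitude(out.pitch_deg, c)
        assert A * (1 - window / d) * 0.5 <= m <= A

    @given(st.floats(-50, 50), st.lists(st.floats(-20, 20), min_size=2,
                                        max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_shift_and_reversal_invariance(self, shift, values):
        x = np.asarray(values)
        c = Cycle(1, 0, len(x) - 1, "pair")
        m = cycle_magnitude(x, c)
        assert cycle_magnitude(x + shift, c) == pytest.approx(m, abs=1e-9)
        assert cycle_magnitude(x[::-1].copy(), c) == pytest.approx(m, abs=1e-9)


class TestWindowSelection:
    @staticmethod
    def rendered(jitter, n=30, seed=0):
        rng = np.random.default_rng(seed)
        cfg = TraceRenderConfig(jitter_sd_deg=jitter)
        traces, counts = [], []
        for i in range(n):
            mags = rng.uniform(2.0, 8.0, size=rng.integers(1, 4))
            trace, truth = render_pitch_trace(mags, cfg, seed=rng,
                                              participant_id=f"p{i}")
            traces.append(trace)
            counts.append(truth["half_cycle_count"])
        return traces, counts

    def test_noiseless_traces_select_window_zero(self):
        traces, counts = self.rendered(jitter=0.0)
        cfg, maes = select_window_size(traces, counts)
        assert cfg.window == 0
        assert maes[0] == 0.0

    def test_jitter_selects_nonzero_window(self):
        traces, counts = self.rendered(jitter=0.5, seed=1)
        cfg, maes = select_window_size(traces, counts)
        assert cfg.window > 0
        assert maes[cfg.window] < maes[0]

    def test_singleton_candidate_returned_regardless(self):
        traces, counts = self.rendered(jitter=0.0, n=1)
        cfg, _ = select_window_size(traces, counts, candidate_windows=[5])
        assert cfg.window == 5

    def test_empty_annotations_rejected(self):
        with pytest.raises(ValueError):
            select_window_size([], [])


def _nod(nod_id, mags, too_short=False):
    rec = NodRecord(nod_id=nod_id, participant_id="p0")
    if too_short:
        rec.excluded = True
        rec.exclusion_reason = "too_short"
        return rec
    n = len(mags)
    rec.cycles = [Cycle(i + 1, 0, 1, "pair", m) for i, m in enumerate(mags)]
    return rec


class TestExclusions:
    def test_magnitude_over_90_drops_whole_nod(self):
        retained, log = apply_exclusions([_nod("a", [95.0]), _nod("b", [5.0])])
        assert [n.nod_id for n in retained] == ["b"]
        assert log["reason_counts"]["magnitude_gt_90"] == 1

    def test_zero_magnitude_drops_whole_nod(self):
        retained, log = apply_exclusions([_nod("a", [4.0, 0.0, 3.0])])
        assert retained == []
        assert log["reason_counts"]["zero_magnitude"] == 1

    def test_length_over_five_excluded(self):
        retained, log = apply_exclusions([_nod("a", [3.0] * 6)])
        assert retained == []
        assert log["reason_counts"]["length_gt_5"] == 1

    def test_precedence_too_short_first(self):
        retained, log = apply_exclusions([_nod("a", [], too_short=True)])
        assert log["reason_counts"]["too_short"] == 1

    def test_precedence_magnitude_over_length(self):
        _, log = apply_exclusions([_nod("a", [95.0] * 6)])
        assert log["reason_counts"]["magnitude_gt_90"] == 1
        assert log["reason_counts"]["length_gt_5"] == 0

    def test_retained_plus_excluded_equals_input_and_magnitudes_unchanged(self):
        nods = [_nod("a", [5.0, 2.0]), _nod("b", [95.0]), _nod("c", [1.0])]
        retained, log = apply_exclusions(nods)
        assert len(retained) + len(log["excluded"]) == 3
        assert [c.magnitude_deg for c in retained[0].cycles] == [5.0, 2.0]


class TestCycleTable:
    def test_rows_and_final_flags(self):
        table = build_cycle_table([_nod("a", [2.0]), _nod("b", [3.0, 2.0, 1.0])])
        assert len(table) == 4
        finals = table.loc[table["is_final"], ["length", "position"]]
        assert set(map(tuple, finals.to_numpy())) == {(1, 1), (3, 3)}

    def test_empty_input(self):
        assert len(build_cycle_table([])) == 0


class TestIO:
    def test_openface_dialect_with_padded_headers(self, tmp_path):
        path = tmp_path / "of.csv"
        path.write_text(
            "frame, timestamp, confidence, pose_Rx, pose_Ry\n"
            "1, 0.000, 0.98, 0.10, 0.0\n"
            "2, 0.033333, 0.98, 0.20, 0.0\n"
            "3, 0.066667, 0.98, -0.10, 0.0\n"
        )
        trace = read_openface_csv(path, participant_id="p7")
        assert trace.participant_id == "p7"
        assert trace.pitch_deg[0] == pytest.approx(-np.degrees(0.10))
        assert trace.frame_rate == pytest.approx(30.0, rel=1e-3)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("frame,timestamp\n1,0.0\n")
        with pytest.raises(ValueError, match="pose_Rx"):
            read_openface_csv(path)

    def test_annotations_keep_only_nods(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "participant_id\tstart_s\tend_s\tlabel\n"
            "p0\t0.1\t0.9\tnod\n"
            "p0\t1.0\t1.5\tshake\n"
            "p0\t2.0\t2.4\tnod\n"
        )
        segs = read_annotations(path)
        assert len(segs) == 2
        assert segs[0].start_s == pytest.approx(0.1)
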