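import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitevents.errors import InsufficientDataError
from gaitevents.evaluate import (
    conventional_hs,
    evaluate,
    frequency_error,
    label_events_from_pressure,
    match_events,
    parse_strides,
    temporal_error,
)
from gaitevents.events import HS, TO, GaitEvent


class TestMetrics:
    @pytest.mark.parametrize(
        "det,ref,T,expected",
        [
            (1.00, 0.98, 10.0 / 3.0, -0.6),  # detected later -> delayed
            (0.98, 0.98, 10.0 / 3.0, 0.0),
            (0.90, 0.98, 10.0 / 3.0, 2.4),  # detected earlier -> early
        ],
    )
    def test_temporal_error_sign_convention(self, det, ref, T, expected):
        assert temporal_error(det, ref, T) == pytest.approx(expected, abs=0.01)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(0.0, 100.0),
        st.floats(0.0, 100.0),
        st.floats(0.5, 10.0),
    )
    def test_temporal_error_antisymmetry(self, a, b, T):
        assert temporal_error(a, b, T) == pytest.approx(-temporal_error(b, a, T))

    @pytest.mark.parametrize("nd,nr,expected", [(50, 50, 0.0), (47, 50, -6.0), (51, 50, 2.0)])
    def test_frequency_error(self, nd, nr, expected):
        assert frequency_error(nd, nr) == pytest.approx(expected)

    def test_frequency_error_needs_reference(self):
        with pytest.raises(ValueError):
            frequency_error(3, 0)


class TestParseStrides:
    def test_cycles_from_heel_strikes(self):
        ref = [GaitEvent(HS, t, source="reference") for t in (0.0, 10 / 3, 20 / 3)]
        strides = parse_strides(ref)
        assert len(strides) == 2
        assert strides["T"].to_numpy() == pytest.approx([10 / 3, 10 / 3])

    def test_to_fraction_arithmetic(self):
        # a TO at 1.9 s inside a [0, 10/3) cycle sits at 57% of it
        assert 100 * 1.9 / (10 / 3) == pytest.approx(57.0)

    def test_fewer_than_two_hs_rejected(self):
        with pytest.raises(InsufficientDataError):
            parse_strides([GaitEvent(HS, 1.0)])


class TestMatching:
    def test_one_to_one_nearest(self):
        pairs = match_events([1.0, 2.1, 3.0], [1.05, 2.0, 3.5], max_dist=0.6)
        assert pairs == [(0, 0), (1, 1), (2, 2)]

    def test_no_double_pairing(self):
        pairs = match_events([1.0, 1.01], [1.0], max_dist=0.5)
        assert len(pairs) == 1

    def test_out_of_window_unmatched(self):
        assert match_events([5.0], [1.0], max_dist=0.5) == []


def truth_events(n_strides, T=10 / 3, p_to=0.58):
    ev = []
    for i in range(n_strides):
        ev.append(GaitEvent(HS, i * T, stride=i, source="reference"))
        ev.append(GaitEvent(TO, i * T + p_to * T, stride=i, source="reference"))
    ev.append(GaitEvent(HS, n_strides * T, stride=n_strides, source="reference"))
    return ev


class TestEvaluate:
    def test_perfect_detection_scores_zero(self):
        ref = truth_events(5)
        det = [GaitEvent(e.kind, e.t, source="detector") for e in ref]
        report = evaluate(det, ref)
        s = report.summary().set_index("kind")
        assert s.loc[HS, "mae"] == 0.0 and s.loc[TO, "mae"] == 0.0
        assert s.loc[HS, "frequency_error_pct"] == 0.0

    def test_hand_built_errors(self):
        T = 10 / 3
        ref = truth_events(5)
        # shift the three inner heel strikes by +1%, -1%, +2% (early is +)
        shifts = {1: 0.01, 2: -0.01, 3: 0.02}
        det = []
        for e in ref:
            if e.kind == HS and e.stride in shifts:
                det.append(GaitEvent(HS, e.t - shifts[e.stride] * T))
            elif e.kind == HS:
                det.append(GaitEvent(HS, e.t))
        report = evaluate(det, [e for e in ref if e.kind == HS])
        hs = report.errors[report.errors.kind == HS]
        assert hs.error_pct.abs().mean() == pytest.approx(4 / 3, abs=1e-6)
        assert hs.error_pct.mean() == pytest.approx(2 / 3, abs=1e-6)

    def test_mae_bounds_signed_mean(self, bench):
        result, _ = bench
        s = result.adaptive.summary()
        assert (s["mae"] >= s["mean_signed"].abs() - 1e-12).all()

    def test_empty_reference_rejected(self):
        with pytest.raises(InsufficientDataError):
            evaluate([], [])

    def test_boundary_strides_excluded(self):
        ref = truth_events(4)
        # detections exist only for the inner cycles
        det = [GaitEvent(HS, e.t) for e in ref if e.kind == HS and 0 < e.stride < 4]
        report = evaluate(det, [e for e in ref if e.kind == HS])
        counts = report.counts.set_index("kind")
        assert counts.loc[HS, "n_miss"] == 0  # first/last cycles not demanded


class TestPressureLabeling:
    def test_clean_pulses_label_within_two_samples(self, clean_trace):
        trial = clean_trace.trial
        events = label_events_from_pressure(trial.heel, trial.toe, trial.fs)
        hs_ref = np.array([e.t for e in events if e.kind == HS])
        to_ref = np.array([e.t for e in events if e.kind == TO])
        hs_truth = [e.t for e in clean_trace.truth if e.kind == HS][1:-1]
        to_truth = [e.t for e in clean_trace.truth if e.kind == TO][1:-1]
        for t in hs_truth:
            assert np.abs(hs_ref - t).min() <= 2.0 / trial.fs + 1e-9
        for t in to_truth:
            assert np.abs(to_ref - t).min() <= 2.0 / trial.fs + 1e-9

    def test_scaling_both_channels_leaves_labels_unchanged(self, clean_trace):
        trial = clean_trace.trial
        base = label_events_from_pressure(trial.heel, trial.toe, trial.fs)
        scaled = label_events_from_pressure(10 * trial.heel, 10 * trial.toe, trial.fs)
        assert [e.t for e in base] == [e.t for e in scaled]

    def test_flat_toe_channel_yields_hs_only(self, clean_trace):
        trial = clean_trace.trial
        events = label_events_from_pressure(
            trial.heel, np.zeros_like(trial.toe), trial.fs
        )
        assert any(e.kind == HS for e in events)
        assert not any(e.kind == TO for e in events)

    def test_flat_heel_channel_yields_nothing(self, clean_trace):
        trial = clean_trace.trial
        events = label_events_from_pressure(
            np.zeros_like(trial.heel), trial.toe, trial.fs
        )
        assert events == []

    def test_noisy_pulses_still_label_every_cycle(self, noisy_trace):
        trial = noisy_trace.trial
        events = label_events_from_pressure(trial.heel, trial.toe, trial.fs)
        n_cycles = sum(e.kind == HS for e in noisy_trace.truth) - 1
        assert sum(e.kind == HS for e in events) >= 0.95 * n_cycles
        assert sum(e.kind == TO for e in events) >= 0.9 * n_cycles


class TestConventionalBaseline:
    def test_threshold_inside_every_descent_detects_all(self, clean_trace):
        trial = clean_trace.trial
        thr = float(clean_trace.features.theta_h.mean())
        events, _ = conventional_hs(trial, thr)
        report = evaluate(events, clean_trace.truth, subject="s", stride_freq_hz=0.3)
        counts = report.counts.set_index("kind")
        assert counts.loc[HS, "n_detected"] == counts.loc[HS, "n_reference"]

    def test_wide_population_spread_causes_misses(self, bench):
        result, _ = bench
        s = result.conventional.summary().set_index("kind")
        assert s.loc[HS, "frequency_error_pct"] < 0

    def test_adaptive_beats_conventional_temporal_mae(self, bench):
        result, _ = bench
        adaptive = result.adaptive.summary().set_index("kind").loc[HS, "mae"]
        conventional = result.conventional.summary().set_index("kind").loc[HS, "mae"]
        assert adaptive <= conventional
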