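import numpy as np
import pandas as pd
import pytest

from gaitevents import simulate
from gaitevents.simulate import (
    CROSS_CORR,
    EventCorrelationModel,
    make_dataset,
    nearest_positive_definite,
    sample_subject,
    simulate_trial,
)


class TestSubjectSampling:
    def test_same_seed_same_profile(self):
        a = sample_subject("healthy", 42)
        b = sample_subject("healthy", 42)
        assert np.allclose(a.event_mean, b.event_mean)
        assert a.theta_to == b.theta_to

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            sample_subject("robotic", 1)

    def test_hemiplegic_profile_carries_patient_calibration(self):
        prof = sample_subject("hemiplegic", 3)
        assert prof.theta_to[0] == pytest.approx(-7.68)
        assert prof.omega_to[0] == pytest.approx(0.26)
        assert prof.ax_to[0] == pytest.approx(1.27)
        assert 0.2 <= prof.preferred_freq <= 0.3

    def test_six_subject_hs_angle_spread_near_twenty_degrees(self):
        traces, _ = make_dataset(6, 10, rng_seed=8)
        by_subject = (
            pd.DataFrame(
                dict(s=t.trial.meta.subject_id, th=t.features.theta_h.mean())
                for t in traces
            )
            .groupby("s")["th"]
            .mean()
        )
        spread = by_subject.max() - by_subject.min()
        assert 15.0 <= spread <= 25.0


class TestCorrelationModel:
    def test_cross_block_matches_configured_table(self):
        model = EventCorrelationModel.default()
        assert np.abs(model.cross_block() - CROSS_CORR).max() < 0.02

    def test_nearest_pd_projection_repairs_indefinite_matrix(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(bad)[0] < 0
        fixed = nearest_positive_definite(bad)
        assert np.linalg.eigvalsh(fixed)[0] > 0
        assert np.allclose(np.diag(fixed), 1.0)

    def test_generated_cross_correlations_reproduce_table(self):
        # pooled over a wide cohort: between-subject variance dominates the
        # estimator, so convergence is in subjects, not strides
        traces, _ = make_dataset(400, 1, freqs=(0.3,), rng_seed=105)
        f = pd.concat([t.features for t in traces], ignore_index=True)
        got = np.array(
            [
                [np.corrcoef(f[p], f[h])[0, 1] for h in ("theta_h", "omega_h", "a_h")]
                for p in ("theta_p", "omega_p", "a_p")
            ]
        )
        assert np.abs(got - CROSS_CORR).max() < 0.10
        assert got[0, 0] == pytest.approx(0.8604, abs=0.05)


class TestSimulateTrial:
    def test_zero_noise_channels_pass_through_sampled_event_values(self, clean_trace):
        trial, f = clean_trace.trial, clean_trace.features
        for tcol, vcol, ch in [
            ("t_peak", "theta_p", trial.theta),
            ("t_peak", "omega_p", trial.omega),
            ("t_peak", "a_p", trial.ax),
            ("t_hs_next", "theta_h", trial.theta),
            ("t_hs_next", "omega_h", trial.omega),
            ("t_hs_next", "a_h", trial.ax),
            ("t_to", "theta_to", trial.theta),
            ("t_to", "omega_to", trial.omega),
            ("t_to", "a_to", trial.ax),
        ]:
            vals = np.interp(f[tcol], trial.t, ch)
            assert np.abs(vals - f[vcol]).max() < 0.1, vcol

    def test_truth_alternates_and_to_lies_inside_cycle(self, noisy_trace):
        kinds = [e.kind for e in noisy_trace.truth]
        assert kinds == ["HS", "TO"] * (len(kinds) // 2) + ["HS"]
        hs = [e.t for e in noisy_trace.truth if e.kind == "HS"]
        to = [e.t for e in noisy_trace.truth if e.kind == "TO"]
        for a, b, x in zip(hs, hs[1:], to):
            assert a < x < b

    def test_true_toe_off_fraction_is_58_percent_without_jitter(self):
        prof = sample_subject("healthy", 5)
        prof.stride_jitter_cv = 0.0
        trace = simulate_trial(prof, 0.3, 50, rng_seed=6)
        hs = np.array([e.t for e in trace.truth if e.kind == "HS"])
        to = np.array([e.t for e in trace.truth if e.kind == "TO"])
        frac = (to - hs[:-1]) / np.diff(hs)
        assert frac.mean() == pytest.approx(0.58, abs=0.01)

    def test_angular_velocity_positive_at_true_toe_off(self, healthy_traces):
        f = pd.concat([t.features for t in healthy_traces], ignore_index=True)
        assert (f.omega_to > 0).mean() >= 0.99

    def test_healthy_toe_off_statistics_calibrated(self, healthy_traces):
        f = pd.concat([t.features for t in healthy_traces], ignore_index=True)
        for col, mu in [("theta_to", -8.31), ("omega_to", 0.32), ("a_to", 1.76)]:
            se = f[col].std() / np.sqrt(len(f))
            assert abs(f[col].mean() - mu) < 2 * se, col

    def test_thigh_angle_descends_monotonically_peak_to_trough(self, clean_trace):
        trial, f = clean_trace.trial, clean_trace.features
        for rec in f.iloc[1:-1].itertuples():
            k0 = int(np.ceil(rec.t_peak * trial.fs)) + 1
            k1 = int((rec.t_hs_next + 0.45 * rec.T) * trial.fs)
            seg = trial.theta[k0 : min(k1, len(trial))]
            assert (np.diff(seg) <= 1e-9).all()

    def test_bad_arguments_rejected(self):
        prof = sample_subject("healthy", 1)
        with pytest.raises(ValueError):
            simulate_trial(prof, 1.5, 10)
        with pytest.raises(ValueError):
            simulate_trial(prof, 0.3, 0)
        with pytest.raises(ValueError):
            simulate_trial(prof, 0.11, 100000)


class TestMakeDataset:
    def test_one_trace_per_subject_and_frequency(self, healthy_traces):
        assert len(healthy_traces) == 18  # 6 subjects x 3 frequencies
        freqs = {t.trial.meta.stride_freq_hz for t in healthy_traces}
        assert freqs == {0.25, 0.3, 0.4}

    def test_same_seed_reproduces_manifest_and_data(self):
        t1, m1 = make_dataset(2, 5, rng_seed=9)
        t2, m2 = make_dataset(2, 5, rng_seed=9)
        assert m1 == m2
        for a, b in zip(t1, t2):
            assert np.array_equal(a.trial.theta, b.trial.theta)
            pd.testing.assert_frame_equal(a.features, b.features)

    def test_hemiplegic_subjects_walk_at_preferred_frequency(self):
        traces, _ = make_dataset(3, 40, group="hemiplegic", rng_seed=4)
        assert len(traces) == 3  # one preferred frequency each
        for t in traces:
            assert 0.2 <= t.trial.meta.stride_freq_hz <= 0.3
        f = pd.concat([t.features for t in traces], ignore_index=True)
        assert f.theta_to.mean() == pytest.approx(-7.68, abs=1.0)

    def test_save_load_roundtrip(self, tmp_path):
        traces, manifest = make_dataset(2, 4, freqs=(0.3,), rng_seed=12)
        simulate.save_dataset(traces, manifest, tmp_path)
        back = simulate.load_dataset(tmp_path)
        assert len(back) == 2
        orig = {t.trial.meta.subject_id: t for t in traces}
        for t in back:
            o = orig[t.trial.meta.subject_id]
            assert np.allclose(t.trial.theta, o.trial.theta, atol=1e-8)
            assert len(t.truth) == len(o.truth)
            assert np.allclose(t.features.theta_h, o.features.theta_h, atol=1e-8)
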