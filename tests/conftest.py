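import time

import pytest

from gaitevents import pipeline, simulate


@pytest.fixture(scope="session")
def bench():
    """Default end-to-end cohort run: 10 subjects x 30 strides x 3 stride
    frequencies, 7:3 subject split, fixed seed.  Returns (result, seconds)."""
    t0 = time.perf_counter()
    result = pipeline.run_benchmark(
        n_subjects=10, strides_per_freq=30, freqs=(0.25, 0.3, 0.4),
        rng_seed=11, keep_traces=True,
    )
    return result, time.perf_counter() - t0


@pytest.fixture(scope="session")
def healthy_traces():
    """Six healthy subjects, 20 strides at each of the three frequencies."""
    traces, _ = simulate.make_dataset(6, 20, rng_seed=101)
    return traces


@pytest.fixture(scope="session")
def clean_trace():
    """A noiseless 12-stride trial at the nominal 0.3 Hz cadence."""
    profile = simulate.sample_subject("healthy", 7)
    return simulate.simulate_trial(profile, 0.3, 12, noise_scale=0.0, rng_seed=8)


@pytest.fixture(scope="session")
def noisy_trace():
    """A default-noise 30-stride trial at 0.3 Hz."""
    profile = simulate.sample_subject("healthy", 7)
    return simulate.simulate_trial(profile, 0.3, 30, rng_seed=8)


@pytest.fixture(scope="session")
def zero_noise_cohort_model():
    """Zero-noise 0.3 Hz cohort plus a model trained on it."""
    from gaitevents import regression

    traces, _ = simulate.make_dataset(4, 15, freqs=(0.3,), rng_seed=104,
                                      noise_scale=0.0)
    pairs = regression.collect_training_pairs(traces)
    model = regression.fit_hs_model(pairs)
    return traces, model


def drive_with_truth_hs(trace, thresholds):
    """Run the TO detector over a filtered trial, blanking from truth HS."""
    from gaitevents.io import FilterSpec, ImuSample, filter_trial
    from gaitevents.to import ToState, on_hs, step_to

    filt = filter_trial(trace.trial, FilterSpec(fs=trace.trial.fs))
    hs_times = iter([e.t for e in trace.truth if e.kind == "HS"])
    nxt = next(hs_times)
    st = ToState(thresholds=thresholds, fs=trace.trial.fs)
    out = []
    nominal = 1.0 / trace.trial.meta.stride_freq_hz
    for k in range(len(filt)):
        t = filt.t[k]
        if nxt is not None and t >= nxt:
            on_hs(st, nxt, nominal)
            nxt = next(hs_times, None)
        ev = step_to(st, ImuSample(t, filt.theta[k], filt.omega[k], filt.ax[k]))
        if ev is not None:
            out.append(ev)
    return out
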