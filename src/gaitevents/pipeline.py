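"""End-to-end detection and cohort-level benchmark runs.

``detect_events`` is the deployment path: causal low-pass filtering, the
streaming adaptive heel-strike detector, and the refractory-gated toe-off
detector driven by the detected heel strikes, all in a single pass.
``run_benchmark`` reproduces the full study design on synthetic cohorts:
simulate, split by subject, train the threshold regression, detect on the
held-out subjects and score against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .evaluate import EvalReport, conventional_hs, evaluate, parse_strides
from .events import GaitEvent
from .hs import HSModel, HsConfig, HsState, step_hs
from .io import FilterSpec, TrialRecording, filter_trial
from .regression import collect_training_pairs, fit_hs_model, split_by_subject
from .simulate import GaitTrace, make_dataset
from .to import ToState, ToThresholds, on_hs, step_to


def detect_events(
    trial: TrialRecording,
    model: HSModel,
    hs_config: Optional[HsConfig] = None,
    to_thresholds: Optional[ToThresholds] = None,
) -> tuple[list[GaitEvent], dict]:
    """Detect alternating HS/TO events on one trial.

    Returns the event list (time-ordered) and diagnostics from the
    heel-strike state machine.
    """
    hs_config = hs_config or HsConfig()
    to_thresholds = to_thresholds or ToThresholds.preset(trial.meta.group)
    filt = filter_trial(trial, FilterSpec(fs=trial.fs))
    nominal_T = 1.0 / trial.meta.stride_freq_hz
    hs_state = HsState(nominal_T=nominal_T, config=hs_config)
    to_state = ToState(thresholds=to_thresholds, fs=trial.fs)
    out: list[GaitEvent] = []
    for k in range(len(filt)):
        sample = filt.sample_at(k)
        hs_ev = step_hs(hs_state, sample, model)
        if hs_ev is not None:
            out.append(hs_ev)
            on_hs(to_state, hs_ev.t, nominal_T)
        to_ev = step_to(to_state, sample)
        if to_ev is not None:
            out.append(to_ev)
    diagnostics = {
        "peaks_accepted": hs_state.n_peaks_accepted,
        "peaks_rejected": hs_state.n_peaks_rejected,
        "missed_crossings": hs_state.n_missed_crossings,
    }
    return out, diagnostics


@dataclass
class BenchmarkResult:
    """Everything a cohort run produces."""

    model: HSModel
    train_subjects: list
    test_subjects: list
    adaptive: EvalReport
    conventional: EvalReport
    traces: list = field(default_factory=list)
    per_trial_events: dict = field(default_factory=dict)


def _truth_report(
    trace: GaitTrace, detected: Sequence[GaitEvent], kinds: Optional[set] = None
) -> EvalReport:
    strides = parse_strides(trace.truth)
    reference = trace.truth if kinds is None else [e for e in trace.truth if e.kind in kinds]
    return evaluate(
        detected,
        reference,
        strides=strides,
        subject=trace.trial.meta.subject_id,
        stride_freq_hz=trace.trial.meta.stride_freq_hz,
    )


def run_benchmark(
    n_subjects: int = 20,
    strides_per_freq: int = 50,
    freqs: Sequence[float] = (0.25, 0.3, 0.4),
    group: str = "healthy",
    ratio: str = "7:3",
    rng_seed=0,
    noise_scale: float = 1.0,
    to_thresholds: Optional[ToThresholds] = None,
    model: Optional[HSModel] = None,
    keep_traces: bool = False,
) -> BenchmarkResult:
    """Simulate a cohort, train (unless a model is supplied), detect, score.

    The conventional fixed-threshold baseline uses the mean heel-strike
    thigh angle over the training split, mirroring how a practitioner
    would pick a single population threshold.
    """
    root = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    data_seed, split_seq = root.spawn(2)
    traces, _ = make_dataset(
        n_subjects, strides_per_freq, freqs=freqs, group=group,
        rng_seed=data_seed, noise_scale=noise_scale,
    )
    subjects = sorted({tr.trial.meta.subject_id for tr in traces})
    split_seed = int(split_seq.generate_state(1)[0] % 2**31)
    train_ids, test_ids = split_by_subject(subjects, ratio=ratio, seed=split_seed)
    train_traces = [t for t in traces if t.trial.meta.subject_id in train_ids]
    test_traces = [t for t in traces if t.trial.meta.subject_id in test_ids]

    pairs = collect_training_pairs(train_traces)
    if model is None:
        model = fit_hs_model(pairs)
    fixed_threshold = float(pairs["theta_h"].mean())
    to_thr = to_thresholds or ToThresholds.preset(group)

    adaptive_reports, conventional_reports = [], []
    per_trial_events = {}
    for trace in test_traces:
        detected, _ = detect_events(trace.trial, model, to_thresholds=to_thr)
        adaptive_reports.append(_truth_report(trace, detected))
        conv_events, _ = conventional_hs(trace.trial, fixed_threshold)
        conventional_reports.append(_truth_report(trace, conv_events, kinds={"HS"}))
        key = (trace.trial.meta.subject_id, trace.trial.meta.stride_freq_hz)
        per_trial_events[key] = detected

    return BenchmarkResult(
        model=model,
        train_subjects=train_ids,
        test_subjects=test_ids,
        adaptive=EvalReport.merge(adaptive_reports),
        conventional=EvalReport.merge(conventional_reports),
        traces=traces if keep_traces else [],
        per_trial_events=per_trial_events,
    )
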