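"""Reference labeling, stride parsing, and the two performance metrics.

Temporal error is the signed detection offset as a percentage of the gait
cycle (positive = early detection); frequency error is the signed
percentage of extra (+) or missed (-) detections relative to the reference
event count.  Reference events come either from simulator ground truth or
from the insole pressure channels via trend-based labeling (first sample
of a sustained heel-pressure rise for HS, first sample of the sustained
toe-pressure fall for TO), which is invariant to rescaling the pressure
channels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import GaitEventsError, InsufficientDataError
from .events import HS, TO, GaitEvent
from .hs import HSModel, HsConfig, detect_hs_trial
from .io import FilterSpec, TrialRecording, lowpass

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pressure-based reference labeling


def _sustained_runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """(start, stop) index pairs of runs of True at least min_len long."""
    runs = []
    k = 0
    n = mask.size
    while k < n:
        if mask[k]:
            j = k
            while j < n and mask[j]:
                j += 1
            if j - k >= min_len:
                runs.append((k, j))
            k = j
        else:
            k += 1
    return runs


def label_events_from_pressure(
    heel: np.ndarray,
    toe: np.ndarray,
    fs: float,
    kappa: float = 0.05,
    d: int = 3,
    fraction: float = 0.2,
    smooth_cutoff_hz: float = 10.0,
) -> list[GaitEvent]:
    """Label reference HS/TO events from insole pressure trends.

    HS is the first sample of a sustained heel-pressure rise (smoothed
    derivative above ``kappa *`` (robust range)/s for at least ``d``
    samples, starting from a low-pressure baseline and reaching stance
    level).  TO is the first sample of the sustained toe-pressure fall in
    each cycle that ends below ``fraction`` of that cycle's toe maximum.
    Only trends matter, so rescaling both channels leaves the labels
    unchanged.
    """
    heel = np.asarray(heel, dtype=float)
    toe = np.asarray(toe, dtype=float)
    if heel.shape != toe.shape:
        raise GaitEventsError("heel and toe channels must have equal length")
    spec = FilterSpec(fs=fs, cutoff=smooth_cutoff_hz, mode="zero_phase")
    hs_times = _label_heel_strikes(heel, fs, spec, kappa, d)
    if not hs_times:
        log.warning("flat heel channel: no reference events")
        return []
    events = []
    for i, t in enumerate(hs_times):
        events.append(GaitEvent(HS, t, stride=i, source="reference"))
    to_events = _label_toe_offs(toe, fs, spec, kappa, d, fraction, hs_times)
    events.extend(to_events)
    events.sort(key=lambda e: (e.t, e.kind == TO))
    return events


def _label_heel_strikes(heel, fs, spec, kappa, d) -> list[float]:
    rng_ = np.percentile(heel, 98) - np.percentile(heel, 2)
    if rng_ <= 1e-12:
        return []
    sm = lowpass(heel, spec)
    lo, hi = np.percentile(sm, 2), np.percentile(sm, 98)
    deriv = np.gradient(sm) * fs
    runs = _sustained_runs(deriv > kappa * rng_, d)
    times = []
    n = heel.size
    for start, stop in runs:
        # a heel-strike rise starts near baseline and reaches stance level
        if sm[start] - lo > 0.35 * rng_:
            continue
        ahead = sm[start : min(n, stop + int(0.3 * fs))]
        if ahead.max() - lo < 0.6 * rng_:
            continue
        t = start / fs
        if times and t - times[-1] < 0.5:  # merge ripples within a stance
            continue
        times.append(t)
    return times


def _label_toe_offs(toe, fs, spec, kappa, d, fraction, hs_times) -> list[GaitEvent]:
    rng_ = np.percentile(toe, 98) - np.percentile(toe, 2)
    if rng_ <= 1e-12:
        log.warning("flat toe channel: no reference TO events")
        return []
    sm = lowpass(toe, spec)
    lo = np.percentile(sm, 2)
    deriv = np.gradient(sm) * fs
    fall_runs = _sustained_runs(deriv < -kappa * rng_, d)
    out = []
    bounds = list(zip(hs_times, hs_times[1:]))
    for stride, (t0, t1) in enumerate(bounds):
        k0, k1 = int(t0 * fs), int(t1 * fs)
        cyc = sm[k0:k1]
        if cyc.size == 0:
            continue
        cycmax = cyc.max() - lo
        if cycmax < 0.3 * rng_:
            log.warning("stride %d: toe pulse too small, cycle flagged", stride)
            continue
        found = None
        max_fall = max(d, int(0.15 * (k1 - k0)))  # a fall is a short episode
        for start, stop in fall_runs:
            if not (k0 <= start < k1):
                continue
            if sm[start] - lo < 0.5 * cycmax:
                continue
            tail = sm[start : start + max_fall]
            if tail.min() - lo > fraction * cycmax:
                continue
            found = start / fs
            break
        if found is not None:
            out.append(GaitEvent(TO, found, stride=stride, source="reference"))
        else:
            log.warning("stride %d: no qualifying toe-pressure fall", stride)
    return out


# ---------------------------------------------------------------------------
# stride parsing and the two metrics


def parse_strides(reference: Sequence[GaitEvent]) -> pd.DataFrame:
    """Cycle table from reference heel strikes: cycle i = [HS_i, HS_{i+1})."""
    hs_times = [e.t for e in reference if e.kind == HS]
    if len(hs_times) < 2:
        raise InsufficientDataError("need at least 2 reference heel strikes")
    rows = [
        {"stride": i, "t_hs": a, "t_next": b, "T": b - a}
        for i, (a, b) in enumerate(zip(hs_times, hs_times[1:]))
    ]
    return pd.DataFrame(rows)


def temporal_error(detected_t: float, reference_t: float, T: float) -> float:
    """Signed error in % gait cycle; positive means early detection."""
    if T <= 0:
        raise ValueError("cycle duration must be positive")
    return 100.0 * (reference_t - detected_t) / T


def frequency_error(n_detected: int, n_reference: int) -> float:
    """Signed % of extra (+) or missed (-) detections."""
    if n_reference <= 0:
        raise ValueError("reference event count must be positive")
    return 100.0 * (n_detected - n_reference) / n_reference


def match_events(
    detected: Sequence[float], reference: Sequence[float], max_dist: float
) -> list[tuple[int, int]]:
    """One-to-one nearest matching of detected to reference times.

    Candidate pairs within ``max_dist`` are accepted greedily by distance,
    which is order-preserving whenever events are separated by more than
    2*max_dist (always true for per-cycle gait events).
    """
    cands = []
    for i, td in enumerate(detected):
        for j, tr in enumerate(reference):
            dt = abs(td - tr)
            if dt <= max_dist:
                cands.append((dt, i, j))
    cands.sort()
    used_d, used_r, pairs = set(), set(), []
    for _, i, j in cands:
        if i in used_d or j in used_r:
            continue
        used_d.add(i)
        used_r.add(j)
        pairs.append((i, j))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# evaluation report


@dataclass
class EvalReport:
    """Per-stride temporal errors plus per-kind detection counts.

    ``errors`` columns: subject, stride_freq_hz, kind, stride, error_pct.
    ``counts`` columns: subject, stride_freq_hz, kind, n_detected,
    n_reference, n_miss, n_extra.
    """

    errors: pd.DataFrame = field(default_factory=pd.DataFrame)
    counts: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def merge(cls, reports: Sequence["EvalReport"]) -> "EvalReport":
        return cls(
            errors=pd.concat([r.errors for r in reports], ignore_index=True),
            counts=pd.concat([r.counts for r in reports], ignore_index=True),
        )

    def summary(self, by_freq: bool = False) -> pd.DataFrame:
        keys = ["kind", "stride_freq_hz"] if by_freq else ["kind"]
        err = (
            self.errors.groupby(keys)["error_pct"]
            .agg(mae=lambda s: s.abs().mean(), sd="std", mean_signed="mean",
                 n_matched="count")
            .reset_index()
        )
        cnt = self.counts.groupby(keys)[["n_detected", "n_reference", "n_miss",
                                         "n_extra"]].sum().reset_index()
        out = err.merge(cnt, on=keys, how="outer")
        out["frequency_error_pct"] = 100.0 * (
            out["n_detected"] - out["n_reference"]
        ) / out["n_reference"]
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "summary": self.summary(by_freq=True).to_dict(orient="records"),
                "overall": self.summary().to_dict(orient="records"),
            },
            indent=2,
            default=float,
        )

    def text_table(self, label: str = "proposed") -> str:
        """Human-readable temporal/frequency table per event kind."""
        s = self.summary().set_index("kind")
        lines = [f"{'':12s}{'Performance':28s}{label}"]
        for kind in (HS, TO):
            if kind not in s.index:
                continue
            row = s.loc[kind]
            lines.append(
                f"{'Temporal':12s}{kind + ' error (%gait cycle)':28s}"
                f"{row['mae']:.1f} +- {row['sd']:.1f}"
            )
        for kind in (HS, TO):
            if kind not in s.index:
                continue
            row = s.loc[kind]
            lines.append(
                f"{'Frequency':12s}{kind + ' error (%)':28s}"
                f"{row['frequency_error_pct']:.1f}"
            )
        return "\n".join(lines)


def evaluate(
    detected: Sequence[GaitEvent],
    reference: Sequence[GaitEvent],
    strides: Optional[pd.DataFrame] = None,
    subject: str = "unknown",
    stride_freq_hz: float = np.nan,
) -> EvalReport:
    """Score detected events against a reference sequence for one trial.

    The first and last parsed stride are excluded (boundary effects).
    Matched events contribute temporal errors; unmatched events feed the
    frequency error as misses/extras only.
    """
    if not reference:
        raise InsufficientDataError("empty reference")
    if strides is None:
        strides = parse_strides(reference)
    if len(strides) < 3:
        raise InsufficientDataError("need >= 3 parsed strides to evaluate")
    inner = strides.iloc[1:-1]
    err_rows, cnt_rows = [], []

    for kind in (HS, TO):
        if kind == HS:
            ref = [
                (int(r["stride"]), float(r["t_hs"]), float(r["T"]))
                for _, r in inner.iterrows()
            ]
        else:
            to_by_cycle = {}
            for e in reference:
                if e.kind != TO:
                    continue
                hit = inner[(inner.t_hs <= e.t) & (e.t < inner.t_next)]
                if len(hit):
                    r = hit.iloc[0]
                    to_by_cycle[int(r["stride"])] = (e.t, float(r["T"]))
            ref = [(s, t, T) for s, (t, T) in sorted(to_by_cycle.items())]
        if not ref:
            continue
        half_t = 0.5 * float(inner["T"].median())
        lo = ref[0][1] - half_t
        hi = ref[-1][1] + half_t
        det = sorted(e.t for e in detected if e.kind == kind and lo <= e.t <= hi)
        pairs = match_events(det, [t for _, t, _ in ref], max_dist=half_t)
        for i, j in pairs:
            stride, t_ref, T = ref[j]
            err_rows.append(
                dict(subject=subject, stride_freq_hz=stride_freq_hz, kind=kind,
                     stride=stride, error_pct=temporal_error(det[i], t_ref, T))
            )
        cnt_rows.append(
            dict(subject=subject, stride_freq_hz=stride_freq_hz, kind=kind,
                 n_detected=len(det), n_reference=len(ref),
                 n_miss=len(ref) - len(pairs), n_extra=len(det) - len(pairs))
        )
    return EvalReport(errors=pd.DataFrame(err_rows), counts=pd.DataFrame(cnt_rows))


def conventional_hs(
    trial: TrialRecording,
    fixed_threshold_deg: float,
    config: Optional[HsConfig] = None,
) -> tuple[list[GaitEvent], dict]:
    """Fixed-threshold heel-strike baseline.

    Identical pipeline to the adaptive detector, but the peak-moment
    regression is replaced by a constant thigh-angle threshold with no
    clamp: peaks that never reach the threshold are counted as misses,
    which is exactly how wide inter-subject spread defeats fixed
    thresholds.
    """
    config = config or HsConfig(clamp=False)
    config.clamp = False
    model = HSModel(B=fixed_threshold_deg, W=np.zeros(3),
                    meta={"kind": "conventional-fixed"})
    return detect_hs_trial(trial, model, config)
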