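"""Streaming adaptive heel-strike detection.

The detector tracks the causally filtered thigh angle through three phases:

1. while the angle rises, watch for a turning point; accept it as the
   stride's thigh-angle peak if it is prominent enough and far enough from
   the previous accepted peak (refractory gate);
2. at the accepted peak, predict the heel-strike thigh-angle threshold from
   the three channel values at the peak via the linear model
   ``theta_h = B + W . (a_p, theta_p, omega_p)``;
3. during the descent, emit a heel strike at the first sample whose angle
   falls to or below the predicted threshold.

The prominence and refractory gates are artifact additions: a raw
"angle stopped rising" rule would fire on any mid-stance ripple.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import GaitEventsError
from .events import HS, GaitEvent
from .io import FilterSpec, ImuSample, TrialRecording, filter_trial

FEATURE_ORDER = ("a_p", "theta_p", "omega_p")


@dataclass(frozen=True)
class EventFeatures:
    """Channel values (theta deg, omega rad/s, ax sensor units) at a named
    gait instant, plus its time."""

    theta: float
    omega: float
    ax: float
    t: float

    def vector(self) -> np.ndarray:
        """Feature vector in model order (a, theta, omega)."""
        return np.array([self.ax, self.theta, self.omega])


@dataclass
class HSModel:
    """Linear heel-strike threshold model ``theta_h = B + W . x``.

    ``W`` is ordered (a_p, theta_p, omega_p).  ``meta`` carries training
    provenance (number of strides, subject ids, split ratio, residual
    summary).
    """

    B: float
    W: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (3,):
            raise ValueError("W must have exactly three coefficients")
        if not (np.isfinite(self.B) and np.all(np.isfinite(self.W))):
            raise ValueError("model coefficients must be finite")

    def predict(self, peak: EventFeatures) -> float:
        return float(self.B + self.W @ peak.vector())

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "B": self.B,
                    "W": self.W.tolist(),
                    "feature_order": list(FEATURE_ORDER),
                    "meta": self.meta,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path) -> "HSModel":
        d = json.loads(Path(path).read_text())
        if d.get("feature_order") != list(FEATURE_ORDER):
            raise GaitEventsError("model feature order mismatch")
        return cls(B=float(d["B"]), W=np.asarray(d["W"]), meta=d.get("meta", {}))


@dataclass
class HsConfig:
    prominence_deg: float = 5.0
    refractory_frac: float = 0.4
    clamp_eps_deg: float = 0.5
    #: hysteresis confirming a turn of the angle trace (peak or new rise)
    confirm_margin_deg: float = 1.0
    #: False disables the clamp (used by the fixed-threshold baseline)
    clamp: bool = True


def hs_threshold(model: HSModel, peak: EventFeatures, eps_deg: float = 0.5) -> float:
    """Predicted heel-strike threshold, clamped below the peak angle.

    The clamp (at most ``peak.theta - eps_deg``) prevents instant
    self-triggering when the regression over-predicts.
    """
    if model is None:
        raise GaitEventsError("untrained model")
    return min(model.predict(peak), peak.theta - eps_deg)


@dataclass
class HsState:
    """Mutable state of the streaming detector.

    The phase machine uses a small confirmation margin (hysteresis): a
    peak is only confirmed once the angle has dropped ``confirm_margin_deg``
    below the running maximum, and a failed descent is only abandoned once
    the angle has risen that margin above the running minimum.  Without
    this, single-sample noise wiggles on the flat peak top would both
    trigger premature turning points and abort genuine descents.
    """

    nominal_T: float
    config: HsConfig = field(default_factory=HsConfig)
    phase: str = "falling"  # falling | rising | descending
    best: Optional[EventFeatures] = None
    trough: float = np.inf
    run_min: float = np.inf
    threshold: Optional[float] = None
    last_peak_t: float = -np.inf
    last_hs_t: float = -np.inf
    prev_hs_t: float = -np.inf
    n_peaks_accepted: int = 0
    n_peaks_rejected: int = 0
    n_missed_crossings: int = 0

    @property
    def current_T(self) -> float:
        """Refractory base period: measured once two heel strikes exist,
        the trial's nominal stride period before that.  The measured value
        is clipped to [0.5, 1.5] x nominal so a single missed cycle cannot
        inflate the gate and reject the genuine peaks that follow."""
        if np.isfinite(self.prev_hs_t):
            measured = self.last_hs_t - self.prev_hs_t
            return float(np.clip(measured, 0.5 * self.nominal_T, 1.5 * self.nominal_T))
        return self.nominal_T


def step_hs(
    state: HsState, sample: ImuSample, model: HSModel
) -> Optional[GaitEvent]:
    """Advance the detector by one (already causally filtered) sample.

    Returns a heel-strike event when one is emitted, else ``None``.
    Mutates ``state`` in place.
    """
    cfg = state.config
    margin = cfg.confirm_margin_deg

    if state.phase == "falling":
        state.trough = min(state.trough, sample.theta)
        if sample.theta >= state.trough + margin:
            state.phase = "rising"
            state.best = EventFeatures(sample.theta, sample.omega, sample.ax, sample.t)
        return None

    if state.phase == "rising":
        if state.best is None or sample.theta > state.best.theta:
            state.best = EventFeatures(sample.theta, sample.omega, sample.ax, sample.t)
            return None
        if sample.theta <= state.best.theta - margin:
            candidate = state.best
            prominent = candidate.theta - state.trough >= cfg.prominence_deg
            clear = candidate.t - state.last_peak_t >= cfg.refractory_frac * state.current_T
            if prominent and clear:
                state.last_peak_t = candidate.t
                state.n_peaks_accepted += 1
                if cfg.clamp:
                    state.threshold = hs_threshold(model, candidate, cfg.clamp_eps_deg)
                else:
                    state.threshold = model.predict(candidate)
                if state.threshold >= candidate.theta:
                    # unclamped threshold above the peak: the descent can
                    # never cross it from above -- a structural miss
                    state.n_missed_crossings += 1
                    state.threshold = None
                    state.phase = "falling"
                    state.trough = sample.theta
                else:
                    state.phase = "descending"
                    state.run_min = sample.theta
            else:
                state.n_peaks_rejected += 1
                state.phase = "falling"
                state.trough = min(state.trough, sample.theta)
        return None

    # descending: wait for the threshold crossing
    state.run_min = min(state.run_min, sample.theta)
    if sample.theta <= state.threshold:
        state.phase = "falling"
        state.trough = sample.theta
        state.prev_hs_t = state.last_hs_t
        state.last_hs_t = sample.t
        return GaitEvent(HS, float(sample.t), source="detector")
    if sample.theta >= state.run_min + margin:
        # a new rise began without crossing the threshold: missed HS
        state.n_missed_crossings += 1
        state.phase = "rising"
        state.trough = state.run_min
        state.best = EventFeatures(sample.theta, sample.omega, sample.ax, sample.t)
    return None


def detect_hs_trial(
    trial: TrialRecording,
    model: HSModel,
    config: Optional[HsConfig] = None,
    prefiltered: bool = False,
) -> tuple[list[GaitEvent], dict]:
    """Run the streaming detector over a whole trial.

    The trial is causally filtered first unless ``prefiltered`` is set.
    Returns the heel-strike events and a diagnostics dict with accepted /
    rejected peak and missed-crossing counts.
    """
    config = config or HsConfig()
    if len(trial) == 0:
        return [], {"peaks_accepted": 0, "peaks_rejected": 0, "missed_crossings": 0}
    filt = trial if prefiltered else filter_trial(trial, FilterSpec(fs=trial.fs))
    state = HsState(nominal_T=1.0 / trial.meta.stride_freq_hz, config=config)
    out: list[GaitEvent] = []
    for k in range(len(filt)):
        ev = step_hs(state, filt.sample_at(k), model)
        if ev is not None:
            out.append(ev)
    diagnostics = {
        "peaks_accepted": state.n_peaks_accepted,
        "peaks_rejected": state.n_peaks_rejected,
        "missed_crossings": state.n_missed_crossings,
    }
    return out, diagnostics
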