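"""Toe-off detection: fixed observable thresholds behind a refractory gate.

A toe off is declared at the first sample after the blanking period where
the three conditions hold simultaneously:

    omega(t) >= omega_star      (angular velocity, rad/s)
    theta(t) <  theta_star      (thigh angle, deg)
    ax(t)    >  a_star          (forward axial acceleration)

The comparison operators are deliberately asymmetric (>=, <, >): the
angular-velocity bound is inclusive because it is the limiting threshold.
After each heel strike the detector idles for ``t_d = alpha * T`` (T is the
measured HS-to-HS period, or the trial's nominal period before two heel
strikes exist), which suppresses the mid-stance angular-velocity
fluctuation that would otherwise trigger early.  At most one toe off is
emitted per gait cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import GaitEventsError
from .events import TO, GaitEvent
from .io import ImuSample

#: published threshold sets per population
PRESETS = {
    "healthy": dict(theta_star=0.0, omega_star=0.2, a_star=0.0, alpha=0.4),
    "hemiplegic": dict(theta_star=0.0, omega_star=0.15, a_star=0.0, alpha=0.4),
}


@dataclass(frozen=True)
class ToThresholds:
    omega_star: float = 0.2
    theta_star: float = 0.0
    a_star: float = 0.0
    alpha: float = 0.4

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.alpha > 0.58:
            warnings.warn(
                "alpha > 0.58 overruns the typical toe-off instant (~58% of "
                "the cycle) and will make the detector miss toe offs",
                stacklevel=2,
            )

    @classmethod
    def preset(cls, population: str, **overrides) -> "ToThresholds":
        if population not in PRESETS:
            raise ValueError(f"unknown population preset {population!r}")
        params = dict(PRESETS[population])
        params.update(overrides)
        return cls(**params)


def check_to(sample: ImuSample, thr: ToThresholds) -> bool:
    """True iff the sample satisfies all three fixed thresholds."""
    return (
        sample.omega >= thr.omega_star
        and sample.theta < thr.theta_star
        and sample.ax > thr.a_star
    )


@dataclass
class ToState:
    """Refractory-gated per-cycle state.

    The elapsed time since the last heel strike is counted in integer
    samples and converted by ``fs``, so long trials accumulate no float
    drift.
    """

    thresholds: ToThresholds
    fs: float
    t_N: float = np.nan  # last HS time
    t_Nm1: float = np.nan  # HS before that
    T: float = np.nan  # current cycle duration estimate
    samples_since_hs: int = 0
    fired: bool = True  # no TO before the first HS

    @property
    def t_L(self) -> float:
        return self.samples_since_hs / self.fs

    @property
    def t_d(self) -> float:
        return self.thresholds.alpha * self.T

    @property
    def armed(self) -> bool:
        return (not self.fired) and np.isfinite(self.T) and self.t_L >= self.t_d


def on_hs(state: ToState, t_hs: float, nominal_T: float) -> ToState:
    """Register a heel strike: reset the cycle clock and blanking window.

    ``T`` is the measured interval between the last two heel strikes; the
    trial's nominal stride period is used until two of them exist.
    """
    if np.isfinite(state.t_N) and t_hs <= state.t_N:
        raise GaitEventsError("heel-strike times must be strictly increasing")
    state.t_Nm1 = state.t_N
    state.t_N = t_hs
    state.T = (state.t_N - state.t_Nm1) if np.isfinite(state.t_Nm1) else nominal_T
    state.samples_since_hs = 0
    state.fired = False
    return state


def step_to(state: ToState, sample: ImuSample, thr: Optional[ToThresholds] = None):
    """Advance one sample; emit a toe-off event if the detector is armed and
    the sample passes the threshold conjunction."""
    thr = thr or state.thresholds
    state.samples_since_hs += 1
    if not state.armed:
        return None
    if check_to(sample, thr):
        state.fired = True
        return GaitEvent(TO, float(sample.t), source="detector")
    return None
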