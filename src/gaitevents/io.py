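"""Trial container, CSV persistence, low-pass filtering and angle integration.

Signal conventions: the thigh angle ``theta`` is in degrees (0 deg at quiet
standing, positive with the thigh forward of vertical), the thigh angular
velocity ``omega`` is in rad/s about the mediolateral axis (positive during
forward swing), and ``ax`` is the forward axial acceleration in sensor
units.  All channels are sampled uniformly, 100 Hz by default.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .errors import FormatError, InsufficientDataError, InvalidSpecError
from .events import GaitEvent

RAD2DEG = 180.0 / np.pi

#: uniform-spacing tolerance on timestamps, seconds
_DT_TOL = 1e-6


@dataclass(frozen=True)
class ImuSample:
    """One IMU sample: time (s), thigh angle (deg), angular velocity (rad/s),
    forward axial acceleration (sensor units)."""

    t: float
    theta: float
    omega: float
    ax: float

    def __post_init__(self) -> None:
        for name in ("t", "theta", "omega", "ax"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite {name} in ImuSample")


@dataclass
class TrialMeta:
    subject_id: str = "unknown"
    group: str = "healthy"  # healthy | hemiplegic
    stride_freq_hz: float = 0.3
    leg: str = "right"


@dataclass
class TrialRecording:
    """A uniformly sampled multichannel gait trial.

    Channels are stored as 1-D float arrays of equal length.  ``heel`` and
    ``toe`` are optional insole-pressure channels (arbitrary nonnegative
    units) used only as reference ground truth.
    """

    fs: float
    t: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    ax: np.ndarray
    heel: Optional[np.ndarray] = None
    toe: Optional[np.ndarray] = None
    meta: TrialMeta = field(default_factory=TrialMeta)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        n = self.t.size
        for name in ("theta", "omega", "ax"):
            if getattr(self, name).size != n:
                raise FormatError(f"channel {name!r} length != time length")
        for name in ("heel", "toe"):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=float)
                setattr(self, name, ch)
                if ch.size != n:
                    raise FormatError(f"pressure channel {name!r} length mismatch")
        if n >= 2:
            dt = np.diff(self.t)
            bad = np.where(np.abs(dt - 1.0 / self.fs) > _DT_TOL)[0]
            if bad.size:
                raise FormatError(
                    f"timestamps not uniform at 1/fs: first offending row {bad[0] + 1}"
                )

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def samples(self):
        """Iterate over the IMU channels as :class:`ImuSample` objects."""
        for k in range(len(self)):
            yield ImuSample(self.t[k], self.theta[k], self.omega[k], self.ax[k])

    def sample_at(self, k: int) -> ImuSample:
        return ImuSample(
            float(self.t[k]), float(self.theta[k]), float(self.omega[k]), float(self.ax[k])
        )


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass specification.

    ``mode="causal"`` runs a single forward pass (direct form, step-matched
    initial condition) and is the only mode the real-time detection path may
    use; ``mode="zero_phase"`` is the offline two-pass variant reserved for
    reference labeling.
    """

    fs: float
    order: int = 2
    cutoff: float = 5.0
    mode: str = "causal"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise InvalidSpecError("filter order must be >= 1")
        if not (0.0 < self.cutoff < self.fs / 2.0):
            raise InvalidSpecError(
                f"cutoff {self.cutoff} Hz must lie in (0, fs/2) = (0, {self.fs / 2})"
            )
        if self.mode not in ("causal", "zero_phase"):
            raise InvalidSpecError(f"unknown filter mode {self.mode!r}")


def lowpass(series: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Butterworth low-pass filter a channel.

    The causal mode initializes the recursion at the first sample's value so
    that a constant input passes through without a startup transient.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3 * spec.order:
        raise InsufficientDataError(
            f"series of length {x.size} too short for order-{spec.order} filter"
        )
    b, a = _signal.butter(spec.order, spec.cutoff, fs=spec.fs)
    if spec.mode == "zero_phase":
        return _signal.filtfilt(b, a, x)
    zi = _signal.lfilter_zi(b, a) * x[0]
    y, _ = _signal.lfilter(b, a, x, zi=zi)
    return y


def filter_trial(trial: TrialRecording, spec: Optional[FilterSpec] = None) -> TrialRecording:
    """Return a copy of the trial with the three IMU channels filtered.

    Pressure channels are passed through untouched; the reference labeler
    does its own smoothing.
    """
    if spec is None:
        spec = FilterSpec(fs=trial.fs)
    return TrialRecording(
        fs=trial.fs,
        t=trial.t.copy(),
        theta=lowpass(trial.theta, spec),
        omega=lowpass(trial.omega, spec),
        ax=lowpass(trial.ax, spec),
        heel=None if trial.heel is None else trial.heel.copy(),
        toe=None if trial.toe is None else trial.toe.copy(),
        meta=trial.meta,
    )


def integrate_angle(omega: np.ndarray, theta0: float, fs: float) -> np.ndarray:
    """Accumulate angular velocity into an angle channel.

    ``theta[0] = theta0`` and ``theta[k] = theta[k-1] + omega[k] * (180/pi) / fs``:
    angular velocity in rad/s, angle out in degrees.  This mirrors the
    vertical-standing convention where the walk starts from a known angle and
    the angle is the running sum of rate times sampling interval.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    w = np.asarray(omega, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite angular velocity")
    theta = theta0 + np.cumsum(w) * (RAD2DEG / fs)
    theta[0] = theta0
    if w.size > 1:
        # recurrence skips omega[0]: theta[k] uses increments from k = 1 on
        theta[1:] = theta0 + np.cumsum(w[1:]) * (RAD2DEG / fs)
    return theta


# ---------------------------------------------------------------------------
# CSV persistence
#
# Dialect: "# key=value" comment header (fs, subject_id, group,
# stride_freq_hz, leg), then a header row "t,theta_deg,omega_rad_s,ax[,heel,toe]".

_REQUIRED_COLS = ("t", "theta_deg", "omega_rad_s", "ax")


def write_trial(trial: TrialRecording, path) -> None:
    """Write a trial to CSV; pressure columns are omitted when absent."""
    path = Path(path)
    cols = {
        "t": trial.t,
        "theta_deg": trial.theta,
        "omega_rad_s": trial.omega,
        "ax": trial.ax,
    }
    if trial.heel is not None:
        cols["heel"] = trial.heel
    if trial.toe is not None:
        cols["toe"] = trial.toe
    df = pd.DataFrame(cols)
    buf = _stdio.StringIO()
    m = trial.meta
    buf.write(f"# fs={trial.fs!r}\n")
    buf.write(f"# subject_id={m.subject_id}\n")
    buf.write(f"# group={m.group}\n")
    buf.write(f"# stride_freq_hz={m.stride_freq_hz!r}\n")
    buf.write(f"# leg={m.leg}\n")
    df.to_csv(buf, index=False, float_format="%.9g")
    path.write_text(buf.getvalue(), encoding="utf-8")


def _parse_header(lines: Sequence[str]) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def read_trial(path) -> TrialRecording:
    """Read a trial CSV written by :func:`write_trial`."""
    path = Path(path)
    header_lines = []
    with path.open("r", encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                header_lines.append(line)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        df = pd.read_csv(fh)
    meta_raw = _parse_header(header_lines)
    for col in _REQUIRED_COLS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    t = df["t"].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        bad = np.where(dt <= 0)[0]
        if bad.size:
            raise FormatError(f"non-monotone time at row {bad[0] + 1} in {path}")
    fs = float(meta_raw.get("fs", 100.0))
    meta = TrialMeta(
        subject_id=meta_raw.get("subject_id", "unknown"),
        group=meta_raw.get("group", "healthy"),
        stride_freq_hz=float(meta_raw.get("stride_freq_hz", 0.3)),
        leg=meta_raw.get("leg", "right"),
    )
    return TrialRecording(
        fs=fs,
        t=t,
        theta=df["theta_deg"].to_numpy(dtype=float),
        omega=df["omega_rad_s"].to_numpy(dtype=float),
        ax=df["ax"].to_numpy(dtype=float),
        heel=df["heel"].to_numpy(dtype=float) if "heel" in df.columns else None,
        toe=df["toe"].to_numpy(dtype=float) if "toe" in df.columns else None,
        meta=meta,
    )


def write_events(events: Sequence[GaitEvent], path) -> None:
    """Write an events CSV: columns stride,event,t."""
    df = pd.DataFrame(
        {"stride": [e.stride for e in events],
         "event": [e.kind for e in events],
         "t": [e.t for e in events]}
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_events(path, source: str = "detector") -> list[GaitEvent]:
    df = pd.read_csv(path)
    for col in ("stride", "event", "t"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    return [
        GaitEvent(kind=row.event, t=float(row.t), stride=int(row.stride), source=source)
        for row in df.itertuples()
    ]
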