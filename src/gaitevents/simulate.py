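"""Calibrated synthetic gait generator.

Produces labeled single-leg gait trials (thigh IMU channels plus insole
pressure) whose event-moment statistics are calibrated to the reference
values the detectors are designed around:

* toe off at 58% of the gait cycle, with healthy toe-off moment statistics
  (theta, omega, ax) of (-8.31 +- 5.17 deg, 0.32 +- 0.12 rad/s,
  1.76 +- 1.32) and hemiplegic analogs (-7.68 +- 4.36, 0.26 +- 0.11,
  1.27 +- 1.08);
* a configurable Pearson cross-correlation block between the three channel
  values at the thigh-angle peak and at the subsequent heel strike
  (defaults below reproduce the published table, e.g. r(theta_p, theta_h)
  = 0.8604);
* an inter-subject spread of the thigh angle at heel strike of roughly 20
  degrees across six subjects.

The thigh-angle waveform is built per stride by monotone shape-preserving
(PCHIP) interpolation through keyframes {HS, trough, TO, peak}, so the
angle decreases monotonically from each peak through the following heel
strike down to the trough.  The angular-velocity channel is the analytic
derivative of that interpolant plus a smooth correction pinned so that the
channel passes exactly through the sampled event-moment values; the axial
acceleration channel is interpolated directly through its event keyframes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.stats import norm

from .events import HS, TO, GaitEvent
from .io import RAD2DEG, TrialMeta, TrialRecording

DEG2RAD = np.pi / 180.0

# ---------------------------------------------------------------------------
# population constants
#
# Feature order everywhere: (theta_p, omega_p, a_p, theta_h, omega_h, a_h).
# The cross block below is the calibration target for the peak->HS Pearson
# table.  The within-peak correlations are free constants chosen so that
# the implied linear relation theta_h | (a_p, theta_p, omega_p) is nearly
# deterministic (residual SD ~0.19 deg): the adaptive-threshold premise is
# that the heel-strike angle is linearly encoded in the peak features, and
# the dispersion in real temporal errors is attributed to sensor noise and
# reference labeling rather than model misfit.

PEAK_MEANS = np.array([40.0, 0.05, -0.5])
PEAK_SDS = np.array([10.0, 0.25, 1.0])
HS_MEANS = np.array([23.0, -0.45, 0.3])
HS_SDS = np.array([10.0, 0.15, 0.3])

#: within-peak correlations (theta_p, omega_p, a_p) -- free calibration
R_PEAK = np.array(
    [
        [1.00, -0.64, -0.16],
        [-0.64, 1.00, -0.55],
        [-0.16, -0.55, 1.00],
    ]
)

#: peak-moment (rows theta_p, omega_p, a_p) x HS-moment (cols theta_h,
#: omega_h, a_h) Pearson correlations -- calibration target
CROSS_CORR = np.array(
    [
        [0.8604, -0.3798, 0.5932],
        [-0.2017, -0.1262, 0.0828],
        [-0.6393, 0.0883, -0.7062],
    ]
)

#: share of each feature's variance attributed to between-subject differences
BETWEEN_FRAC = 0.55

#: toe-off moment statistics (mean, sd) per group, order (theta, omega, ax)
TO_STATS = {
    "healthy": ((-8.31, 5.17), (0.32, 0.12), (1.76, 1.32)),
    "hemiplegic": ((-7.68, 4.36), (0.26, 0.11), (1.27, 1.08)),
}
#: physical clamps applied to per-stride toe-off draws: theta stays negative,
#: omega and ax stay positive, so every simulated toe off is detectable.
TO_CLAMPS = ((-1.0, "upper"), (0.05, "lower"), (0.15, "lower"))

THETA_MIN_MEAN, THETA_MIN_SD = -12.0, 3.0

DEFAULT_NOISE_SD = {"theta": 0.5, "omega": 0.05, "ax": 0.2, "pressure": 0.05}

MAX_SAMPLES = 2_000_000


def nearest_positive_definite(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest correlation-like PD matrix.

    Eigenvalues are clipped at ``eps`` and the diagonal is rescaled to 1.
    """
    sym = (corr + corr.T) / 2.0
    w, v = np.linalg.eigh(sym)
    fixed = (v * np.clip(w, eps, None)) @ v.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def _clamped_mean(mu: float, sigma: float, bound: float, side: str) -> float:
    """Mean of clip(N(mu, sigma), bound) for an upper or lower clamp."""
    z = (bound - mu) / sigma
    if side == "upper":
        # E[min(X, c)] = mu - [sigma*phi(z) + (mu-c)*(1-Phi(z))]
        return mu - (sigma * norm.pdf(z) + (mu - bound) * norm.sf(z))
    return mu + (sigma * norm.pdf(z) + (bound - mu) * norm.cdf(z))


def _compensated_center(target_mu: float, sigma: float, bound: float, side: str) -> float:
    """Center of the pre-clamp normal so the post-clamp mean equals target."""
    lo, hi = target_mu - 6 * sigma, target_mu + 6 * sigma
    return brentq(lambda m: _clamped_mean(m, sigma, bound, side) - target_mu, lo, hi)


@dataclass
class EventCorrelationModel:
    """Joint Gaussian over the 6-tuple (theta_p, omega_p, a_p, theta_h,
    omega_h, a_h), sampled per stride with a between/within-subject split.

    The cross-correlation block between peak and HS features is set to the
    configured table; within-HS correlations follow from regressing the HS
    features on the peak features with independent residuals, which keeps
    the assembled matrix positive definite by construction.
    """

    mean: np.ndarray
    cov: np.ndarray
    between_frac: float = BETWEEN_FRAC

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (6, 6) or self.mean.shape != (6,):
            raise ValueError("EventCorrelationModel must be 6-dimensional")
        w = np.linalg.eigvalsh((self.cov + self.cov.T) / 2)
        if w[0] <= 0:
            corr = self.correlation()
            corr = nearest_positive_definite(corr)
            sd = np.sqrt(np.diag(self.cov))
            self.cov = corr * np.outer(sd, sd)
        self._chol = np.linalg.cholesky(self.cov)

    @classmethod
    def default(cls) -> "EventCorrelationModel":
        corr = np.eye(6)
        corr[:3, :3] = R_PEAK
        corr[:3, 3:] = CROSS_CORR
        corr[3:, :3] = CROSS_CORR.T
        # implied within-HS correlations from shared dependence on the peak
        # features, residuals independent
        implied = CROSS_CORR.T @ np.linalg.inv(R_PEAK) @ CROSS_CORR
        hs_block = implied.copy()
        np.fill_diagonal(hs_block, 1.0)
        corr[3:, 3:] = hs_block
        sd = np.concatenate([PEAK_SDS, HS_SDS])
        mean = np.concatenate([PEAK_MEANS, HS_MEANS])
        return cls(mean=mean, cov=corr * np.outer(sd, sd))

    def correlation(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.cov))
        return self.cov / np.outer(sd, sd)

    def cross_block(self) -> np.ndarray:
        """Implied peak x HS Pearson block (rows theta_p, omega_p, a_p)."""
        return self.correlation()[:3, 3:]

    def sample_subject_mean(self, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(6)
        return self.mean + np.sqrt(self.between_frac) * (self._chol @ z)

    def sample_strides(
        self, subject_mean: np.ndarray, n: int, rng: np.random.Generator
    ) -> np.ndarray:
        z = rng.standard_normal((n, 6))
        return subject_mean + np.sqrt(1.0 - self.between_frac) * (z @ self._chol.T)


@dataclass
class SubjectProfile:
    """Per-subject generator parameters.

    ``event_mean`` holds the subject-level means of the 6-tuple
    (theta_p, omega_p, a_p, theta_h, omega_h, a_h); stride-to-stride
    variation around it comes from the population correlation model.
    Toe-off moment statistics are population-level (no subject offset), so
    the profile's ``theta_to``/``omega_to``/``ax_to`` means are the group
    calibration values verbatim.
    """

    group: str
    subject_id: str
    event_mean: np.ndarray
    correlation_model: EventCorrelationModel
    theta_to: tuple = TO_STATS["healthy"][0]
    omega_to: tuple = TO_STATS["healthy"][1]
    ax_to: tuple = TO_STATS["healthy"][2]
    theta_min: tuple = (THETA_MIN_MEAN, THETA_MIN_SD)
    p_peak: float = 0.90
    p_trough: float = 0.50
    p_to: float = 0.58
    p_footflat: float = 0.15
    p_heeloff: float = 0.45
    stride_jitter_cv: float = 0.02
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    preferred_freq: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.p_footflat < self.p_heeloff < self.p_to < self.p_peak < 1):
            raise ValueError("keyframe phases out of order")
        if not (
            self.theta_peak_mean > self.theta_hs_mean > self.theta_min[0]
        ):
            raise ValueError("keyframe angle means out of order")

    @property
    def theta_peak_mean(self) -> float:
        return float(self.event_mean[0])

    @property
    def theta_hs_mean(self) -> float:
        return float(self.event_mean[3])


def sample_subject(group: str, rng_seed) -> SubjectProfile:
    """Draw a subject profile for ``group`` ("healthy" | "hemiplegic").

    Deterministic given the seed.  Between-subject variation enters through
    the subject-level means of the peak/HS event features (about 20 deg of
    heel-strike thigh-angle spread across six subjects); toe-off statistics
    are population constants per group.
    """
    if group not in TO_STATS:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(rng_seed)
    model = EventCorrelationModel.default()
    # rejection sampling keeps the joint feature distribution intact (and
    # with it the linear peak->HS relation) while excluding geometrically
    # implausible subjects whose peak barely clears the heel-strike angle
    for _ in range(200):
        mu = model.sample_subject_mean(rng)
        if mu[0] - mu[3] >= 6.0:
            break
    stats = TO_STATS[group]
    preferred = None
    if group == "hemiplegic":
        preferred = float(rng.uniform(0.2, 0.3))
    return SubjectProfile(
        group=group,
        subject_id=f"{group[:4]}-{rng.integers(0, 10**8):08d}",
        event_mean=mu,
        correlation_model=model,
        theta_to=stats[0],
        omega_to=stats[1],
        ax_to=stats[2],
        preferred_freq=preferred,
    )


@dataclass
class GaitTrace:
    """A simulated trial plus its ground truth.

    ``truth`` alternates HS, TO, HS, ... with every TO strictly inside its
    HS-HS interval.  ``features`` has one row per stride with the sampled
    event-moment values the channels pass through at zero noise: columns
    ``t_peak, theta_p, omega_p, a_p`` (peak of stride i), ``t_hs_next,
    theta_h, omega_h, a_h`` (the following heel strike) and ``t_to,
    theta_to, omega_to, a_to, T`` (that stride's toe off and period).
    """

    trial: TrialRecording
    truth: list
    features: "object"  # pandas.DataFrame

    @property
    def n_strides(self) -> int:
        return len(self.features)


def _clamped_normal(
    rng: np.random.Generator, target_mu: float, sigma: float, bound: float, side: str, n: int
) -> np.ndarray:
    """Clamped normal draws whose post-clamp mean equals ``target_mu``."""
    center = _compensated_center(target_mu, sigma, bound, side)
    x = rng.normal(center, sigma, size=n)
    return np.minimum(x, bound) if side == "upper" else np.maximum(x, bound)


def _pressure_pulse(t, t_on, t_off, rise, fall):
    """Smooth unit pulse: cosine rise starting at t_on, plateau, cosine fall
    starting at t_off (so the fall ONSET marks the event of interest)."""
    y = np.zeros_like(t)
    u = (t - t_on) / rise
    rising = (u >= 0) & (u < 1)
    y[rising] = 0.5 * (1 - np.cos(np.pi * u[rising]))
    y[(t >= t_on + rise) & (t < t_off)] = 1.0
    v = (t - t_off) / fall
    falling = (v >= 0) & (v < 1)
    y[falling] = 0.5 * (1 + np.cos(np.pi * v[falling]))
    return y


def simulate_trial(
    profile: SubjectProfile,
    stride_freq: float,
    n_strides: int,
    fs: float = 100.0,
    noise_scale: float = 1.0,
    rng_seed=0,
) -> GaitTrace:
    """Simulate one continuous walking trial.

    Stride periods are jittered by the profile's CV around ``1/stride_freq``;
    keyframes are drawn per stride from the correlation model and the
    toe-off statistics, then the three IMU channels are built by monotone
    interpolation (see module docstring).  Gaussian channel noise is added
    before any filtering so the detection path's causal filter is exercised.
    """
    import pandas as pd

    if not (0.1 < stride_freq < 1.0):
        raise ValueError("stride_freq must lie in (0.1, 1.0) Hz")
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    if n_strides * (1.0 / stride_freq) * fs > MAX_SAMPLES:
        raise ValueError("requested trial exceeds the sample cap")

    rng = np.random.default_rng(rng_seed)
    n = n_strides
    T0 = 1.0 / stride_freq
    jitter = np.clip(rng.standard_normal(n + 1), -3, 3) * profile.stride_jitter_cv
    periods = T0 * (1.0 + jitter)  # one spare period for the tail

    tuples = profile.correlation_model.sample_strides(profile.event_mean, n, rng)
    # the heel strike happens a tenth of a cycle after the peak, mid-descent:
    # redraw strides whose peak-to-HS drop would be degenerate (rejection
    # keeps the linear peak->HS relation exact on every kept stride)
    for _ in range(100):
        bad = tuples[:, 0] - tuples[:, 3] < 3.5
        if not bad.any():
            break
        tuples[bad] = profile.correlation_model.sample_strides(
            profile.event_mean, int(bad.sum()), rng
        )
    theta_p, omega_p, a_p = tuples[:, 0], tuples[:, 1], tuples[:, 2]
    theta_h, omega_h, a_h = tuples[:, 3], tuples[:, 4], tuples[:, 5]

    to_draws = []
    for (mu, sd), (bound, side) in zip(
        (profile.theta_to, profile.omega_to, profile.ax_to), TO_CLAMPS
    ):
        to_draws.append(_clamped_normal(rng, mu, sd, bound, side, n))
    theta_to, omega_to, ax_to = to_draws
    # the thigh swings forward quickly once the foot leaves the ground: pin
    # the angle shortly after TO so the zero-crossing phase is consistent
    theta_postto = np.maximum(2.0, theta_to + 4.0)
    theta_p = np.maximum(theta_p, theta_postto + 6.0)

    theta_min = rng.normal(THETA_MIN_MEAN if profile.theta_min is None else profile.theta_min[0],
                           profile.theta_min[1], size=n + 1)

    # --- keyframe assembly -------------------------------------------------
    # stride i: HS_i .. trough .. TO_i .. peak_i .. HS_{i+1}; the angle at
    # HS_{i+1} is stride i's sampled theta_h (the quantity the adaptive
    # threshold predicts from the peak features).
    t_hs = np.concatenate([[0.0], np.cumsum(periods[:n])])
    hs_theta = np.concatenate([[profile.theta_hs_mean], theta_h])
    hs_omega = np.concatenate([[float(profile.event_mean[4])], omega_h])
    hs_ax = np.concatenate([[float(profile.event_mean[5])], a_h])

    kf_t, kf_theta = [], []
    w_t, w_target = [], []  # angular-velocity pin points (time, value rad/s)
    a_t, a_val = [], []
    truth: list[GaitEvent] = []
    rows = []
    p_preto = profile.p_to - 0.03

    for i in range(n):
        T = periods[i]
        t0 = t_hs[i]
        t_trough = t0 + profile.p_trough * T
        t_preto = t0 + p_preto * T
        t_to = t0 + profile.p_to * T
        t_postto = t0 + (profile.p_to + 0.07) * T
        t_peak = t0 + profile.p_peak * T
        t_next = t_hs[i + 1]
        tr = min(theta_min[i], hs_theta[i] - 5.0, theta_to[i] - 1.5)

        kf_t += [t0, t_trough, t_to, t_postto, t_peak]
        kf_theta += [hs_theta[i], tr, theta_to[i], theta_postto[i], theta_p[i]]

        # extra pins at ~5/6 of the cycle flatten omega and a_x across the
        # peak, so the peak-feature reads are insensitive to filter lag
        t_prepeak = t0 + (profile.p_peak - 0.07) * T
        w_t += [t0, t_trough, t_preto, t_to, t_prepeak, t_peak]
        w_target += [hs_omega[i], 0.0, 0.03, omega_to[i], omega_p[i], omega_p[i]]

        a_t += [t0, t_to, t_prepeak, t_peak]
        a_val += [hs_ax[i], ax_to[i], a_p[i], a_p[i]]

        truth.append(GaitEvent(HS, float(t0), stride=i, source="truth"))
        truth.append(GaitEvent(TO, float(t_to), stride=i, source="truth"))
        rows.append(
            dict(
                stride=i, T=float(T), t_hs=float(t0),
                t_peak=float(t_peak), theta_p=theta_p[i], omega_p=omega_p[i], a_p=a_p[i],
                t_hs_next=float(t_next), theta_h=theta_h[i], omega_h=omega_h[i], a_h=a_h[i],
                t_to=float(t_to), theta_to=theta_to[i], omega_to=omega_to[i], a_to=ax_to[i],
            )
        )

    # closing HS and a short tail so the last heel strike is detectable
    T_tail = periods[n]
    t_end_kf = t_hs[n] + 0.5 * T_tail
    tail_trough = min(theta_min[n], hs_theta[n] - 5.0)
    kf_t += [t_hs[n], t_end_kf]
    kf_theta += [hs_theta[n], tail_trough]
    w_t += [t_hs[n], t_end_kf]
    w_target += [hs_omega[n], 0.0]
    a_t += [t_hs[n], t_end_kf]
    a_val += [hs_ax[n], float(profile.event_mean[5])]
    truth.append(GaitEvent(HS, float(t_hs[n]), stride=n, source="truth"))

    theta_spline = PchipInterpolator(np.asarray(kf_t), np.asarray(kf_theta))
    dtheta = theta_spline.derivative()

    t_grid = np.arange(0.0, t_hs[n] + 0.45 * T_tail, 1.0 / fs)
    theta = theta_spline(t_grid)
    omega_base = dtheta(t_grid) * DEG2RAD

    w_t = np.asarray(w_t)
    offsets = np.asarray(w_target) - dtheta(w_t) * DEG2RAD
    offset_spline = PchipInterpolator(w_t, offsets)
    omega = omega_base + offset_spline(np.clip(t_grid, w_t[0], w_t[-1]))

    ax_spline = PchipInterpolator(np.asarray(a_t), np.asarray(a_val))
    ax = ax_spline(np.clip(t_grid, a_t[0], a_t[-1]))

    heel = np.zeros_like(t_grid)
    toe = np.zeros_like(t_grid)
    for i in range(n):
        T = periods[i]
        t0 = t_hs[i]
        heel += _pressure_pulse(
            t_grid, t0, t0 + profile.p_heeloff * T, rise=0.06 * T, fall=0.10 * T
        )
        toe += _pressure_pulse(
            t_grid, t0 + profile.p_footflat * T, t0 + profile.p_to * T,
            rise=0.08 * T, fall=0.06 * T,
        )

    if noise_scale > 0:
        ns = profile.noise_sd
        theta = theta + rng.normal(0, ns["theta"] * noise_scale, t_grid.size)
        omega = omega + rng.normal(0, ns["omega"] * noise_scale, t_grid.size)
        ax = ax + rng.normal(0, ns["ax"] * noise_scale, t_grid.size)
        heel = heel + rng.normal(0, ns["pressure"] * noise_scale, t_grid.size)
        toe = toe + rng.normal(0, ns["pressure"] * noise_scale, t_grid.size)
    heel = np.clip(heel, 0.0, None)
    toe = np.clip(toe, 0.0, None)

    trial = TrialRecording(
        fs=fs,
        t=t_grid,
        theta=theta,
        omega=omega,
        ax=ax,
        heel=heel,
        toe=toe,
        meta=TrialMeta(
            subject_id=profile.subject_id,
            group=profile.group,
            stride_freq_hz=stride_freq,
            leg="right",
        ),
    )
    return GaitTrace(trial=trial, truth=truth, features=pd.DataFrame(rows))


def save_trace(trace: GaitTrace, out_dir, stem: str) -> None:
    """Write a trace as three CSVs: trial, truth events, true feature tuples."""
    from pathlib import Path

    from .io import write_events, write_trial

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_trial(trace.trial, out_dir / f"{stem}.csv")
    write_events(trace.truth, out_dir / f"{stem}.events.csv")
    trace.features.to_csv(out_dir / f"{stem}.features.csv", index=False,
                          float_format="%.9g")


def load_trace(out_dir, stem: str) -> GaitTrace:
    import pandas as pd
    from pathlib import Path

    from .io import read_events, read_trial

    out_dir = Path(out_dir)
    trial = read_trial(out_dir / f"{stem}.csv")
    truth = read_events(out_dir / f"{stem}.events.csv", source="truth")
    features = pd.read_csv(out_dir / f"{stem}.features.csv")
    return GaitTrace(trial=trial, truth=truth, features=features)


def save_dataset(traces: Sequence[GaitTrace], manifest: dict, out_dir) -> list[str]:
    """Write every trace under <out_dir>/<subject>/trial_<freq>.{csv,...}
    plus a manifest.json; returns the list of stems written."""
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stems = []
    for trace in traces:
        meta = trace.trial.meta
        stem = f"trial_{meta.stride_freq_hz:.3f}hz"
        save_trace(trace, out_dir / meta.subject_id, stem)
        stems.append(f"{meta.subject_id}/{stem}")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return stems


def load_dataset(data_dir) -> list[GaitTrace]:
    from pathlib import Path

    data_dir = Path(data_dir)
    traces = []
    for trial_csv in sorted(data_dir.glob("*/*.csv")):
        if trial_csv.name.endswith(".events.csv") or trial_csv.name.endswith(
            ".features.csv"
        ):
            continue
        traces.append(load_trace(trial_csv.parent, trial_csv.stem))
    return traces


def make_dataset(
    n_subjects: int,
    strides_per_freq: int,
    freqs: Sequence[float] = (0.25, 0.3, 0.4),
    group: str = "healthy",
    rng_seed=0,
    fs: float = 100.0,
    noise_scale: float = 1.0,
) -> tuple[list[GaitTrace], dict]:
    """Generate one trace per (subject, stride frequency).

    Hemiplegic subjects walk at a single preferred frequency drawn from
    [0.2, 0.3] Hz instead of the supplied list.  Returns the traces and a
    manifest recording every seed used, so runs are reproducible.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    root = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    subject_seeds = root.spawn(n_subjects)
    traces: list[GaitTrace] = []
    manifest = {
        "rng_seed": rng_seed if isinstance(rng_seed, int) else repr(rng_seed),
        "group": group,
        "subjects": [],
    }
    for s, sseq in enumerate(subject_seeds):
        profile_seed, *trial_seeds = sseq.spawn(1 + len(freqs))
        profile = sample_subject(group, profile_seed)
        profile.subject_id = f"{group[:4]}{s:02d}"
        use_freqs = [profile.preferred_freq] if group == "hemiplegic" else list(freqs)
        entry = {"subject_id": profile.subject_id, "freqs": [], "trial_entropy": []}
        for f, tseq in zip(use_freqs, trial_seeds):
            traces.append(
                simulate_trial(
                    profile, f, strides_per_freq, fs=fs,
                    noise_scale=noise_scale, rng_seed=tseq,
                )
            )
            entry["freqs"].append(float(f))
            entry["trial_entropy"].append(int(tseq.entropy) % (2**63))
        manifest["subjects"].append(entry)
    return traces, manifest
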