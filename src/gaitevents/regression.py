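"""Fitting and inspecting the adaptive heel-strike threshold model.

The model is ordinary least squares on one row per stride: the three
channel values at the thigh-angle peak predict the thigh angle at the
following heel strike.  Splitting is always at the subject level so a
subject never appears in both train and test sets.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import GaitEventsError, InsufficientDataError, UndefinedCorrelationError
from .hs import FEATURE_ORDER, HSModel
from .io import FilterSpec, filter_trial
from .simulate import GaitTrace

log = logging.getLogger(__name__)

PEAK_COLS = ("theta_p", "omega_p", "a_p")
HS_COLS = ("theta_h", "omega_h", "a_h")


def _read_at(trial, t: float) -> tuple[float, float, float]:
    """Linearly interpolated channel values at an (off-grid) instant."""
    return (
        float(np.interp(t, trial.t, trial.theta)),
        float(np.interp(t, trial.t, trial.omega)),
        float(np.interp(t, trial.t, trial.ax)),
    )


def collect_training_pairs(
    traces: Sequence[GaitTrace], mode: str = "causal"
) -> pd.DataFrame:
    """One row per stride pairing peak-moment features with the HS angle.

    ``mode`` selects how the values are read:

    * ``"causal"`` (default, used for training the online detector) reads
      the causally filtered channels exactly the way the streaming
      detector does: the peak features at the causal channel's own
      thigh-angle maximum, and the target ``theta_h`` as the causal
      channel's value at the true heel-strike instant.  Training on the
      signal the detector actually sees makes the filter's group delay
      cancel at the threshold crossing instead of appearing as a
      stride-frequency-dependent detection delay.
    * ``"zero_phase"`` / ``"raw"`` read the (lag-free) filtered or
      unfiltered channels at the true event instants -- the offline
      reference reading used for correlation analysis.

    Rows with any non-finite value are dropped with a logged count.
    """
    rows = []
    for trace in traces:
        if trace.features is None or len(trace.features) == 0:
            raise GaitEventsError("trace carries no true events")
        trial = trace.trial
        if mode == "raw":
            src = trial
        else:
            fmode = "causal" if mode == "causal" else "zero_phase"
            src = filter_trial(trial, FilterSpec(fs=trial.fs, mode=fmode))
        for rec in trace.features.itertuples():
            if mode == "causal":
                # the causal channel peaks about one group delay after the
                # true peak; search a window around it like the detector does
                half = 0.12 * rec.T
                k0 = max(0, int((rec.t_peak - half - src.t[0]) * src.fs))
                k1 = min(len(src), int((rec.t_peak + half - src.t[0]) * src.fs) + 1)
                k = k0 + int(np.argmax(src.theta[k0:k1]))
                th_p, om_p, ax_p = (
                    float(src.theta[k]), float(src.omega[k]), float(src.ax[k])
                )
            else:
                th_p, om_p, ax_p = _read_at(src, rec.t_peak)
            th_h, om_h, ax_h = _read_at(src, rec.t_hs_next)
            rows.append(
                dict(
                    subject=trial.meta.subject_id,
                    stride_freq_hz=trial.meta.stride_freq_hz,
                    stride=rec.stride,
                    theta_p=th_p, omega_p=om_p, a_p=ax_p,
                    theta_h=th_h, omega_h=om_h, a_h=ax_h,
                )
            )
    df = pd.DataFrame(rows)
    finite = np.isfinite(df[list(PEAK_COLS + HS_COLS)].to_numpy()).all(axis=1)
    if (~finite).sum():
        log.warning("dropping %d rows with non-finite channels", int((~finite).sum()))
    return df[finite].reset_index(drop=True)


def fit_hs_model(pairs: pd.DataFrame) -> HSModel:
    """Ordinary least squares for (B, W), W ordered (a_p, theta_p, omega_p)."""
    if len(pairs) < 4:
        raise InsufficientDataError("need at least 4 strides to fit 4 parameters")
    X = np.column_stack(
        [np.ones(len(pairs)), pairs["a_p"], pairs["theta_p"], pairs["omega_p"]]
    )
    if np.linalg.matrix_rank(X) < 4:
        raise InsufficientDataError("design matrix is rank deficient")
    y = pairs["theta_h"].to_numpy(dtype=float)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    meta = {
        "n_strides": int(len(pairs)),
        "subjects": sorted(pairs["subject"].astype(str).unique().tolist()),
        "feature_order": list(FEATURE_ORDER),
        "residual_sd_deg": float(np.std(resid, ddof=4)),
        "residual_mae_deg": float(np.mean(np.abs(resid))),
    }
    return HSModel(B=float(coef[0]), W=coef[1:], meta=meta)


def pearson_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """3x3 Pearson table: rows (theta_p, omega_p, a_p), columns
    (theta_h, omega_h, a_h)."""
    if len(pairs) < 3:
        raise InsufficientDataError("need at least 3 rows for correlations")
    for col in PEAK_COLS + HS_COLS:
        if np.isclose(np.std(pairs[col].to_numpy()), 0.0):
            raise UndefinedCorrelationError(f"column {col!r} has zero variance")
    table = np.empty((3, 3))
    for i, pc in enumerate(PEAK_COLS):
        for j, hc in enumerate(HS_COLS):
            table[i, j] = np.corrcoef(pairs[pc], pairs[hc])[0, 1]
    return pd.DataFrame(table, index=list(PEAK_COLS), columns=list(HS_COLS))


def split_by_subject(
    subject_ids: Sequence[str], ratio="7:3", seed: Optional[int] = 0
) -> tuple[list[str], list[str]]:
    """Randomly split subjects into train/test sets at the given ratio.

    ``ratio`` may be a string like ``"7:3"`` (interpreted as proportions of
    the cohort) or a float train fraction.  Deterministic per seed.
    """
    ids = sorted(set(map(str, subject_ids)))
    n = len(ids)
    if isinstance(ratio, str):
        a, _, b = ratio.partition(":")
        frac = Fraction(int(a), int(a) + int(b))
    else:
        frac = Fraction(ratio).limit_denominator(1000)
    n_train = int(round(n * float(frac)))
    if n_train < 1 or n - n_train < 1:
        raise InsufficientDataError(
            f"cannot split {n} subjects at ratio {ratio!r}: both sets need >= 1"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = sorted(ids[k] for k in perm[:n_train])
    test = sorted(ids[k] for k in perm[n_train:])
    return train, test
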