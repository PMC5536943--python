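"""Conditioned-response scoring from eyelid EMG.

The instantaneous EMG amplitude is the magnitude of the analytic signal
(absolute Hilbert transform).  Per trial, two window-averaged amplitudes are
taken: the pre-CS value (200 ms before CS onset) and the CR value (200 ms
before real or virtual US onset).  A session-wide threshold T = mean + 1 SD
of all pre-CS values then drives a three-branch rule:

* pre > 1.3 T           -> trial discarded (animal hyperactive before the CS)
* pre <= T              -> CR iff cr > 1.1 T
* T < pre <= 1.3 T      -> CR iff (cr - T) >= 5 x (pre - T)

CR% per block is 100 x #CR / #valid trials.  pre-CR% re-runs the same rule
with the scoring window moved to 480-280 ms before CS onset, measuring blink
activity not time-locked to the CS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.fft import next_fast_len

from .types import EMGTrace, SessionSchedule, TrialTable, ValidationError

__all__ = [
    "CrDetectionParams",
    "CrScores",
    "emg_envelope",
    "session_threshold",
    "label_trial",
    "score_session",
    "block_cr_stats",
]

# Envelope of segments longer than this is computed piecewise with guard
# padding rather than in one session-length FFT.
_CHUNK_SAMPLES = 4_000_000
_GUARD_S = 0.5


@dataclass(frozen=True)
class CrDetectionParams:
    """Windows (s, relative to CS or US onset) and threshold factors."""

    pre_cs_window: tuple[float, float] = (-0.200, 0.0)  # rel. CS onset
    cr_window: tuple[float, float] = (-0.200, 0.0)  # rel. (virtual) US onset
    pre_cr_window: tuple[float, float] = (-0.480, -0.280)  # rel. CS onset
    threshold_k_sd: float = 1.0
    hyper_factor: float = 1.30
    cr_factor: float = 1.10
    ratio_factor: float = 5.0
    sd_ddof: int = 0  # population SD convention
    threshold_scope: str = "session"  # "session" | "block"
    bandpass: bool = True
    band_low_hz: float = 250.0
    band_high_hz: float = 5000.0

    def __post_init__(self) -> None:
        if self.hyper_factor <= 1 or self.cr_factor <= 1 or self.ratio_factor <= 0:
            raise ValidationError("threshold factors out of range")
        if self.threshold_scope not in ("session", "block"):
            raise ValidationError("threshold_scope must be 'session' or 'block'")


@dataclass
class CrScores:
    """Per-trial values/labels plus per-block CR statistics."""

    trial_df: pd.DataFrame  # trial_index, block_id, pre_cs_value, cr_value, label, pre_cr_label
    block_df: pd.DataFrame  # block_id, n_trials, n_valid, cr_percent, pre_cr_percent
    threshold: float

    @property
    def labels(self) -> np.ndarray:
        return self.trial_df["label"].to_numpy()


def _filtered(trace: EMGTrace, params: CrDetectionParams) -> np.ndarray:
    x = trace.samples
    if not params.bandpass:
        return x
    high = min(params.band_high_hz, 0.45 * trace.rate_hz)
    if high <= params.band_low_hz:
        raise ValidationError("band edges incompatible with EMG sampling rate")
    sos = signal.butter(4, [params.band_low_hz, high], btype="bandpass",
                        fs=trace.rate_hz, output="sos")
    return signal.sosfiltfilt(sos, x)


def emg_envelope(trace: EMGTrace, params: CrDetectionParams | None = None) -> np.ndarray:
    """Instantaneous amplitude: |analytic signal| of the (band-passed) EMG.

    Same length and time base as the input.  Long traces are processed in
    overlapping chunks with 0.5 s guards, since the analytic signal is only
    edge-contaminated within a filter transient of the segment boundary.
    """
    params = params or CrDetectionParams()
    if len(trace.samples) == 0:
        raise ValidationError("empty EMG trace")
    x = _filtered(trace, params)
    n = len(x)
    if n <= _CHUNK_SAMPLES:
        return np.abs(signal.hilbert(x, N=next_fast_len(n))[:n])
    guard = int(_GUARD_S * trace.rate_hz)
    out = np.empty(n)
    step = _CHUNK_SAMPLES
    for lo in range(0, n, step):
        hi = min(lo + step, n)
        a, b = max(0, lo - guard), min(n, hi + guard)
        seg = np.abs(signal.hilbert(x[a:b], N=next_fast_len(b - a))[: b - a])
        out[lo:hi] = seg[lo - a: lo - a + (hi - lo)]
    return out


def session_threshold(pre_cs_values: np.ndarray, k_sd: float = 1.0, ddof: int = 0) -> float:
    """Mean of all pre-CS values plus ``k_sd`` standard deviations."""
    v = np.asarray(pre_cs_values, float)
    if v.size < 2:
        raise ValidationError("threshold needs at least 2 pre-CS values")
    return float(v.mean() + k_sd * v.std(ddof=ddof))


def label_trial(pre: float, cr: float, threshold: float,
                params: CrDetectionParams | None = None) -> str:
    """Apply the three-branch CR rule; returns 'CR', 'noCR' or 'discarded'."""
    p = params or CrDetectionParams()
    t = threshold
    if pre > p.hyper_factor * t:
        return "discarded"
    if pre <= t:
        return "CR" if cr > p.cr_factor * t else "noCR"
    return "CR" if (cr - t) >= p.ratio_factor * (pre - t) else "noCR"


def _window_means(envelope: np.ndarray, rate_hz: float, t0_s: float,
                  starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    lo = np.round((starts - t0_s) * rate_hz).astype(int)
    hi = np.round((ends - t0_s) * rate_hz).astype(int)
    if lo.min() < 0 or hi.max() > len(envelope):
        raise ValidationError("scoring window outside the EMG trace")
    return np.array([envelope[a:b].mean() for a, b in zip(lo, hi)])


def score_session(trace: EMGTrace, trials: TrialTable,
                  schedule: SessionSchedule | None = None,
                  params: CrDetectionParams | None = None) -> CrScores:
    """Score every trial of a session and compute per-block CR%/pre-CR%."""
    params = params or CrDetectionParams()
    schedule = schedule or trials.schedule or SessionSchedule()
    env = emg_envelope(trace, params)
    cs_on = trials.df["cs_onset_s"].to_numpy(float)
    us_eq = trials.us_equivalent_s(schedule.trial_window_s)

    pre = _window_means(env, trace.rate_hz, trace.t0_s,
                        cs_on + params.pre_cs_window[0], cs_on + params.pre_cs_window[1])
    cr = _window_means(env, trace.rate_hz, trace.t0_s,
                       us_eq + params.cr_window[0], us_eq + params.cr_window[1])
    pre_cr = _window_means(env, trace.rate_hz, trace.t0_s,
                           cs_on + params.pre_cr_window[0], cs_on + params.pre_cr_window[1])

    block_ids = trials.df["block_id"].to_numpy()
    if params.threshold_scope == "session":
        thr = np.full(len(trials), session_threshold(pre, params.threshold_k_sd, params.sd_ddof))
    else:
        thr = np.empty(len(trials))
        for bid in np.unique(block_ids):
            m = block_ids == bid
            thr[m] = session_threshold(pre[m], params.threshold_k_sd, params.sd_ddof)

    labels = np.array([label_trial(p, c, t, params) for p, c, t in zip(pre, cr, thr)])
    pre_cr_labels = np.array([label_trial(p, c, t, params) for p, c, t in zip(pre, pre_cr, thr)])

    trial_df = pd.DataFrame({
        "trial_index": trials.df["trial_index"],
        "block_id": block_ids,
        "pre_cs_value": pre,
        "cr_value": cr,
        "pre_cr_value": pre_cr,
        "label": labels,
        "pre_cr_label": pre_cr_labels,
    })
    block_df = block_cr_stats(trial_df)
    return CrScores(trial_df=trial_df, block_df=block_df, threshold=float(thr[0]))


def block_cr_stats(trial_df: pd.DataFrame) -> pd.DataFrame:
    """Per-block CR% and pre-CR% over valid (non-discarded) trials.

    Blocks with zero valid trials get NaN percentages and ``undefined=True``.
    """
    rows = []
    for bid, sub in trial_df.groupby("block_id"):
        valid = sub["label"] != "discarded"
        n_valid = int(valid.sum())
        cr_pct = 100.0 * (sub.loc[valid, "label"] == "CR").sum() / n_valid if n_valid else np.nan
        pv = sub["pre_cr_label"] != "discarded"
        n_pv = int(pv.sum())
        pre_pct = 100.0 * (sub.loc[pv, "pre_cr_label"] == "CR").sum() / n_pv if n_pv else np.nan
        rows.append((bid, len(sub), n_valid, cr_pct, pre_pct, n_valid == 0))
    return pd.DataFrame(rows, columns=[
        "block_id", "n_trials", "n_valid", "cr_percent", "pre_cr_percent", "undefined"])
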