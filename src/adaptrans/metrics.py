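"""Evaluation statistics for neural response fitting.

PSTH, raw Pearson correlation (CC_raw), trial-based signal power (SP), the
noise-ceiling-normalized correlation (CC_norm) and its ceiling (CC_max), and
Welch coherence between prediction and response with a split-half upper
bound.  Conventions:

- metrics are computed over the temporal dimension of the *concatenated*
  evaluation set (concatenate clips first, then evaluate);
- with a single trial, CC_norm falls back to CC_raw (a conservative lower
  bound: the recording is treated as noise-free);
- SP is an unbiased but noisy estimator and can be negative on small-N data;
  in that case the normalized metrics are reported as NaN rather than
  silently clipped.

All variances/covariances use the unbiased (N-1) normalization consistently,
so the identity CC_norm * CC_max = CC_raw holds exactly wherever all three
are defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import coherence as _welch_coherence

from .data import split_half_partitions

__all__ = [
    "psth",
    "cc_raw",
    "signal_power",
    "cc_norm",
    "cc_max",
    "coherence",
    "coherence_upper_bound",
    "CoherenceCurve",
    "concatenate_clips",
    "evaluate_predictions",
]


def psth(trials) -> np.ndarray:
    """Trial-averaged response: r = (1/N) sum_n r_n."""
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if trials.size == 0:
        raise ValueError("no trials")
    return trials.mean(axis=0)


def cc_raw(r, r_hat) -> float:
    """Pearson correlation over time between PSTH and prediction.

    Returns NaN if either series has zero variance.
    """
    r = np.asarray(r, dtype=float)
    r_hat = np.asarray(r_hat, dtype=float)
    if r.shape != r_hat.shape:
        raise ValueError("series must have equal length")
    vr, vh = r.var(ddof=1), r_hat.var(ddof=1)
    if vr <= 0 or vh <= 0:
        return float("nan")
    cov = np.cov(r, r_hat, ddof=1)[0, 1]
    return float(cov / np.sqrt(vr * vh))


def signal_power(trials) -> float:
    """Stimulus-locked (repeatable) response variance, estimated from trials:

        SP = [Var(sum_n r_n) - sum_n Var(r_n)] / (N (N-1))

    Unbiased for Var(signal) under independent additive trial noise; can be
    negative by chance for noisy, small-N data.  Requires N >= 2 (returns NaN
    for a single trial, triggering the single-trial fallback downstream).
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    N = trials.shape[0]
    if N < 2:
        return float("nan")
    total = trials.sum(axis=0)
    return float((total.var(ddof=1) - trials.var(axis=1, ddof=1).sum())
                 / (N * (N - 1)))


def cc_norm(r, r_hat, trials) -> float:
    """Noise-corrected correlation: Cov(r, r_hat) / sqrt(SP * Var(r_hat)).

    With one trial returns cc_raw; with non-positive SP returns NaN.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if trials.shape[0] < 2:
        return cc_raw(r, r_hat)
    sp = signal_power(trials)
    r = np.asarray(r, dtype=float)
    r_hat = np.asarray(r_hat, dtype=float)
    vh = r_hat.var(ddof=1)
    if not np.isfinite(sp) or sp <= 0:
        warnings.warn("non-positive signal-power estimate; normalized "
                      "correlation is undefined for this unit", RuntimeWarning,
                      stacklevel=2)
        return float("nan")
    if vh <= 0:
        return float("nan")
    cov = np.cov(r, r_hat, ddof=1)[0, 1]
    return float(cov / np.sqrt(sp * vh))


def cc_max(r, trials) -> float:
    """Noise ceiling sqrt(SP / Var(r)), clipped to [0, 1].

    cc_norm = cc_raw / cc_max wherever all quantities are defined.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if trials.shape[0] < 2:
        return float("nan")
    sp = signal_power(trials)
    vr = np.asarray(r, dtype=float).var(ddof=1)
    if not np.isfinite(sp) or sp <= 0 or vr <= 0:
        return float("nan")
    return float(np.clip(np.sqrt(sp / vr), 0.0, 1.0))


@dataclass
class CoherenceCurve:
    """Frequency-resolved squared correlation in [0, 1] (optionally with an
    upper bound on the same grid)."""

    frequencies: np.ndarray
    coherence: np.ndarray
    upper_bound: np.ndarray | None = None


# Welch settings: 500 ms segments (long-range temporal context), Hann window,
# 50% overlap.
COHERENCE_SEGMENT_S = 0.5


def _welch_args(dt, n_samples, segment_s):
    nperseg = int(round(segment_s / dt))
    if n_samples < nperseg:
        raise ValueError(
            f"series too short for coherence: need >= {nperseg} samples "
            f"({segment_s} s at dt={dt}), got {n_samples}")
    return dict(fs=1.0 / dt, nperseg=nperseg, noverlap=nperseg // 2,
                window="hann")


def coherence(r, r_hat, dt, segment_s=COHERENCE_SEGMENT_S) -> CoherenceCurve:
    """Welch magnitude-squared coherence between response and prediction."""
    r = np.asarray(r, dtype=float)
    r_hat = np.asarray(r_hat, dtype=float)
    f, c = _welch_coherence(r, r_hat, **_welch_args(dt, len(r), segment_s))
    return CoherenceCurve(frequencies=f, coherence=np.clip(c, 0.0, 1.0))


def coherence_upper_bound(trials, dt, segment_s=COHERENCE_SEGMENT_S,
                          max_splits=126) -> CoherenceCurve:
    """Split-half coherence ceiling: average coherence between half-trial
    PSTHs over up to ``max_splits`` deterministic partitions.

    With a single trial the worst-case bound of 1 at all frequencies is
    returned (no overestimation of model performance possible).
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    N, T = trials.shape
    args = _welch_args(dt, T, segment_s)
    if N < 2:
        f = np.fft.rfftfreq(args["nperseg"], d=dt)
        return CoherenceCurve(frequencies=f, coherence=np.ones_like(f))
    curves = []
    f = None
    for half_a, half_b in split_half_partitions(N, cap=max_splits):
        ra = trials[list(half_a)].mean(axis=0)
        rb = trials[list(half_b)].mean(axis=0)
        f, c = _welch_coherence(ra, rb, **args)
        curves.append(c)
    mean = np.clip(np.mean(curves, axis=0), 0.0, 1.0)
    return CoherenceCurve(frequencies=f, coherence=mean)


def concatenate_clips(clips, predictions):
    """Concatenate per-clip PSTHs, predictions and trials along time.

    Trials are concatenated per repeat index; clips with fewer repeats than
    the maximum have their available trials cycled to fill the matrix (only
    the PSTH and trial-noise structure matter for the metrics).
    """
    rs = [psth(c.trials) for c in clips]
    r = np.concatenate(rs)
    r_hat = np.concatenate([np.asarray(p, dtype=float) for p in predictions])
    n_max = max(c.n_trials for c in clips)
    blocks = []
    for c in clips:
        reps = np.resize(np.arange(c.n_trials), n_max)
        blocks.append(c.trials[reps])
    trials = np.concatenate(blocks, axis=1)
    return r, r_hat, trials


def evaluate_predictions(clips, predictions, dt=None) -> dict:
    """All scalar metrics for a set of clips and matching predictions."""
    r, r_hat, trials = concatenate_clips(clips, predictions)
    return {
        "cc_raw": cc_raw(r, r_hat),
        "cc_norm": cc_norm(r, r_hat, trials),
        "cc_max": cc_max(r, trials),
        "n_trials": int(trials.shape[0]),
        "n_bins": int(len(r)),
    }
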