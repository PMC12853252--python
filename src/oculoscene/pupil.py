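"""Pupillometry preprocessing: masking, interpolation, smoothing, epoching,
rejection, block-wise z-normalization, and condition averaging.

The processing order is fixed: missing data are masked (gaze away from
fixation, eye closures padded by 250 ms), recovered by shape-preserving
piecewise cubic interpolation, smoothed with a 150 ms Hann window, epoched
(sequence-evoked: -1..10 s around scene onset; change-locked: -0.5..2.5 s
around change time), rejected on the pre-interpolation missing fraction and
on outlying samples, and z-scored against pooled per-block, per-condition
baseline samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator

FIXATION_RADIUS_PX = 100.0
CLOSURE_PAD_MS = 250.0
SMOOTH_WINDOW_MS = 150.0

SEQUENCE_WINDOW_S = (-1.0, 10.0)
CHANGE_WINDOW_S = (-0.5, 2.5)
SEQUENCE_BASELINE_S = (-1.0, 0.0)
CHANGE_BASELINE_S = (-0.5, 0.0)

MISSING_MAX_FRACTION = 0.5      # strictly greater -> rejected
OUTLIER_FRACTION = 0.10         # >= this fraction of outlying samples -> rejected
OUTLIER_SD = 3.0                # strictly beyond -> outlying


def closure_intervals(valid: np.ndarray) -> list:
    """(start, end) sample-index pairs of runs where the eye is not tracked."""
    v = np.asarray(valid, dtype=bool)
    if v.all():
        return []
    edges = np.diff((~v).astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if not v[0]:
        starts.insert(0, 0)
    if not v[-1]:
        ends.append(v.size)
    return list(zip(starts, ends))


def mask_missing(gaze_x: np.ndarray, gaze_y: np.ndarray, valid: np.ndarray,
                 fixation_center_px: tuple, radius_px: float = FIXATION_RADIUS_PX,
                 pad_ms: float = CLOSURE_PAD_MS, fs_hz: int = 1000) -> np.ndarray:
    """Boolean missing mask for one eye.

    A sample is missing when gaze is strictly outside ``radius_px`` of the
    fixation cross, or when it falls inside an eye-closure interval extended
    by ``pad_ms`` on both sides (blink-edge artifacts).
    """
    cx, cy = fixation_center_px
    dist = np.hypot(np.asarray(gaze_x) - cx, np.asarray(gaze_y) - cy)
    missing = dist > radius_px
    pad = int(round(pad_ms * fs_hz / 1000.0))
    n = missing.size
    for a, b in closure_intervals(valid):
        missing[max(0, a - pad):min(n, b + pad)] = True
    return missing


def interpolate_missing(values: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Fill missing spans by shape-preserving piecewise cubic interpolation.

    Interior gaps are recovered with a monotonicity-preserving cubic (PCHIP:
    no overshoot beyond neighboring samples); leading/trailing gaps hold the
    nearest valid value.
    """
    x = np.asarray(values, dtype=float).copy()
    missing = np.asarray(missing, dtype=bool)
    good = np.flatnonzero(~missing)
    if good.size < 2:
        raise ValueError("fewer than 2 valid samples; cannot interpolate")
    if good.size == x.size:
        return x
    interp = PchipInterpolator(good, x[good])
    bad = np.flatnonzero(missing)
    interior = bad[(bad > good[0]) & (bad < good[-1])]
    x[interior] = interp(interior)
    x[: good[0]] = x[good[0]]
    x[good[-1] + 1:] = x[good[-1]]
    return x


def smooth(values: np.ndarray, window_ms: float = SMOOTH_WINDOW_MS,
           fs_hz: int = 1000) -> np.ndarray:
    """Zero-phase smoothing with a unit-area Hann window (reflected edges)."""
    x = np.asarray(values, dtype=float)
    n_win = int(round(window_ms * fs_hz / 1000.0))
    if n_win % 2 == 0:
        n_win += 1
    w = np.hanning(n_win)
    w = w / w.sum()
    half = n_win // 2
    if x.size <= half:
        raise ValueError("trace shorter than half the smoothing window")
    xp = np.pad(x, half, mode="reflect")
    return np.convolve(xp, w, mode="valid")


def extract_epochs(signal: np.ndarray, missing: np.ndarray,
                   event_times_ms: np.ndarray, window_s: tuple,
                   fs_hz: int = 1000):
    """Cut epochs around events.

    Returns ``(data, miss, time_s, kept_events)``; events whose window falls
    outside the trace are skipped.
    """
    lo = int(round(window_s[0] * fs_hz))
    hi = int(round(window_s[1] * fs_hz))
    t = np.arange(lo, hi) / fs_hz
    rows, miss_rows, kept = [], [], []
    for k, ev in enumerate(np.atleast_1d(event_times_ms)):
        i = int(round(ev * fs_hz / 1000.0))
        a, b = i + lo, i + hi
        if a < 0 or b > signal.size:
            continue
        rows.append(signal[a:b])
        miss_rows.append(missing[a:b])
        kept.append(k)
    data = np.asarray(rows) if rows else np.empty((0, t.size))
    miss = np.asarray(miss_rows) if miss_rows else np.empty((0, t.size), dtype=bool)
    return data, miss, t, np.asarray(kept, dtype=int)


@dataclass
class EpochSet:
    """Epoched (and optionally normalized) pupil data for one condition."""

    data: np.ndarray            # surviving epochs x time
    time_s: np.ndarray
    condition: str
    baseline_window_s: tuple
    n_rejected: int
    kept: np.ndarray            # indices into the input epochs
    blocks: Optional[np.ndarray] = None   # block label per surviving epoch


def epoch_and_reject(data: np.ndarray, missing: np.ndarray, time_s: np.ndarray,
                     condition: str = "", baseline_window_s: tuple = SEQUENCE_BASELINE_S,
                     blocks: Optional[np.ndarray] = None,
                     missing_max: float = MISSING_MAX_FRACTION,
                     outlier_fraction: float = OUTLIER_FRACTION,
                     outlier_sd: float = OUTLIER_SD) -> EpochSet:
    """Reject epochs with too much missing data or too many outlying samples.

    Missing fractions use the pre-interpolation mask (strictly >50%
    rejects).  Outliers are samples deviating strictly more than 3 SD from
    the per-time-point condition mean (computed once, from the epochs that
    survive the missing criterion); an epoch is rejected when >=10% of its
    samples are outlying.
    """
    n_in = data.shape[0]
    miss_frac = missing.mean(axis=1) if n_in else np.array([])
    keep = miss_frac <= missing_max
    surv = data[keep]
    if surv.shape[0] >= 2:
        mu = surv.mean(axis=0)
        sd = surv.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        out_frac = (np.abs(data - mu) > outlier_sd * sd).mean(axis=1)
        keep = keep & (out_frac < outlier_fraction)
    kept = np.flatnonzero(keep)
    return EpochSet(data=data[kept], time_s=time_s, condition=condition,
                    baseline_window_s=baseline_window_s,
                    n_rejected=int(n_in - kept.size), kept=kept,
                    blocks=None if blocks is None else np.asarray(blocks)[kept])


def znormalize(epochs: EpochSet) -> EpochSet:
    """Z-score epochs against pooled baseline samples per block (per condition).

    The mean and SD across *all* baseline samples of this condition within
    each block define the transform for that block's epochs.  Blocks whose
    pooled baseline SD is zero have their epochs dropped.
    """
    lo, hi = epochs.baseline_window_s
    sel = (epochs.time_s >= lo) & (epochs.time_s < hi)
    if not np.any(sel):
        raise ValueError("baseline window outside the epoch")
    blocks = epochs.blocks
    if blocks is None:
        blocks = np.zeros(epochs.data.shape[0], dtype=int)
    out = np.empty_like(epochs.data)
    keep = np.ones(epochs.data.shape[0], dtype=bool)
    for b in np.unique(blocks):
        rows = blocks == b
        base = epochs.data[rows][:, sel]
        mu, sd = base.mean(), base.std(ddof=0)
        if sd == 0:
            keep[rows] = False
            continue
        out[rows] = (epochs.data[rows] - mu) / sd
    n_dropped = int((~keep).sum())
    return EpochSet(data=out[keep], time_s=epochs.time_s, condition=epochs.condition,
                    baseline_window_s=epochs.baseline_window_s,
                    n_rejected=epochs.n_rejected + n_dropped,
                    kept=epochs.kept[keep],
                    blocks=None if epochs.blocks is None else np.asarray(blocks)[keep])


def average_condition(epochs: EpochSet):
    """Per-time-point mean and SEM across epochs (one series per condition)."""
    if epochs.data.shape[0] < 1:
        raise ValueError("no surviving epochs to average")
    mean = epochs.data.mean(axis=0)
    n = epochs.data.shape[0]
    sem = epochs.data.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return mean, sem
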