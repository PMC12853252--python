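"""Binocular microsaccade detection and rate estimation.

An Engbert–Kliegl-style velocity detector: gaze velocity from a 5-sample
moving difference, per-axis thresholds at lambda = 6 median-based standard
deviations computed over the whole block, candidate events as maximal
above-threshold runs lasting 5–100 ms, binocular pairing with onset
disparity < 10 ms, and a 50 ms refractory sweep.  Eye-closure intervals are
treated as missing and never interpolated; runs touching missing data are
discarded.  Rates reuse the causal-kernel estimator from :mod:`.pdr`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import pdr

LAMBDA = 6.0
MIN_DURATION_MS = 5.0
MAX_DURATION_MS = 100.0
MAX_DISPARITY_MS = 10.0
REFRACTORY_MS = 50.0

SEQUENCE_WINDOW_S = (-0.5, 10.0)
CHANGE_WINDOW_S = (-0.15, 2.5)
SEQUENCE_BASELINE_S = (-0.5, 0.0)
CHANGE_BASELINE_S = (-0.15, 0.0)
ROI_WINDOW_S = (0.100, 0.250)   # typical MSI latency window; effects outside
                                # it are reported as exploratory


def gaze_velocity(pos: np.ndarray, fs_hz: int = 1000) -> np.ndarray:
    """5-sample centered moving-difference velocity (units/s).

    v_t = (x_{t+2} + x_{t+1} - x_{t-1} - x_{t-2}) * fs / 6; the two samples
    at each edge are NaN.
    """
    x = np.asarray(pos, dtype=float)
    v = np.full(x.size, np.nan)
    if x.size >= 5:
        v[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) * fs_hz / 6.0
    return v


def median_sd(v: np.ndarray) -> float:
    """Median-based standard deviation: sqrt(median(v^2) - median(v)^2)."""
    v = v[~np.isnan(v)]
    var = np.median(v ** 2) - np.median(v) ** 2
    return float(np.sqrt(max(var, 0.0)))


@dataclass
class VelocityThresholds:
    eta_x: float
    eta_y: float
    lam: float = LAMBDA


def velocity_threshold(vx: np.ndarray, vy: np.ndarray,
                       lam: float = LAMBDA) -> VelocityThresholds:
    """Per-axis elliptic thresholds over a block's velocity series."""
    sx, sy = median_sd(vx), median_sd(vy)
    if sx == 0 or sy == 0:
        raise ValueError("degenerate (flat) velocity trace; thresholds undefined")
    return VelocityThresholds(eta_x=lam * sx, eta_y=lam * sy, lam=lam)


def above_threshold(vx: np.ndarray, vy: np.ndarray,
                    thr: VelocityThresholds) -> np.ndarray:
    """Elliptic criterion: (vx/eta_x)^2 + (vy/eta_y)^2 > 1 (strict)."""
    with np.errstate(invalid="ignore"):
        r = (vx / thr.eta_x) ** 2 + (vy / thr.eta_y) ** 2
    out = r > 1.0
    out[np.isnan(r)] = False
    return out


def _runs(mask: np.ndarray):
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    edges = np.diff(m.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(m.size)
    return list(zip(starts, ends))


def detect_monocular(vx: np.ndarray, vy: np.ndarray, thr: VelocityThresholds,
                     x: np.ndarray, y: np.ndarray,
                     missing: Optional[np.ndarray] = None,
                     fs_hz: int = 1000,
                     min_duration_ms: float = MIN_DURATION_MS,
                     max_duration_ms: float = MAX_DURATION_MS) -> pd.DataFrame:
    """Monocular candidates: maximal above-threshold runs of 5–100 ms.

    Runs that contain or abut missing samples are discarded (closures are
    excluded, not interpolated).  Returns onset/offset sample indices, peak
    velocity and start-to-end amplitude.
    """
    above = above_threshold(vx, vy, thr)
    if missing is not None:
        missing = np.asarray(missing, dtype=bool)
    n_min = int(round(min_duration_ms * fs_hz / 1000.0))
    n_max = int(round(max_duration_ms * fs_hz / 1000.0))
    rows = []
    for a, b in _runs(above):
        if not (n_min <= b - a <= n_max):
            continue
        if missing is not None and missing[max(0, a - 1):min(missing.size, b + 1)].any():
            continue
        speed = np.hypot(vx[a:b], vy[a:b])
        rows.append(dict(onset=a, offset=b,
                         peak_velocity=float(np.max(speed)),
                         amplitude=float(np.hypot(x[b - 1] - x[a], y[b - 1] - y[a]))))
    return pd.DataFrame(rows, columns=["onset", "offset", "peak_velocity", "amplitude"])


@dataclass
class MsEvent:
    """A binocular microsaccade (times in samples on the block clock)."""

    onset: int              # paired onset: the earlier of the two eyes
    onset_left: int
    onset_right: int
    offset_left: int
    offset_right: int
    disparity_ms: float
    peak_velocity: float    # mean of eyes
    amplitude: float        # mean of eyes


def pair_binocular(left: pd.DataFrame, right: pd.DataFrame,
                   max_disparity_ms: float = MAX_DISPARITY_MS,
                   fs_hz: int = 1000) -> list:
    """Greedy nearest-onset matching of monocular candidates.

    Candidate pairs are considered in order of increasing onset disparity;
    a pair is accepted when both events are unused and |disparity| is
    strictly below the bound.  Unmatched candidates are dropped.
    """
    if len(left) == 0 or len(right) == 0:
        return []
    max_disp = max_disparity_ms * fs_hz / 1000.0
    pairs = []
    for i, li in enumerate(left.onset.to_numpy()):
        for j, rj in enumerate(right.onset.to_numpy()):
            d = abs(int(li) - int(rj))
            if d < max_disp:
                pairs.append((d, i, j))
    pairs.sort()
    used_l, used_r = set(), set()
    events = []
    for d, i, j in pairs:
        if i in used_l or j in used_r:
            continue
        used_l.add(i)
        used_r.add(j)
        le, re = left.iloc[i], right.iloc[j]
        events.append(MsEvent(
            onset=int(min(le.onset, re.onset)),
            onset_left=int(le.onset), onset_right=int(re.onset),
            offset_left=int(le.offset), offset_right=int(re.offset),
            disparity_ms=d * 1000.0 / fs_hz,
            peak_velocity=float((le.peak_velocity + re.peak_velocity) / 2.0),
            amplitude=float((le.amplitude + re.amplitude) / 2.0)))
    events.sort(key=lambda e: e.onset)
    return events


def enforce_refractory(events: list, min_interval_ms: float = REFRACTORY_MS,
                       fs_hz: int = 1000) -> list:
    """Keep an event only if its onset is strictly more than 50 ms after the
    last kept onset (the first event is always kept)."""
    min_gap = min_interval_ms * fs_hz / 1000.0
    kept = []
    last = -np.inf
    for e in sorted(events, key=lambda e: e.onset):
        if e.onset - last > min_gap:
            kept.append(e)
            last = e.onset
    return kept


def detect_block(xl, yl, xr, yr, missing_left=None, missing_right=None,
                 fs_hz: int = 1000, lam: float = LAMBDA) -> list:
    """Full chain on one block: velocity, thresholds, monocular runs,
    binocular pairing, refractory sweep."""
    vxl, vyl = gaze_velocity(xl, fs_hz), gaze_velocity(yl, fs_hz)
    vxr, vyr = gaze_velocity(xr, fs_hz), gaze_velocity(yr, fs_hz)
    if missing_left is not None:
        vxl, vyl = vxl.copy(), vyl.copy()
        vxl[missing_left] = np.nan
        vyl[missing_left] = np.nan
    if missing_right is not None:
        vxr, vyr = vxr.copy(), vyr.copy()
        vxr[missing_right] = np.nan
        vyr[missing_right] = np.nan
    thr_l = velocity_threshold(vxl, vyl, lam)
    thr_r = velocity_threshold(vxr, vyr, lam)
    left = detect_monocular(vxl, vyl, thr_l, xl, yl, missing_left, fs_hz)
    right = detect_monocular(vxr, vyr, thr_r, xr, yr, missing_right, fs_hz)
    return enforce_refractory(pair_binocular(left, right, fs_hz=fs_hz), fs_hz=fs_hz)


def events_table(events: list, fs_hz: int = 1000) -> pd.DataFrame:
    rows = [dict(onset_s=e.onset / fs_hz,
                 duration_ms=(max(e.offset_left - e.onset_left,
                                  e.offset_right - e.onset_right)) * 1000.0 / fs_hz,
                 amplitude_px=e.amplitude, peak_velocity=e.peak_velocity,
                 disparity_ms=e.disparity_ms) for e in events]
    return pd.DataFrame(rows, columns=["onset_s", "duration_ms", "amplitude_px",
                                       "peak_velocity", "disparity_ms"])


def ms_rate(event_onsets_s: list, epoch_starts_s: np.ndarray, window_s: tuple,
            kernel: pdr.CausalKernel, baseline_window_s: tuple,
            epoch_missing_frac: Optional[np.ndarray] = None,
            condition: str = "", participant: str = "") -> pdr.RateSeries:
    """Microsaccade rate: unit pulses at binocular onsets through the causal
    kernel estimator (same normalization, baseline correction and peak-
    latency shift as the pupil dilation rate).

    ``event_onsets_s`` holds block-clock onset times; ``epoch_starts_s`` are
    the lock-event times of the epochs (one per trial).  Epochs with more
    than 50% missing data should be excluded upstream via
    ``epoch_missing_frac``.
    """
    onsets = np.asarray(event_onsets_s, dtype=float)
    t0, t1 = window_s
    trains = []
    for k, ev in enumerate(np.atleast_1d(epoch_starts_s)):
        if epoch_missing_frac is not None and epoch_missing_frac[k] > 0.5:
            continue
        rel = onsets[(onsets >= ev + t0) & (onsets < ev + t1)] - ev
        trains.append(np.sort(rel))
    if not trains:
        raise ValueError("no usable epochs for rate estimation")
    train = pdr.EventTrain(trials=trains, t_start_s=t0, duration_s=t1 - t0,
                           fs_hz=kernel.fs_hz)
    return pdr.event_rate(train, kernel, baseline_window_s=baseline_window_s,
                          condition=condition, participant=participant)
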