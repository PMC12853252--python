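"""Pupil dilation rate (PDR): event extraction and causal-kernel rate estimation.

Dilation events are strict local minima of the smoothed pupil trace that are
followed by continuous (non-decreasing) dilation for at least 100 ms.  Event
trains — here and for microsaccades — are represented as unit pulses,
averaged across trials, and convolved with the causal kernel

    w(tau) = alpha^2 * tau * exp(-alpha * tau),   tau >= 0,

an Erlang(2) window borrowed from spike-train firing-rate estimation, with
time constant 1/alpha = 150 ms.  The kernel peaks at tau = 1/alpha, so the
rate time axis is shifted left by that peak latency to compensate the
smoothing delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

DEFAULT_ALPHA_MS = 150.0
DEFAULT_MIN_DILATION_MS = 100.0


@dataclass
class EventTrain:
    """Point events (one array of onset times per trial) on a common epoch."""

    trials: list                 # list of sorted 1-D arrays, times in s on the epoch axis
    t_start_s: float             # epoch start relative to the lock event
    duration_s: float
    fs_hz: int = 1000

    def __post_init__(self):
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]
        t_end = self.t_start_s + self.duration_s
        for tr in self.trials:
            if tr.size and (np.any(np.diff(tr) <= 0)):
                raise ValueError("per-trial event times must be strictly increasing")
            if tr.size and (tr[0] < self.t_start_s - 1e-9 or tr[-1] >= t_end + 1e-9):
                raise ValueError("event outside epoch bounds")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))


@dataclass
class RateSeries:
    """Trial-normalized, kernel-smoothed, baseline-corrected rate (events/s)."""

    time_s: np.ndarray
    rate_hz: np.ndarray
    baseline_window_s: Optional[tuple] = None
    condition: str = ""
    participant: str = ""


@dataclass
class CausalKernel:
    weights: np.ndarray     # discretized, truncated, renormalized to sum 1
    fs_hz: int
    alpha_ms: float

    @property
    def peak_lag_s(self) -> float:
        return float(np.argmax(self.weights)) / self.fs_hz


def causal_kernel(fs_hz: int, alpha_ms: float = DEFAULT_ALPHA_MS,
                  cutoff: float = 1e-6) -> CausalKernel:
    """Discretize w(tau) = alpha^2 tau exp(-alpha tau) at ``fs_hz``.

    Truncated where the tail falls below ``cutoff`` times the maximum and
    renormalized to unit sum, so convolving a rate signal preserves its mean.
    """
    alpha = 1000.0 / alpha_ms          # s^-1
    # generous support: the tail is negligible beyond ~30 time constants
    n = int(np.ceil(30.0 / alpha * fs_hz)) + 1
    tau = np.arange(n) / fs_hz
    w = alpha ** 2 * tau * np.exp(-alpha * tau)
    keep = np.flatnonzero(w >= cutoff * w.max())
    w = w[: keep[-1] + 1]
    w = w / w.sum()
    return CausalKernel(weights=w, fs_hz=fs_hz, alpha_ms=alpha_ms)


def detect_dilation_events(pupil: np.ndarray, fs_hz: int = 1000,
                           min_dilation_ms: float = DEFAULT_MIN_DILATION_MS) -> np.ndarray:
    """Sample indices of dilation onsets in a smoothed, gap-free trace.

    An onset is a strict local minimum (plateaus credit their first sample)
    followed by a non-decreasing trace for the full ``min_dilation_ms``
    window; minima too close to the end to verify the window are not events.
    """
    x = np.asarray(pupil, dtype=float)
    n = x.size
    min_run = int(round(min_dilation_ms * fs_hz / 1000.0))
    if n < min_run + 2:
        return np.array([], dtype=int)
    d = np.diff(x)

    # length of the non-decreasing run of diffs starting at each index
    dec = np.flatnonzero(d < 0)
    next_dec = np.full(n - 1, n - 1)
    if dec.size:
        pos = np.searchsorted(dec, np.arange(n - 1))
        has = pos < dec.size
        next_dec[has] = dec[pos[has]]
    run_len = next_dec - np.arange(n - 1)
    run_len[d < 0] = 0

    # strict drop into the sample (also makes it the first sample of a plateau)
    prev_ok = np.zeros(n, dtype=bool)
    prev_ok[1:] = d < 0

    # the next value that differs must be larger (true local minimum)
    nz = np.flatnonzero(d != 0)
    next_ok = np.zeros(n, dtype=bool)
    if nz.size:
        pos = np.searchsorted(nz, np.arange(n))
        has = pos < nz.size
        idx = np.arange(n)[has]
        next_ok[idx] = d[nz[pos[has]]] > 0

    cand = prev_ok & next_ok
    cand[: 1] = False
    ok = np.zeros(n, dtype=bool)
    valid_span = np.arange(n) + min_run <= n - 1
    t = np.flatnonzero(cand & valid_span)
    ok_t = run_len[t] >= min_run
    return t[ok_t]


def event_rate(train: EventTrain, kernel: CausalKernel,
               baseline_window_s: Optional[tuple] = None,
               condition: str = "", participant: str = "") -> RateSeries:
    """Kernel-smoothed event rate in events/s.

    Per-trial unit-pulse trains are summed, normalized by the number of
    trials and the sampling interval, causally convolved with the kernel,
    baseline-corrected (mean over ``baseline_window_s`` on the shifted axis),
    and the time axis is shifted left by the kernel's peak latency.
    """
    if train.n_trials == 0:
        raise ValueError("event rate undefined for zero trials")
    if kernel.fs_hz != train.fs_hz:
        raise ValueError("kernel and train sampling rates differ")
    fs = train.fs_hz
    n = train.n_samples
    counts = np.zeros(n)
    for tr in train.trials:
        idx = np.round((tr - train.t_start_s) * fs).astype(int)
        idx = idx[(idx >= 0) & (idx < n)]
        np.add.at(counts, idx, 1.0)
    pulse_rate = counts / train.n_trials * fs          # events per second
    rate = np.convolve(pulse_rate, kernel.weights)[:n]
    time_s = train.t_start_s + np.arange(n) / fs - kernel.peak_lag_s
    if baseline_window_s is not None:
        lo, hi = baseline_window_s
        sel = (time_s >= lo) & (time_s < hi)
        if not np.any(sel):
            raise ValueError("baseline window outside epoch")
        rate = rate - rate[sel].mean()
    return RateSeries(time_s=time_s, rate_hz=rate,
                      baseline_window_s=baseline_window_s,
                      condition=condition, participant=participant)
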