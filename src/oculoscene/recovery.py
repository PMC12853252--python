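"""Parameter-recovery estimators for synthetic-session validation.

These estimators compare pipeline output against the generator's ground
truth.  They are allowed to know the generative model (e.g., the raised-
cosine shape of the injected microsaccadic-inhibition profile) because their
job is to measure how well an injected parameter is recovered from the
pipeline's detected events — they are not part of the blind analysis path.
"""

from __future__ import annotations

import numpy as np

from .pdr import RateSeries


def pooled_counts(trains: list, t_start_s: float, duration_s: float,
                  fs_hz: int = 1000) -> np.ndarray:
    """Per-millisecond event counts pooled over epochs."""
    n = int(round(duration_s * fs_hz))
    counts = np.zeros(n)
    for tr in trains:
        idx = np.round((np.asarray(tr) - t_start_s) * fs_hz).astype(int)
        idx = idx[(idx >= 0) & (idx < n)]
        np.add.at(counts, idx, 1.0)
    return counts


def fit_msi_latency(change_trains: list, control_trains: list,
                    t_start_s: float, duration_s: float, fs_hz: int = 1000,
                    halfwidth_ms: float = 100.0,
                    latency_grid_s=None, depth_grid=None):
    """Maximum-likelihood recovery of the injected inhibition latency.

    Fits an inhomogeneous-Poisson model r(t) = b (1 - d g(t - L)) — with g
    the generator's raised-cosine suppression profile — to the pooled
    per-millisecond counts of the change-locked epochs; the control epochs
    pin the base rate b.  Returns ``(latency_s, depth)``.
    """
    if latency_grid_s is None:
        latency_grid_s = np.arange(0.05, 0.5, 0.005)
    if depth_grid is None:
        depth_grid = np.arange(0.1, 1.0, 0.05)
    n = int(round(duration_s * fs_hz))
    t = t_start_s + np.arange(n) / fs_hz
    k_change = pooled_counts(change_trains, t_start_s, duration_s, fs_hz)
    k_control = pooled_counts(control_trains, t_start_s, duration_s, fs_hz)
    base = k_control.sum() / (len(control_trains) * duration_s)
    hw = halfwidth_ms / 1000.0
    best_ll, best = -np.inf, (np.nan, np.nan)
    n_trials = len(change_trains)
    for lat in latency_grid_s:
        u = (t - lat) / hw
        g = np.where(np.abs(u) < 1.0, 0.5 * (1.0 + np.cos(np.pi * u)), 0.0)
        for depth in depth_grid:
            lam = n_trials * base * (1.0 - depth * g) / fs_hz
            ll = float(np.sum(k_change * np.log(lam) - lam))
            if ll > best_ll:
                best_ll, best = ll, (float(lat), float(depth))
    return best


def null_calibration_run(rng: np.random.Generator, n_participants: int = 12,
                         n_trials: int = 32, decimate: int = 10,
                         floor_iter: int = 100, boot_iter: int = 1000,
                         params=None) -> bool:
    """One null-session calibration run of the guarded bootstrap procedure.

    Simulates no-change pupil trials with *no* condition effect for each
    participant, smooths and z-normalizes them, splits each participant's
    trials into two pseudo-conditions, and asks whether the surrogate-split
    noise floor (built from the same control trials) lets any spuriously
    significant interval through as "robust".  Returns True when a spurious
    robust effect is flagged.
    """
    from scipy.signal import oaconvolve

    from . import pupil as pup
    from . import stats as st
    from .synth import SynthParams, draw_traits, pupil_template

    params = SynthParams() if params is None else params
    fs = params.fs_hz
    t = np.arange(-1.0, 10.0, 1.0 / fs)
    n_win = int(round(pup.SMOOTH_WINDOW_MS * fs / 1000.0)) + 1
    w = np.hanning(n_win)
    w /= w.sum()

    diffs, controls = [], []
    for _ in range(n_participants):
        traits = draw_traits(params, rng)
        base = pupil_template(t, "RND", "NC", None, traits, params)
        phases = rng.uniform(0, 2 * np.pi, n_trials)
        osc = params.osc_amp * np.sin(
            2 * np.pi * params.osc_freq_hz * t[None, :] + phases[:, None])
        x = base[None, :] + osc + rng.normal(0, params.pupil_noise_sd,
                                             (n_trials, t.size))
        x = oaconvolve(np.pad(x, ((0, 0), (n_win // 2, n_win // 2)), mode="reflect"),
                       w[None, :], mode="valid", axes=1)
        eps = pup.EpochSet(data=x, time_s=t, condition="NC",
                           baseline_window_s=pup.SEQUENCE_BASELINE_S,
                           n_rejected=0, kept=np.arange(n_trials))
        eps = pup.znormalize(eps)
        z = eps.data[:, ::decimate]
        half = n_trials // 2
        perm = rng.permutation(n_trials)
        diffs.append(z[perm[:half]].mean(axis=0) - z[perm[half:]].mean(axis=0))
        controls.append(z)
    td = t[::decimate]
    observed = st.bootstrap_difference(np.asarray(diffs), td, n_iter=boot_iter, rng=rng)
    floor = st.noise_floor(controls, td, n_iter=floor_iter, boot_iter=boot_iter,
                           rng=rng)
    return len(st.robust_intervals(observed, floor)) > 0


def rate_trough(rate: RateSeries, window_s=(0.0, 0.5)) -> tuple:
    """(time, value) of the minimum of a rate series inside ``window_s``."""
    sel = (rate.time_s >= window_s[0]) & (rate.time_s <= window_s[1])
    i = int(np.argmin(rate.rate_hz[sel]))
    return float(rate.time_s[sel][i]), float(rate.rate_hz[sel][i])


def fit_divergence_onset(diff_mean: np.ndarray, time_s: np.ndarray,
                         common_mean=None, grid_s=None) -> float:
    """Least-squares hinge fit of a tonic divergence changepoint.

    Models the group-mean condition difference as
    a + c*m(t) + b*max(0, t - T0) and returns the best-fitting T0, where
    m(t) (``common_mean``) is the conditions' common response shape.  The
    m(t) regressor absorbs per-condition normalization-scale interference,
    which is proportional to the common template; the hinge is the
    generator's injected form.  Unlike the first-significant-time readout,
    this estimator is not biased late by the detection threshold.
    """
    d = np.asarray(diff_mean, dtype=float)
    t = np.asarray(time_s, dtype=float)
    cols = [np.ones_like(t)]
    if common_mean is not None:
        cols.append(np.asarray(common_mean, dtype=float))
    if grid_s is None:
        grid_s = np.arange(1.0, 6.0, 0.02)
    best_sse, best_t0 = np.inf, np.nan
    for t0 in grid_s:
        X = np.column_stack(cols + [np.clip(t - t0, 0.0, None)])
        beta, res, *_ = np.linalg.lstsq(X, d, rcond=None)
        sse = float(res[0]) if res.size else float(np.sum((d - X @ beta) ** 2))
        if sse < best_sse:
            best_sse, best_t0 = sse, float(t0)
    return best_t0


def tonic_onset_zero_crossing(diff_mean: np.ndarray, time_s: np.ndarray,
                              fit_window_s=(5.0, 9.0)) -> float:
    """Divergence onset by zero-crossing extrapolation of the late linear fit.

    The injected tonic divergence grows linearly after its onset, so a line
    fitted to the group-mean difference over the late window (where the
    signal dwarfs the noise) crosses zero at the onset.  Unbiased where the
    first-significant-time readout is late by the detection threshold.
    """
    d = np.asarray(diff_mean, dtype=float)
    t = np.asarray(time_s, dtype=float)
    sel = (t >= fit_window_s[0]) & (t <= fit_window_s[1])
    b, a = np.polyfit(t[sel], d[sel], 1)
    return float(-a / b)


def divergence_onset_from_mask(time_s: np.ndarray, sig_mask: np.ndarray) -> float:
    """Start time of the longest contiguous significant run (NaN if none)."""
    m = np.asarray(sig_mask, dtype=bool)
    if not m.any():
        return np.nan
    edges = np.diff(m.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(m.size)
    a, b = max(zip(starts, ends), key=lambda r: r[1] - r[0])
    return float(time_s[a])
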