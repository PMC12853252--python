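"""Microsaccade detection: velocity estimator, median-based thresholds,
run detection, binocular pairing, refractory sweep, and the full chain
against a brute-force oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oculoscene import microsaccades as ms

FS = 1000


class TestVelocity:
    def test_constant_position_gives_zero_velocity(self):
        v = ms.gaze_velocity(np.full(100, 3.0), FS)
        assert np.all(v[2:-2] == 0.0)
        assert np.isnan(v[:2]).all() and np.isnan(v[-2:]).all()

    def test_linear_motion_recovered_exactly(self):
        # 100 px/s ramp: plug the sequence into the 5-point formula
        x = 100.0 * np.arange(500) / FS
        v = ms.gaze_velocity(x, FS)
        assert np.allclose(v[2:-2], 100.0)

    def test_alternating_noise_attenuated_versus_two_point_difference(self):
        x = np.where(np.arange(1000) % 2 == 0, 1.0, -1.0)
        v5 = ms.gaze_velocity(x, FS)[2:-2]
        v2 = np.diff(x) * FS
        # the 5-point kernel nulls the Nyquist component entirely
        assert np.abs(v5).max() < 0.05 * np.abs(v2).max()


class TestThresholds:
    def test_median_based_sd_matches_gaussian_sd(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0.0, 37.0, 100_000)
        # median(v^2) = sigma^2 * median(chi2_1) -> correct with the constant
        est = ms.median_sd(v)
        chi2_med = 0.454936423119572  # median of chi-square(1)
        assert est / np.sqrt(chi2_med) == pytest.approx(37.0, rel=0.05)

    def test_exactly_on_threshold_is_not_above(self):
        thr = ms.VelocityThresholds(eta_x=10.0, eta_y=10.0)
        vx = np.array([10.0, 0.0, 7.1])
        vy = np.array([0.0, 10.0, 7.1])
        above = ms.above_threshold(vx, vy, thr)
        assert not above[0] and not above[1]
        assert above[2]    # sqrt(2)*7.1 exceeds the ellipse

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        vx = rng.normal(0, 5, 5000)
        vy = rng.normal(0, 5, 5000)
        vx[1000:1010] += 80
        t1 = ms.velocity_threshold(vx, vy)
        t2 = ms.velocity_threshold(2 * vx, 2 * vy)
        assert t2.eta_x == pytest.approx(2 * t1.eta_x)
        assert np.array_equal(ms.above_threshold(vx, vy, t1),
                              ms.above_threshold(2 * vx, 2 * vy, t2))

    def test_flat_trace_raises(self):
        with pytest.raises(ValueError):
            ms.velocity_threshold(np.zeros(100), np.zeros(100))


def _candidates(onsets, offsets):
    return pd.DataFrame(dict(onset=onsets, offset=offsets,
                             peak_velocity=1.0, amplitude=1.0))


class TestRunDetection:
    def _detect(self, above, missing=None):
        vx = np.where(above, 100.0, 0.0)
        vy = np.zeros_like(vx)
        thr = ms.VelocityThresholds(eta_x=10.0, eta_y=10.0)
        x = np.cumsum(vx) / FS
        return ms.detect_monocular(vx, vy, thr, x, np.zeros_like(x),
                                   missing, FS)

    def test_duration_bounds_inclusive(self):
        above = np.zeros(1000, bool)
        above[100:104] = True    # 4 ms -> rejected
        above[300:305] = True    # 5 ms -> kept
        above[500:600] = True    # 100 ms -> kept
        above[700:820] = True    # 120 ms -> rejected
        out = self._detect(above)
        assert out.onset.tolist() == [300, 500]

    def test_runs_touching_missing_data_are_dropped(self):
        above = np.zeros(1000, bool)
        above[100:120] = True
        above[300:320] = True
        missing = np.zeros(1000, bool)
        missing[120] = True      # abuts the first run
        out = self._detect(above, missing)
        assert out.onset.tolist() == [300]


class TestBinocularPairing:
    def test_identical_lists_pair_fully_with_zero_disparity(self):
        left = _candidates([100, 300, 500], [110, 315, 512])
        events = ms.pair_binocular(left, left.copy())
        assert len(events) == 3
        assert all(e.disparity_ms == 0.0 for e in events)

    def test_disparity_bound_is_strict(self):
        left = _candidates([100], [110])
        right = _candidates([112], [122])
        assert ms.pair_binocular(left, right) == []
        right = _candidates([109], [119])
        assert len(ms.pair_binocular(left, right)) == 1

    def test_paired_onset_is_the_earlier_eye(self):
        left = _candidates([105], [115])
        right = _candidates([100], [112])
        e = ms.pair_binocular(left, right)[0]
        assert e.onset == 100

    @given(st.integers(0, 2_000))
    @settings(max_examples=40, deadline=None)
    def test_greedy_matching_attains_optimal_cardinality(self, seed):
        # exhaustive matching oracle on small lists (<= 6 events per eye)
        rng = np.random.default_rng(seed)
        nl, nr = rng.integers(1, 6, 2)
        lo = np.sort(rng.choice(np.arange(0, 300, 3), nl, replace=False))
        ro = np.sort(rng.choice(np.arange(0, 300, 3), nr, replace=False))
        left = _candidates(lo, lo + 10)
        right = _candidates(ro, ro + 10)
        got = len(ms.pair_binocular(left, right))
        best = 0
        for k in range(min(nl, nr), 0, -1):
            for li in itertools.permutations(range(nl), k):
                for ri in itertools.combinations(range(nr), k):
                    if all(abs(int(lo[a]) - int(ro[b])) < 10
                           for a, b in zip(li, ri)):
                        best = k
                        break
                if best == k:
                    break
            if best == k:
                break
        assert got == best


class TestRefractory:
    def _events(self, onsets):
        return [ms.MsEvent(onset=o, onset_left=o, onset_right=o,
                           offset_left=o + 10, offset_right=o + 10,
                           disparity_ms=0.0, peak_velocity=1.0, amplitude=1.0)
                for o in onsets]

    def test_single_event_kept(self):
        assert len(ms.enforce_refractory(self._events([42]))) == 1

    def test_sweep_semantics(self):
        kept = ms.enforce_refractory(self._events([0, 30, 90]))
        assert [e.onset for e in kept] == [0, 90]

    def test_exactly_50_ms_apart_drops_the_second(self):
        kept = ms.enforce_refractory(self._events([0, 50]))
        assert [e.onset for e in kept] == [0]


def brute_force_chain(xl, yl, xr, yr, missing_l, missing_r, fs=FS):
    """Naive re-implementation of the full detection chain with plain loops."""
    def velocity(x):
        v = [np.nan, np.nan]
        for t in range(2, len(x) - 2):
            v.append((x[t + 2] + x[t + 1] - x[t - 1] - x[t - 2]) * fs / 6.0)
        v += [np.nan, np.nan]
        return np.array(v)

    def med_sd(v):
        v = v[~np.isnan(v)]
        return np.sqrt(max(np.median(v ** 2) - np.median(v) ** 2, 0.0))

    def monocular(x, y, miss):
        vx, vy = velocity(x), velocity(y)
        if miss is not None:
            vx[miss] = np.nan
            vy[miss] = np.nan
        ex, ey = 6 * med_sd(vx), 6 * med_sd(vy)
        above = []
        for t in range(len(x)):
            r = (vx[t] / ex) ** 2 + (vy[t] / ey) ** 2
            above.append(bool(r > 1.0) if not np.isnan(r) else False)
        runs, t = [], 0
        while t < len(above):
            if above[t]:
                u = t
                while u < len(above) and above[u]:
                    u += 1
                runs.append((t, u))
                t = u
            else:
                t += 1
        out = []
        for a, b in runs:
            if not (5 <= b - a <= 100):
                continue
            if miss is not None and miss[max(0, a - 1):min(len(x), b + 1)].any():
                continue
            out.append((a, b))
        return out

    L, R = monocular(xl, yl, missing_l), monocular(xr, yr, missing_r)
    pairs = sorted((abs(a[0] - b[0]), i, j) for i, a in enumerate(L)
                   for j, b in enumerate(R) if abs(a[0] - b[0]) < 10)
    used_l, used_r, events = set(), set(), []
    for d, i, j in pairs:
        if i in used_l or j in used_r:
            continue
        used_l.add(i)
        used_r.add(j)
        events.append(min(L[i][0], R[j][0]))
    events.sort()
    kept, last = [], -np.inf
    for o in events:
        if o - last > 50:
            kept.append(o)
            last = o
    return kept


def _random_trace(rng, n=1500):
    """Drift + noise + a few conjugate high-velocity steps."""
    def drift():
        return np.cumsum(rng.normal(0, 0.1, n))
    xl, yl = drift(), drift()
    xr, yr = xl + rng.normal(0, 0.05, n), yl + rng.normal(0, 0.05, n)
    for _ in range(rng.integers(0, 5)):
        o = rng.integers(10, n - 40)
        dur = rng.integers(6, 26)
        amp = rng.uniform(3, 25)
        phi = rng.uniform(0, 2 * np.pi)
        step = np.diff(0.5 * (1 - np.cos(np.pi * np.arange(dur + 1) / dur)))
        d = int(rng.integers(0, 5))
        for x, y, off in ((xl, yl, 0), (xr, yr, d)):
            x[o + off:o + off + dur] += np.cumsum(amp * np.cos(phi) * step)
            x[o + off + dur:] += amp * np.cos(phi)
            y[o + off:o + off + dur] += np.cumsum(amp * np.sin(phi) * step)
            y[o + off + dur:] += amp * np.sin(phi)
    missing = np.zeros(n, bool)
    if rng.random() < 0.3:
        a = rng.integers(0, n - 100)
        missing[a:a + rng.integers(20, 100)] = True
    return xl, yl, xr, yr, missing


class TestFullChain:
    def test_matches_brute_force_on_random_small_traces(self):
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(100):
            xl, yl, xr, yr, missing = _random_trace(rng)
            try:
                events = ms.detect_block(xl, yl, xr, yr, missing, missing)
            except ValueError:
                continue
            oracle = brute_force_chain(xl, yl, xr, yr, missing, missing)
            assert [e.onset for e in events] == oracle
            checked += 1
        assert checked > 90

    def test_invariant_to_offset_and_rotation(self):
        rng = np.random.default_rng(5)
        xl, yl, xr, yr, _ = _random_trace(rng)
        base = [e.onset for e in ms.detect_block(xl, yl, xr, yr)]
        shifted = [e.onset for e in ms.detect_block(xl + 500, yl - 200,
                                                    xr + 500, yr - 200)]
        rotated = [e.onset for e in ms.detect_block(-yl, xl, -yr, xr)]
        assert base == shifted == rotated

    def test_known_event_onset_recovered_within_crossing_delay(self):
        # a raised-cosine step first exceeds the 6-sigma threshold once its
        # velocity reaches 6/8 of its 8-sigma peak, i.e. asin(0.75)/pi of the
        # way through the event; the detected onset may lag true onset by
        # that much plus the 5-point estimator's 2-sample smear
        rng = np.random.default_rng(17)
        n, dur, onset = 4000, 15, 2000
        noise = 1.0
        xl = rng.normal(0, noise, n)
        yl = rng.normal(0, noise, n)
        vel_sd = noise * np.sqrt(4.0) / 6.0 * FS   # 5-point formula on white noise
        peak = 8 * 6 * vel_sd / np.sqrt(2)         # 8x the elliptic threshold
        amp = peak * 2 * (dur / FS) / np.pi
        step = np.diff(0.5 * (1 - np.cos(np.pi * np.arange(dur + 1) / dur)))
        for arr in (xl, yl):
            arr[onset:onset + dur] += np.cumsum(amp / np.sqrt(2) * step)
            arr[onset + dur:] += amp / np.sqrt(2)
        xr, yr = xl.copy(), yl.copy()
        events = ms.detect_block(xl, yl, xr, yr)
        near = [e for e in events if abs(e.onset - onset) < 30]
        assert len(near) == 1
        delay_bound = dur * np.arcsin(6 / 8) / np.pi + 2
        assert -3 <= near[0].onset - onset <= delay_bound + 1


class TestRateWrapper:
    def test_no_events_give_zero_baseline_corrected_rate(self):
        from oculoscene import pdr
        k = pdr.causal_kernel(FS)
        rs = ms.ms_rate([], np.array([5.0, 20.0]), ms.CHANGE_WINDOW_S, k,
                        ms.CHANGE_BASELINE_S)
        assert np.allclose(rs.rate_hz, 0.0)

    def test_poisson_events_recover_base_rate(self):
        from oculoscene import pdr
        rng = np.random.default_rng(3)
        k = pdr.causal_kernel(FS)
        lam = 1.5
        starts = np.arange(200) * 20.0 + 5.0
        onsets = []
        for s in starts:
            n = rng.poisson(lam * 12.0)
            onsets.extend(np.sort(rng.uniform(s - 2, s + 10, n)))
        rs = ms.ms_rate(sorted(onsets), starts, ms.SEQUENCE_WINDOW_S, k,
                        baseline_window_s=None)
        plateau = rs.rate_hz[(rs.time_s > 1.0) & (rs.time_s < 9.0)]
        assert plateau.mean() == pytest.approx(lam, rel=0.05)

    def test_epochs_with_majority_missing_are_excluded(self):
        from oculoscene import pdr
        k = pdr.causal_kernel(FS)
        with pytest.raises(ValueError):
            ms.ms_rate([1.0], np.array([5.0]), ms.CHANGE_WINDOW_S, k,
                       ms.CHANGE_BASELINE_S,
                       epoch_missing_frac=np.array([0.9]))
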