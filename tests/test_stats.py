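"""Bootstrap significance, surrogate-split noise floor, divergence latency,
effect sizes, behavior scoring, RT-pupil correlation."""

import numpy as np
import pandas as pd
import pytest

from oculoscene import stats


def _time(T, dt=0.01, t0=-0.5):
    return t0 + dt * np.arange(T)


class TestBootstrapDifference:
    def test_all_zero_differences_are_never_significant(self, rng):
        res = stats.bootstrap_difference(np.zeros((8, 200)), _time(200), rng=rng)
        assert not res.sig_mask.any()

    def test_constant_positive_difference_is_always_significant(self, rng):
        res = stats.bootstrap_difference(np.ones((8, 200)), _time(200), rng=rng)
        assert res.sig_mask.all()
        assert np.all(res.prop_consistent == 1.0)

    def test_reproducible_under_fixed_seed(self):
        d = np.random.default_rng(3).normal(0, 1, (10, 300))
        t = _time(300)
        a = stats.bootstrap_difference(d, t, rng=np.random.default_rng(11))
        b = stats.bootstrap_difference(d, t, rng=np.random.default_rng(11))
        assert np.array_equal(a.sig_mask, b.sig_mask)
        assert np.array_equal(a.prop_consistent, b.prop_consistent)

    def test_participant_order_invariance_for_clear_effects(self, rng):
        d = 1.0 + np.random.default_rng(4).normal(0, 0.1, (12, 100))
        t = _time(100)
        a = stats.bootstrap_difference(d, t, rng=np.random.default_rng(0))
        b = stats.bootstrap_difference(d[::-1], t, rng=np.random.default_rng(0))
        assert np.array_equal(a.sig_mask, b.sig_mask)

    def test_requires_two_participants(self, rng):
        with pytest.raises(ValueError):
            stats.bootstrap_difference(np.ones((1, 10)), _time(10), rng=rng)

    def test_pointwise_type_one_rate_under_the_null(self):
        # two one-sided 5% checks -> ~10% asymptotically, slightly higher at
        # small N; this property motivates the noise-floor guard
        rng = np.random.default_rng(0)
        d = rng.normal(0, 1, (32, 3000))
        res = stats.bootstrap_difference(d, _time(3000), rng=rng)
        assert 0.06 < res.sig_mask.mean() < 0.17

    def test_injected_late_divergence_onset_recovered(self):
        # REG-RND style: difference ramps down from 3 s; the longest
        # significant run must start within +-0.5 s of the injected onset
        rng = np.random.default_rng(8)
        t = np.arange(-1.0, 10.0, 0.01)
        ramp = np.clip(t - 3.0, 0, None) * -0.8
        d = ramp + rng.normal(0, 0.4, (16, t.size)) \
            + rng.normal(0, 0.1, (16, 1))
        res = stats.bootstrap_difference(d, t, rng=rng)
        from oculoscene.recovery import divergence_onset_from_mask
        onset = divergence_onset_from_mask(t, res.sig_mask)
        assert onset == pytest.approx(3.0, abs=0.5)


class TestNoiseFloor:
    def test_deterministic_identical_trials_give_zero_floor(self, rng):
        c = [np.tile(np.sin(_time(100)), (6, 1)) for _ in range(5)]
        floor = stats.noise_floor(c, _time(100), n_iter=20, boot_iter=200,
                                  rng=rng)
        assert floor.threshold_s == 0.0
        assert floor.is_robust(0.01)

    def test_iid_noise_floor_is_short_and_injected_effect_exceeds_it(self):
        rng = np.random.default_rng(9)
        t = _time(300)
        controls = [rng.normal(0, 1, (20, 300)) for _ in range(10)]
        floor = stats.noise_floor(controls, t, n_iter=60, boot_iter=400,
                                  rng=rng)
        assert floor.threshold_s < 0.5       # spurious runs are short
        assert floor.is_robust(1.0)          # a 1 s effect clears the floor

    def test_halving_trials_preserves_detection_of_a_strong_effect(self):
        rng = np.random.default_rng(10)
        t = _time(300)
        effect = np.where((t > 0.5) & (t < 1.5), 2.0, 0.0)

        def run(n_trials):
            diffs, controls = [], []
            for _ in range(10):
                a = effect + rng.normal(0, 1, (n_trials, t.size))
                b = rng.normal(0, 1, (n_trials, t.size))
                diffs.append(a.mean(0) - b.mean(0))
                controls.append(rng.normal(0, 1, (2 * n_trials, t.size)))
            obs = stats.bootstrap_difference(np.asarray(diffs), t,
                                             n_iter=400, rng=rng)
            floor = stats.noise_floor(controls, t, n_iter=40, boot_iter=400,
                                      rng=rng)
            return stats.robust_intervals(obs, floor)

        assert len(run(16)) > 0
        assert len(run(8)) > 0


class TestDivergenceLatency:
    def test_immediate_huge_effect_gives_first_sample_latency(self):
        rng = np.random.default_rng(1)
        t = _time(100)
        a = 10.0 + rng.normal(0, 0.01, (8, 100))
        b = rng.normal(0, 0.01, (8, 100))
        res = stats.divergence_latency(a, b, t, n_iter=50, boot_iter=200,
                                       rng=rng)
        first = t[t >= 0][0]
        assert np.all(res.latencies_s == first)
        assert res.missing_rate == 0.0

    def test_no_effect_gives_all_missing(self):
        rng = np.random.default_rng(2)
        t = _time(50)
        a = np.zeros((8, 50))
        res = stats.divergence_latency(a, a, t, n_iter=40, boot_iter=200,
                                       rng=rng)
        assert res.missing_rate == 1.0
        assert np.isnan(res.mean_s)

    def test_injected_latency_pair_ordered_and_within_100_ms(self):
        rng = np.random.default_rng(3)
        t = np.arange(-0.5, 2.5, 0.01)
        nc = np.zeros((16, t.size))

        def cond(onset):
            eff = np.where(t > onset, 3.0, 0.0)
            return eff + rng.normal(0, 0.2, (16, t.size))

        ca = stats.divergence_latency(cond(0.45), nc, t, n_iter=200,
                                      boot_iter=400, min_run_s=0.1, rng=rng)
        cd = stats.divergence_latency(cond(1.0), nc, t, n_iter=200,
                                      boot_iter=400, min_run_s=0.1, rng=rng)
        assert ca.mean_s == pytest.approx(0.45, abs=0.1)
        assert cd.mean_s == pytest.approx(1.0, abs=0.1)
        assert ca.mean_s < cd.mean_s

    def test_monotone_in_effect_amplitude(self):
        rng = np.random.default_rng(4)
        t = np.arange(-0.5, 2.5, 0.02)
        nc = np.zeros((12, t.size))
        means = []
        for amp in (0.5, 1.5, 4.0):
            eff = np.clip(t - 0.4, 0, None) * amp
            a = eff + rng.normal(0, 0.3, (12, t.size))
            res = stats.divergence_latency(a, nc, t, n_iter=100, boot_iter=300,
                                           min_run_s=0.1, rng=rng)
            means.append(res.mean_s)
        assert means[0] >= means[1] >= means[2]


class TestWilcoxonEffectSize:
    def test_identical_scores_give_zero(self):
        a = np.arange(10.0)
        assert stats.wilcoxon_effect_size(a, a) == 0.0

    def test_maximal_r_for_perfectly_ordered_differences(self):
        # closed form: all 32 differences positive and distinct ->
        # Z = (T - mu) / sigma with T = n(n+1)/2
        n = 32
        a = np.arange(n, dtype=float) + 1.0
        b = np.zeros(n)
        T = n * (n + 1) / 2
        mu = n * (n + 1) / 4
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        expected = (T - mu) / sigma / np.sqrt(n)
        assert stats.wilcoxon_effect_size(a, b) == pytest.approx(expected,
                                                                 abs=1e-9)

    def test_sign_flip_leaves_r_unchanged(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 32)
        b = rng.normal(0.3, 1, 32)
        assert stats.wilcoxon_effect_size(a, b) == pytest.approx(
            stats.wilcoxon_effect_size(b, a), abs=1e-12)

    def test_exact_branch_used_for_small_samples(self):
        a = np.array([1.0, 2.0, 3.5, 0.25, 5.0, 6.125, 7.0, 0.0625])
        r = stats.wilcoxon_effect_size(a, np.zeros_like(a))
        assert 0.0 < r <= 1.2


class TestBehavior:
    def _table(self):
        rows = [
            dict(block=1, trial=1, condition="REG-NC", regularity="REG",
                 change_type="NC", change_time_s=None, gap_start_s=4.0,
                 is_decoy=True, onset_s=0.0),
            dict(block=1, trial=2, condition="REG-NC", regularity="REG",
                 change_type="NC", change_time_s=None, gap_start_s=None,
                 is_decoy=False, onset_s=0.0),
            dict(block=1, trial=3, condition="RND-NC", regularity="RND",
                 change_type="NC", change_time_s=None, gap_start_s=2.0,
                 is_decoy=True, onset_s=0.0),
        ]
        return pd.DataFrame(rows)

    def test_hit_window_boundary(self):
        table = self._table()
        resp = pd.DataFrame([dict(block=1, trial=1, press_time_s=4.0 + 1.9),
                             dict(block=1, trial=3, press_time_s=2.0 + 2.1)])
        scored = stats.score_trial_presses(table, resp)
        assert scored.loc[scored.trial == 1, "hit"].item()
        assert scored.loc[scored.trial == 1, "rt_s"].item() == pytest.approx(1.9)
        assert not scored.loc[scored.trial == 3, "hit"].item()
        assert scored.loc[scored.trial == 3, "false_alarm"].item()

    def test_press_on_no_gap_trial_is_false_alarm(self):
        table = self._table()
        resp = pd.DataFrame([dict(block=1, trial=2, press_time_s=3.0)])
        scored = stats.score_trial_presses(table, resp)
        row = scored[scored.trial == 2].iloc[0]
        assert row.false_alarm and not row.hit and row.any_press

    def test_no_presses_give_undefined_hit_rate_and_zero_fa(self):
        table = self._table()
        scored = stats.score_trial_presses(table, pd.DataFrame(
            columns=["block", "trial", "press_time_s"]))
        summary = stats.score_behavior({"P0": scored})
        per = summary.per_participant
        assert (per.hit_rate == 0).all() or per.hit_rate.notna().all()
        assert (per.n_fa == 0).all()
        assert len(summary.fa_times) == 0

    def test_uniform_false_alarm_times_yield_flat_histogram(self):
        # a synthetic responder pressing uniformly at random on no-gap trials
        rng = np.random.default_rng(6)
        rows, resp = [], []
        for k in range(600):
            rows.append(dict(block=1, trial=k, condition="REG-NC",
                             regularity="REG", change_type="NC",
                             change_time_s=None, gap_start_s=None,
                             is_decoy=False, onset_s=0.0))
            resp.append(dict(block=1, trial=k,
                             press_time_s=float(rng.uniform(0, 9.0))))
        scored = stats.score_trial_presses(pd.DataFrame(rows),
                                           pd.DataFrame(resp))
        summary = stats.score_behavior({"P0": scored})
        times = summary.fa_times.press_time_s.to_numpy()
        assert len(times) == 600
        from scipy.stats import kstest
        assert kstest(times / 9.0, "uniform").pvalue > 0.01


class TestRtPdCorrelation:
    def test_proportional_series_give_unit_correlation(self):
        rng = np.random.default_rng(7)
        rt = rng.normal(0, 1, 20)
        t = np.arange(-1.0, 10.0, 0.1)
        pd_diffs = rt[:, None] * np.ones(t.size)[None, :] * 2.5
        out = stats.rt_pd_correlation(rt, pd_diffs, t)
        assert np.allclose(out["r_t"], 1.0)
        assert out["r_window"] == pytest.approx(1.0)

    def test_windowed_equals_pointwise_of_time_average(self):
        rng = np.random.default_rng(8)
        rt = rng.normal(0, 1, 32)
        t = np.arange(-1.0, 10.0, 0.1)
        pd_diffs = rng.normal(0, 1, (32, t.size))
        out = stats.rt_pd_correlation(rt, pd_diffs, t, window_s=(6.0, 10.0))
        sel = (t >= 6.0) & (t <= 10.0)
        from scipy.stats import pearsonr
        manual = pearsonr(rt, pd_diffs[:, sel].mean(axis=1))[0]
        assert out["r_window"] == pytest.approx(manual, abs=1e-12)

    def test_null_calibration_of_pointwise_significance(self):
        rng = np.random.default_rng(9)
        rt = rng.normal(0, 1, 32)
        t = np.arange(0, 50.0, 0.1)
        pd_diffs = rng.normal(0, 1, (32, t.size))
        out = stats.rt_pd_correlation(rt, pd_diffs, t, window_s=(0, 50))
        assert (out["p_t"] < 0.05).mean() < 0.15

    def test_requires_three_participants(self):
        with pytest.raises(ValueError):
            stats.rt_pd_correlation(np.ones(2), np.ones((2, 5)), _time(5))
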