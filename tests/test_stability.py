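"""State-space reconstruction, Kantz Lyapunov exponents and MeanSD variability."""

import numpy as np
import pytest

from trunkmotion.signal_io import AccelTrace
from trunkmotion.simulate import TaskSimParams, simulate_pointing_task
from trunkmotion.stability import (
    acceleration_norm_series,
    average_mutual_information,
    delay_embed,
    global_false_nearest_neighbors,
    kantz_lyapunov,
    mean_sd_variability,
    select_task_cycles,
    time_normalize_series,
)


def _trace(ax, ay, az, fs=500.0):
    n = len(ax)
    return AccelTrace("T2", fs, np.arange(n) / fs, ax, ay, az)


class TestNormSeries:
    def test_constant_trace_gives_zeros(self):
        tr = _trace(np.full(100, 0.3), np.full(100, -0.2), np.full(100, 0.9))
        assert acceleration_norm_series(tr) == pytest.approx(np.zeros(100))

    def test_two_sample_arithmetic(self):
        tr = _trace(np.array([1.0, 2.0]), np.zeros(2), np.zeros(2))
        assert acceleration_norm_series(tr) == pytest.approx([-0.5, 0.5])

    def test_matches_brute_force_reference(self):
        rng = np.random.default_rng(8)
        t = np.arange(3000) / 500.0
        ax = 0.4 + 0.2 * np.sin(2 * np.pi * 0.2 * t) + rng.normal(0, 0.01, t.size)
        ay = -0.1 + 0.1 * np.sin(2 * np.pi * 0.4 * t + 1.0)
        az = 1.0 + 0.3 * np.cos(2 * np.pi * 0.2 * t)
        tr = _trace(ax, ay, az)
        # independent reference, written out longhand
        ref = []
        mx, my, mz = min(ax), min(ay), min(az)
        for i in range(t.size):
            ref.append(
                ((ax[i] - mx) ** 2 + (ay[i] - my) ** 2 + (az[i] - mz) ** 2) ** 0.5
            )
        ref = np.array(ref)
        ref -= ref.mean()
        assert np.max(np.abs(acceleration_norm_series(tr) - ref)) < 1e-12


class TestDelayEmbed:
    def test_small_example(self):
        emb = delay_embed(np.array([1.0, 2, 3, 4, 5, 6]), m=3, tau=1)
        expected = [[1, 2, 3], [2, 3, 4], [3, 4, 5], [4, 5, 6]]
        assert emb.vectors == pytest.approx(np.array(expected, float))

    def test_m1_is_identity(self):
        x = np.random.default_rng(0).normal(size=50)
        assert delay_embed(x, m=1, tau=7).vectors[:, 0] == pytest.approx(x)

    @pytest.mark.parametrize("m,tau", [(2, 3), (4, 10), (5, 75)])
    def test_vector_count(self, m, tau):
        x = np.random.default_rng(1).normal(size=1000)
        assert delay_embed(x, m, tau).vectors.shape == (1000 - (m - 1) * tau, m)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            delay_embed(np.zeros(10), m=5, tau=5)


class TestCycleSelection:
    def test_clean_32_cycles_give_30(self):
        params = TaskSimParams(cycle_rate=1.0 / 6.0, seed=4)
        trace, gt = simulate_pointing_task(params)
        raw = acceleration_norm_series(trace)
        trimmed, b = select_task_cycles(raw, trace.sampling_rate, nominal_rate=1.0 / 6.0)
        assert b.size == 31
        period = trace.sampling_rate * 6.0
        # boundaries align with ground-truth cycle starts within 5% of a cycle
        for bi in b:
            assert np.min(np.abs(gt - bi)) < 0.05 * period

    def test_too_few_cycles_raise(self):
        params = TaskSimParams(n_cycles=20, seed=0)
        trace, _ = simulate_pointing_task(params)
        raw = acceleration_norm_series(trace)
        with pytest.raises(ValueError, match="cycles"):
            select_task_cycles(raw, trace.sampling_rate)

    def test_period_jitter_tolerated(self):
        params = TaskSimParams(period_jitter_sd=0.05, seed=9)
        trace, _ = simulate_pointing_task(params)
        raw = acceleration_norm_series(trace)
        _, b = select_task_cycles(raw, trace.sampling_rate)
        assert b.size == 31


class TestTimeNormalize:
    def test_output_length_18000(self):
        params = TaskSimParams(cycle_rate=1.0 / 6.0, seed=4)
        trace, _ = simulate_pointing_task(params)
        raw = acceleration_norm_series(trace)
        trimmed, b = select_task_cycles(raw, trace.sampling_rate, nominal_rate=1.0 / 6.0)
        norm = time_normalize_series(trimmed, b - b[0])
        assert norm.x.size == 18000
        assert abs(norm.x.mean()) < 1e-9

    def test_cycles_of_600_samples_pass_through(self):
        rng = np.random.default_rng(3)
        series = rng.normal(size=3001)
        b = np.arange(0, 3001, 600)
        norm = time_normalize_series(series, b)
        reference = np.concatenate([series[b[i] : b[i] + 600] for i in range(5)])
        assert norm.x == pytest.approx(reference - reference.mean(), abs=1e-9)

    def test_unequal_sinusoid_cycles_match_analytic(self):
        lengths = [550, 600, 650, 580, 620]
        segs = [np.sin(2 * np.pi * np.arange(n + 1) / n) for n in lengths]
        series = np.concatenate([s[:-1] for s in segs] + [[0.0]])
        b = np.concatenate([[0], np.cumsum(lengths)])
        norm = time_normalize_series(series, b, points_per_cycle=600)
        one = np.sin(2 * np.pi * np.arange(600) / 600.0)
        expected = np.tile(one, 5)
        assert np.max(np.abs(norm.x - (expected - expected.mean()))) < 1e-3


class TestAMI:
    def test_iid_noise_near_zero(self):
        # finite-sample bias for a 32x32 equiprobable table at n=18,000 is
        # ~(B-1)^2/(2n) = 0.027 nats; bound frozen from Monte-Carlo runs
        rng = np.random.default_rng(11)
        ami, _ = average_mutual_information(rng.uniform(size=18000), max_lag=40)
        assert np.max(ami[1:]) < 0.035

    def test_noisy_sinusoid_quarter_period_minimum(self):
        base = np.sin(2 * np.pi * np.arange(18000) / 600.0)
        x = base + np.random.default_rng(12).normal(0, 0.05, 18000)
        _, lag = average_mutual_information(x, max_lag=300)
        assert 145 <= lag <= 155

    def test_periodic_signal_maximum_at_period(self):
        base = np.sin(2 * np.pi * np.arange(18000) / 600.0)
        x = base + np.random.default_rng(13).normal(0, 0.05, 18000)
        ami, _ = average_mutual_information(x, max_lag=650)
        # AMI peaks back up at the full period (self-similarity)
        assert abs((550 + np.argmax(ami[550:650])) - 600) <= 3

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(14)
        x = np.cumsum(rng.normal(size=5000))
        fwd, _ = average_mutual_information(x, max_lag=20)
        rev, _ = average_mutual_information(x[::-1], max_lag=20)
        assert np.max(np.abs(fwd - rev)) < 0.02

    def test_constant_series_raises(self):
        with pytest.raises(ValueError):
            average_mutual_information(np.ones(1000), max_lag=10)


class TestFNN:
    def test_sinusoid_embeds_in_plane(self, sinusoid_600):
        frac, m_min = global_false_nearest_neighbors(
            sinusoid_600, tau=150, m_max=3, theiler=450
        )
        assert frac[1] < 0.01
        assert m_min == 2

    def test_iid_noise_never_embeds(self):
        rng = np.random.default_rng(15)
        frac, m_min = global_false_nearest_neighbors(
            rng.normal(size=10000), tau=1, m_max=6
        )
        assert m_min is None
        assert np.all(frac > 0.05)


class TestKantz:
    def test_noiseless_sinusoid_is_marginally_stable(self, sinusoid_600):
        emb = delay_embed(sinusoid_600, m=3, tau=150)
        curve = kantz_lyapunov(emb, theiler=600)
        assert abs(curve.lambda_max) <= 0.002

    def test_scale_and_shift_invariance(self, lorenz_series):
        x = lorenz_series[:8000]
        base = kantz_lyapunov(delay_embed(x, 3, 17), theiler=100).lambda_max
        scaled = kantz_lyapunov(
            delay_embed(3.7 * x + 11.0, 3, 17), theiler=100
        ).lambda_max
        assert scaled == pytest.approx(base, abs=1e-6)

    def test_divergence_slope_consistency(self, lorenz_series):
        curve = kantz_lyapunov(delay_embed(lorenz_series[:8000], 3, 17), theiler=100)
        lo, hi = curve.fit_range
        slope = np.polyfit(curve.k[lo : hi + 1], curve.ln_div[lo : hi + 1], 1)[0]
        assert curve.lambda_max == pytest.approx(slope, abs=1e-12)
        assert curve.n_reference > 0


class TestMeanSD:
    def test_identical_cycles_zero(self):
        one = np.sin(2 * np.pi * np.arange(400) / 400.0)
        series = np.tile(one, 30)
        b = np.arange(0, 30 * 400 + 1, 400)
        res = mean_sd_variability(series, b)
        assert res.mean_sd == pytest.approx(0.0, abs=1e-9)

    def test_two_constant_cycles(self):
        series = np.concatenate([np.zeros(101), np.ones(101)])
        b = np.array([0, 101, 202])
        res = mean_sd_variability(series, b)
        assert res.mean_sd == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_noise_sd_recovered(self):
        # cycle length 401: the 101-point grid lands on integer samples, so
        # resampling does not attenuate the per-point noise
        errs = []
        for sigma in (0.1, 0.3):
            est = []
            for seed in range(20):
                rng = np.random.default_rng(100 + seed)
                base = np.sin(2 * np.pi * np.arange(401) / 400.0)
                cycles = [base + rng.normal(0, sigma, 401) for _ in range(30)]
                series = np.concatenate(cycles)
                b = np.arange(0, 30 * 401 + 1, 401)
                est.append(mean_sd_variability(series, b).mean_sd)
            errs.append(abs(np.mean(est) - sigma) / sigma)
        assert max(errs) < 0.10

    def test_shift_invariance_and_scaling(self):
        rng = np.random.default_rng(16)
        series = np.tile(np.sin(2 * np.pi * np.arange(300) / 300.0), 10)
        series = series + rng.normal(0, 0.2, series.size)
        b = np.arange(0, 3001, 300)
        base = mean_sd_variability(series, b).mean_sd
        shifted = mean_sd_variability(series + 5.0, b).mean_sd
        scaled = mean_sd_variability(series * 2.0, b).mean_sd
        assert shifted == pytest.approx(base, abs=1e-12)
        assert scaled == pytest.approx(2.0 * base, abs=1e-12)

    def test_single_cycle_raises(self):
        with pytest.raises(ValueError):
            mean_sd_variability(np.zeros(100), np.array([0, 99]))
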