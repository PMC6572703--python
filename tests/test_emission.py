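"""Emission estimators: segmentation, background, deconvolution, cyclic SS."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from onebox import (
    ConcentrationSeries,
    EmissionSchedule,
    EstimationError,
    GeneratorConfig,
    Scenario,
    activity_mean,
    cyclic_steady_state,
    deconvolve,
    deconvolved_background_rate,
    detect_activity,
    estimate_background,
    generate_ground_truth,
    simulate_one_box,
    spraying_duration,
    summarize_convolution,
)
from onebox.emission import ACTIVITY, BACKGROUND, OTHER


def discretization_factor(lam, dt):
    """Fraction of a constant source recovered by the discrete inverse."""
    x = lam * dt
    return (1.0 - np.exp(-x)) / x


class TestDetectActivity:
    def test_all_below_threshold(self):
        t = np.arange(0.0, 30.0, 1.0)
        labels = detect_activity(ConcentrationSeries(t, np.full(30, 1e3)), 1e5)
        assert not labels.activity.any()

    def test_square_wave_matches_high_phase(self):
        t = np.arange(0.0, 40.0, 1.0)
        v = np.where((t // 10) % 2 == 0, 1e4, 1e6)
        labels = detect_activity(ConcentrationSeries(t, v), 1e5)
        np.testing.assert_array_equal(labels.activity, v == 1e6)

    def test_background_window_overrides(self):
        t = np.arange(0.0, 30.0, 1.0)
        labels = detect_activity(
            ConcentrationSeries(t, np.full(30, 2e5)), 1e5, background_window=(10, 20)
        )
        assert set(labels.state[10:20]) == {BACKGROUND}
        assert set(labels.state[:10]) == {ACTIVITY}

    def test_counts_generated_bursts(self, short_cycle_truth):
        """Thresholding the room response finds one block per true burst."""
        labels = detect_activity(short_cycle_truth.clean_series, threshold=5e4)
        n_true = len(short_cycle_truth.labels.activity_blocks())
        assert len(labels.activity_blocks()) == n_true == short_cycle_truth.config.n_bursts


class TestSegmentLabels:
    def test_shift_aligns_source_steps_with_readings(self):
        t = np.arange(0.0, 5.0, 1.0)
        labels = detect_activity(ConcentrationSeries(t, [1e6, 1e3, 1e3, 1e3, 1e3]), 1e5)
        shifted = labels.shifted(1)
        assert shifted.state[1] == ACTIVITY
        assert shifted.state[0] == OTHER

    def test_activity_blocks_are_half_open_runs(self):
        t = np.arange(0.0, 6.0, 1.0)
        v = np.array([1e6, 1e6, 1e3, 1e6, 1e3, 1e6])
        labels = detect_activity(ConcentrationSeries(t, v), 1e5)
        assert labels.activity_blocks() == [(0, 2), (3, 4), (5, 6)]


class TestEstimateBackground:
    def test_constant_window(self):
        t = np.arange(0.0, 60.0, 1.0)
        bg = estimate_background(
            ConcentrationSeries(t, np.full(60, 1.7e4)), (0, 60), flow_m3h=6216.0
        )
        assert bg.mean == pytest.approx(1.7e4)
        assert bg.sd == 0.0

    def test_sample_standard_deviation(self):
        t = np.arange(0.0, 3.0, 1.0)
        bg = estimate_background(ConcentrationSeries(t, [90.0, 100.0, 110.0]), (0, 3), 60.0)
        assert bg.mean == pytest.approx(100.0)
        assert bg.sd == pytest.approx(10.0)  # ddof=1

    def test_s_bg_is_flow_times_mean(self):
        t = np.arange(0.0, 10.0, 1.0)
        bg = estimate_background(ConcentrationSeries(t, np.full(10, 1.9e4)), (0, 10), 6216.0)
        assert bg.s_bg == pytest.approx(6216.0 * 1e6 / 60.0 * 1.9e4)

    def test_lognormal_mean_within_three_se(self, rng):
        n, mu, cv = 2000, 2.0e4, 0.2
        sigma2 = np.log1p(cv**2)
        v = mu * rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), n)
        t = np.arange(0.0, float(n), 1.0)
        bg = estimate_background(ConcentrationSeries(t, v), (0, n), 6216.0)
        se = mu * cv / np.sqrt(n)
        assert abs(bg.mean - mu) < 3 * se


class TestDeconvolve:
    def test_constant_series_closed_form(self):
        t = np.arange(0.0, 20.0, 1.0)
        gamma, vol, n = 0.4, 2.486e8, 5.0e4
        sched = deconvolve(ConcentrationSeries(t, np.full(20, n)), gamma, vol)
        assert np.isnan(sched.rates[0])
        expected = vol * n * (1 - np.exp(-gamma)) / 1.0
        np.testing.assert_allclose(sched.rates[1:], expected, rtol=1e-12)

    def test_zero_series_gives_zero_schedule(self):
        t = np.arange(0.0, 10.0, 1.0)
        sched = deconvolve(ConcentrationSeries(t, np.zeros(10)), 0.4, 1e8)
        np.testing.assert_array_equal(sched.rates[1:], 0.0)

    @pytest.mark.parametrize("lam_dt", [0.01, 0.1, 0.5])
    def test_forward_inverse_bias_bound(self, lam_dt):
        """Recovered constant source biased by at most (1-e^-x)/x - 1."""
        dt = 1.0
        lam = lam_dt / dt
        sc = Scenario(volume=248.6, ach=lam * 60.0, background=1.9e4, dt=dt)
        times = np.arange(0.0, 200.0, dt)
        true = 1.0e13
        rates = np.where((times >= 40) & (times < 100), true, 0.0)
        out = simulate_one_box(sc, EmissionSchedule(times, rates), n0=1.9e4)

        sched = deconvolve(out, lam, sc.volume_cm3)
        # background rate estimated the same way, from source-off steps
        off = np.zeros(times.size, bool)
        off[1:20] = True
        s_bg = float(sched.rates[off].mean())
        on = np.zeros(times.size, bool)
        on[41:101] = True  # rates sit at the end of their step
        recovered = float((sched.rates[on] - s_bg).mean())
        bound = abs(discretization_factor(lam, dt) - 1.0)
        assert abs(recovered / true - 1.0) <= bound + 1e-9

    def test_bias_vanishes_as_dt_shrinks(self):
        biases = []
        for dt in (1.0, 0.1):
            lam = 25.0 / 60.0
            sc = Scenario(volume=248.6, ach=25.0, background=1.9e4, dt=dt)
            times = np.arange(0.0, 150.0, dt)
            rates = np.where((times >= 40) & (times < 100), 1e13, 0.0)
            out = simulate_one_box(sc, EmissionSchedule(times, rates), n0=1.9e4)
            sched = deconvolve(out, lam, sc.volume_cm3)
            s_bg = float(np.nanmean(sched.rates[times < 40][1:]))
            on = np.roll((times >= 40) & (times < 100), 1)
            biases.append(abs(float((sched.rates[on] - s_bg).mean()) / 1e13 - 1))
        assert biases[1] < biases[0]
        assert biases[1] < 0.05


class TestSummarizeConvolution:
    def test_pure_background_nets_to_zero(self):
        t = np.arange(0.0, 50.0, 1.0)
        sched = EmissionSchedule(t, np.full(50, 2.0e12))
        labels = detect_activity(ConcentrationSeries(t, np.full(50, 2e5)), 1e5)
        est = summarize_convolution(sched, labels, s_bg=2.0e12)
        assert est.rate == pytest.approx(0.0, abs=1e-3)
        assert est.method == "convolution"

    def test_no_activity_steps_raises(self):
        t = np.arange(0.0, 10.0, 1.0)
        sched = EmissionSchedule(t, np.ones(10))
        labels = detect_activity(ConcentrationSeries(t, np.full(10, 1e3)), 1e5)
        with pytest.raises(EstimationError):
            summarize_convolution(sched, labels, 0.0)

    def test_recovers_true_rate_within_bound(self, short_cycle_truth):
        truth = short_cycle_truth
        sc = truth.scenario
        sched = deconvolve(truth.clean_series, sc.loss_rate, sc.volume_cm3)
        labels = truth.labels.shifted(1)
        s_bg = deconvolved_background_rate(sched, labels)
        est = summarize_convolution(sched, labels, s_bg)
        bound = abs(discretization_factor(sc.loss_rate, sc.dt) - 1.0)
        assert abs(est.rate / truth.config.true_rate - 1.0) <= bound + 1e-9

    def test_deconvolved_background_on_noisy_day_nets_to_zero(self, noisy_truth):
        """Net rate over source-off steps has mean 0 within 3 SE under noise."""
        truth = noisy_truth
        sc = truth.scenario
        sched = deconvolve(truth.noisy_series, sc.loss_rate, sc.volume_cm3)
        labels = truth.labels.shifted(1)
        s_bg = deconvolved_background_rate(sched, labels)
        m = labels.background & np.isfinite(sched.rates)
        net = sched.rates[m] - s_bg
        se = net.std(ddof=1) / np.sqrt(m.sum())
        assert abs(net.mean()) < 3 * se + 1e-6


class TestCyclicSteadyState:
    def test_identity(self):
        assert cyclic_steady_state(1.0, 1.0, 1.0).rate == 1.0

    def test_worked_arithmetic(self):
        """Mean activity level 2.5e5 in a 2.486e8 cm^3 room over 8-min cycles."""
        est = cyclic_steady_state(2.5e5, 2.486e8, 8.0)
        assert est.rate == pytest.approx(2.5e5 * 2.486e8 / 8.0)
        assert est.rate == pytest.approx(7.77e12, rel=1e-3)

    @given(
        c_hat=st.floats(1e2, 1e7),
        vol=st.floats(1e6, 1e10),
        t_esd=st.floats(0.5, 120.0),
        k=st.floats(0.1, 10.0),
    )
    def test_scaling_laws(self, c_hat, vol, t_esd, k):
        """Linear in C_hat and V, inverse in t_ESD."""
        base = cyclic_steady_state(c_hat, vol, t_esd).rate
        assert cyclic_steady_state(k * c_hat, vol, t_esd).rate == pytest.approx(k * base)
        assert cyclic_steady_state(c_hat, k * vol, t_esd).rate == pytest.approx(k * base)
        assert cyclic_steady_state(c_hat, vol, k * t_esd).rate == pytest.approx(base / k)
        # invariant: rate * t_esd / V recovers C_hat exactly
        est = cyclic_steady_state(c_hat, vol, t_esd)
        assert est.rate * est.t_esd / vol == pytest.approx(c_hat)

    def test_nonpositive_duration_rejected(self):
        from onebox import DomainError

        with pytest.raises(DomainError):
            cyclic_steady_state(1e5, 1e8, 0.0)

    def test_duration_modes(self, short_cycle_truth):
        labels = short_cycle_truth.labels
        per_rep = spraying_duration(labels, "per_repetition")
        total = spraying_duration(labels, "total")
        n = len(labels.activity_blocks())
        assert total == pytest.approx(per_rep * n)
        lo, hi = short_cycle_truth.config.burst_duration
        assert lo - 1 <= per_rep <= hi + 1  # grid quantization


class TestEstimatorAgreement:
    @pytest.mark.parametrize("ach,volume", [(25.0, 248.6), (35.0, 459.4)])
    def test_methods_within_order_of_magnitude(self, ach, volume):
        """Deconvolution and cyclic SS disagree by at most ~10x, the spread
        seen between the two estimators in workshop conditions."""
        cfg = GeneratorConfig(seed=5, ach=ach, volume=volume, true_rate=5e12)
        truth = generate_ground_truth(cfg)
        sc = truth.scenario
        sched = deconvolve(truth.noisy_series, sc.loss_rate, sc.volume_cm3)
        labels = truth.labels.shifted(1)
        conv = summarize_convolution(
            sched, labels, deconvolved_background_rate(sched, labels)
        )
        c_hat = activity_mean(truth.noisy_series, truth.labels)
        cyc = cyclic_steady_state(
            c_hat, sc.volume_cm3, spraying_duration(truth.labels)
        )
        ratio = conv.rate / cyc.rate
        assert 0.1 <= ratio <= 10.0
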