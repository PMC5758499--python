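import numpy as np
import pytest

from calyxkit.depletion import DepletionModelParams
from calyxkit.kernels import WaveformKernel
from calyxkit.synth import (EventGroundTruth, simulate_event_series,
                            simulate_spike_train, synthesize_ais_stack,
                            synthesize_juxtacellular_trace,
                            synthesize_na_sweeps, synthesize_wholecell_step,
                            wt_like_ground_truth)

from conftest import make_trace


class TestSpikeTrain:
    def test_zero_rate_gives_no_events(self, wt_truth):
        truth = wt_like_ground_truth(spont_rate=0.0)
        assert simulate_spike_train(None, truth, 0, duration=5000.0).size == 0

    def test_poisson_count_within_three_sd(self):
        truth = wt_like_ground_truth(spont_rate=50.0)
        n = simulate_spike_train(None, truth, 7, duration=100_000.0).size
        assert abs(n - 5000) < 3 * np.sqrt(5000)

    def test_refractory_enforced_for_any_seed(self, protocol, wt_truth):
        for seed in range(5):
            t = simulate_spike_train(protocol, wt_truth, seed, interval=40.0)
            assert np.all(np.diff(t) >= wt_truth.refractory)

    def test_identical_seed_identical_train(self, protocol, wt_truth):
        a = simulate_spike_train(protocol, wt_truth, 3, interval=80.0)
        b = simulate_spike_train(protocol, wt_truth, 3, interval=80.0)
        assert np.array_equal(a, b)

    def test_rate_too_high_for_dead_time_rejected(self):
        truth = wt_like_ground_truth(spont_rate=960.0)
        with pytest.raises(ValueError, match="refractory"):
            simulate_spike_train(None, truth, 0, duration=1000.0)


class TestEventSeries:
    def test_no_depletion_no_failures_constant(self, wt_truth):
        from dataclasses import replace
        flat = DepletionModelParams(A=1.0, states=((0.0, 10.0),))
        truth = wt_like_ground_truth(
            depletion_params_eepsp=replace(flat, A=8.0),
            depletion_params_eap=replace(flat, A=150.0),
            depletion_params_prespike=replace(flat, A=0.5),
            failure_prob=0.0)
        gt = simulate_event_series(np.arange(50) * 5.0, truth, seed=0)
        assert np.allclose(gt.true_eepsp_slope, 8.0)
        assert np.allclose(gt.true_eap_dvdt, 150.0)
        assert not gt.is_failure.any()

    def test_pair_follows_two_event_recursion(self):
        truth = wt_like_ground_truth(
            depletion_params_prespike=DepletionModelParams(
                A=1.0, states=((0.5, 100.0),)))
        gt = simulate_event_series(np.array([0.0, 30.0]), truth, seed=0)
        expect = 1.0 - 0.5 * np.exp(-30.0 / 100.0)
        assert gt.true_prespike_amp[1] == pytest.approx(expect, rel=1e-9)

    def test_failure_probability_binomial(self, wt_truth):
        gt = simulate_event_series(np.arange(20_000) * 10.0, wt_truth, seed=1)
        frac = gt.is_failure.mean()
        assert abs(frac - 0.106) < 3 * np.sqrt(0.106 * 0.894 / 20_000)

    def test_interval_dependent_failures_rise_at_short_intervals(self):
        truth = wt_like_ground_truth(failure_model="interval")
        short = simulate_event_series(np.arange(5000) * 2.0, truth, seed=2)
        long_ = simulate_event_series(np.arange(5000) * 50.0, truth, seed=2)
        assert short.is_failure.mean() > long_.is_failure.mean() + 0.05


class TestJuxtacellularTrace:
    def test_zero_events_pure_noise(self):
        gt = EventGroundTruth(np.empty(0), np.empty(0), np.empty(0),
                              np.empty(0), np.empty(0))
        tr = synthesize_juxtacellular_trace(gt, WaveformKernel(), 0.2,
                                            50_000.0, seed=0, duration=2000.0)
        assert tr.samples.std() == pytest.approx(0.2, rel=0.05)

    def test_eap_halfwidth_matches_kernel(self):
        from calyxkit.events import detect_events, measure_events
        k = WaveformKernel(eap_halfwidth=0.3)
        tr = make_trace([50.0], 8.0, 150.0, 0.5, False, kernel=k)
        ev = measure_events(tr, detect_events(tr))[0]
        assert ev.eap_halfwidth == pytest.approx(0.3, abs=0.02)

    def test_failure_event_omits_the_spike(self):
        k = WaveformKernel()
        tr = make_trace([50.0], 8.0, 150.0, 0.5, True, kernel=k)
        assert tr.samples.max() < 0.5 * k.eap_amp
        assert tr.samples.max() > 0.2  # prespike and EPSP are present

    def test_synthesis_is_linear_in_events(self):
        k = WaveformKernel()
        tr_a = make_trace([30.0], 8.0, 150.0, 0.5, False, kernel=k, duration=100.0)
        tr_b = make_trace([60.0], 6.0, 120.0, 0.4, False, kernel=k, duration=100.0)
        tr_ab = synthesize_juxtacellular_trace(
            EventGroundTruth([30.0, 60.0], [8.0, 6.0], [150.0, 120.0],
                             [0.5, 0.4], [False, False]),
            k, 0.0, 50_000.0, seed=0, duration=100.0)
        assert np.allclose(tr_ab.samples, tr_a.samples + tr_b.samples, atol=1e-12)


class TestWholecellStep:
    def test_rc_circuit_closed_form(self):
        sw = synthesize_wholecell_step(8.0, 72.0, 25.0, -10.0, noise_sd=0.0)
        dt = sw.dt_ms
        i_on = int(20.0 / dt)
        assert sw.samples[i_on] == pytest.approx(-1.25, rel=1e-3)  # step/Rs
        i_ss = int(200.0 / dt)
        assert sw.samples[i_ss] == pytest.approx(-0.125, rel=1e-3)  # step/(Rs+Rm)
        # relaxation time constant Rs*Cm*Rm/(Rs+Rm) = 180 us
        i_ss_val = -0.125
        target = i_ss_val + (-1.25 - i_ss_val) / np.e
        seg = sw.samples[i_on:i_on + int(1.0 / dt)]
        t_tau = np.argmin(np.abs(seg - target)) * dt
        assert t_tau == pytest.approx(0.180, abs=0.02)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            synthesize_wholecell_step(-1.0, 72.0, 25.0, -10.0)
        with pytest.raises(ValueError):
            synthesize_wholecell_step(8.0, 72.0, 25.0, 0.0)


class TestNaSweeps:
    def test_recovery_ratio_closed_form(self):
        sweeps = synthesize_na_sweeps(50.0, np.array([50.0]), 2.0, 0.0, seed=0)
        assert sweeps[0].meta["true_ratio"] == pytest.approx(1 - np.exp(-1), rel=1e-9)

    def test_short_interval_almost_no_recovery(self):
        sweeps = synthesize_na_sweeps(50.0, np.array([0.2]), 2.0, 0.0, seed=0)
        assert sweeps[0].meta["true_ratio"] == pytest.approx(0.004, abs=0.001)

    def test_long_interval_full_recovery(self):
        sweeps = synthesize_na_sweeps(50.0, np.array([5000.0]), 2.0, 0.0, seed=0)
        assert sweeps[0].meta["true_ratio"] == pytest.approx(1.0, abs=1e-9)


class TestAisStack:
    def test_noiseless_rod_extent_matches_length(self):
        st = synthesize_ais_stack(12.0, 0.4, (0.0, 0.0, 1.0), seed=0,
                                  blur=False, noise=False, intensity_cv=0.0)
        fg = np.argwhere(st.voxels > st.voxels.max() / 2)
        extent_x = (fg[:, 2].max() - fg[:, 2].min()) * st.spacing[2]
        assert extent_x == pytest.approx(12.0, abs=0.3)

    def test_zero_intensity_gives_flat_stack(self):
        st = synthesize_ais_stack(12.0, 0.4, (0.0, 0.0, 1.0), seed=0,
                                  peak_intensity=0.0, background=0.0, noise=False)
        assert not st.voxels.any()

    def test_xy_orientation_swap_is_equivalent(self):
        a = synthesize_ais_stack(8.0, 0.4, (0.0, 0.0, 1.0), seed=5,
                                 blur=False, noise=False, intensity_cv=0.0)
        b = synthesize_ais_stack(8.0, 0.4, (0.0, 1.0, 0.0), seed=5,
                                 blur=False, noise=False, intensity_cv=0.0)
        assert np.array_equal(a.voxels.transpose(0, 2, 1), b.voxels)

    def test_rod_exceeding_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            synthesize_ais_stack(12.0, 0.4, (0.0, 0.0, 1.0), shape=(9, 15, 50))

    def test_too_short_rod_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            synthesize_ais_stack(0.8, 0.4, (0.0, 0.0, 1.0))
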