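import numpy as np
import pytest

from calyxkit.intrinsics import (ap_features, estimate_resistances,
                                 fit_na_recovery, na_amplitude,
                                 threshold_from_failures,
                                 threshold_inflection)
from calyxkit.synth import (EventGroundTruth, SweepRecording,
                            synthesize_na_sweeps, synthesize_wholecell_cc,
                            synthesize_wholecell_step)


@pytest.fixture(scope="module")
def cc_trace():
    times = np.arange(40) * 25.0 + 20.0
    rng = np.random.default_rng(0)
    fails = rng.random(40) < 0.3
    sub = np.where(fails, rng.uniform(5.0, 12.0, 40), 0.0)
    return synthesize_wholecell_cc(times, fails, seed=1, sub_peak_dv=sub)


class TestResistances:
    def test_ideal_rc_closed_form(self):
        sw = synthesize_wholecell_step(8.0, 72.0, 25.0, -10.0, noise_sd=0.0)
        r = estimate_resistances([sw], blank=False)
        assert r.R_series == pytest.approx(8.0, rel=0.01)
        assert r.R_input == pytest.approx(80.0, rel=0.01)
        assert r.R_membrane == r.R_input - r.R_series  # identity, exact

    def test_blanking_recovers_event_free_estimate(self):
        ev = EventGroundTruth(np.array([60.0, 100.0, 150.0]), np.ones(3),
                              np.ones(3), np.ones(3), np.zeros(3, bool))
        clean = synthesize_wholecell_step(8.0, 72.0, 25.0, -10.0, noise_sd=0.0)
        dirty = synthesize_wholecell_step(8.0, 72.0, 25.0, -10.0,
                                          spont_events=ev, seed=1)
        r_clean = estimate_resistances([clean], blank=False)
        r_dirty = estimate_resistances([dirty])
        assert r_dirty.R_series == pytest.approx(r_clean.R_series, rel=0.02)
        assert r_dirty.R_input == pytest.approx(r_clean.R_input, rel=0.02)

    def test_zero_step_rejected(self):
        with pytest.raises(ValueError):
            synthesize_wholecell_step(8.0, 72.0, 25.0, 0.0)


class TestAPFeatures:
    def test_amplitude_halfwidth_closure(self, cc_trace):
        f = ap_features(cc_trace)
        assert f.v_rest == pytest.approx(-65.0, abs=0.5)
        assert f.ap_amplitude == pytest.approx(55.0, rel=0.02)
        assert f.halfwidth == pytest.approx(0.44, rel=0.02)
        assert f.dvdt_max > 100.0

    def test_flat_trace_is_an_error(self):
        tr = SweepRecording(np.full(5000, -65.0), 50_000.0, "wholecell_cc")
        with pytest.raises(ValueError, match="no action potentials"):
            ap_features(tr)

    def test_doubling_sample_rate_is_stable(self):
        times = np.arange(20) * 30.0 + 20.0
        a = ap_features(synthesize_wholecell_cc(times, np.zeros(20, bool),
                                                seed=3, noise_sd=0.0))
        b = ap_features(synthesize_wholecell_cc(times, np.zeros(20, bool),
                                                seed=3, noise_sd=0.0,
                                                sample_rate=100_000.0))
        assert b.ap_amplitude == pytest.approx(a.ap_amplitude, rel=0.01)
        assert b.halfwidth == pytest.approx(a.halfwidth, rel=0.01)
        assert b.v_rest == pytest.approx(a.v_rest, abs=0.3)
        # the sub-0.1 ms upstroke makes the discrete derivative clock-dependent
        assert b.dvdt_max == pytest.approx(a.dvdt_max, rel=0.10)

    def test_junction_correction_applied_once(self, cc_trace):
        f = ap_features(cc_trace, junction_mv=-11.0)
        f0 = ap_features(cc_trace)
        assert f.v_rest == pytest.approx(f0.v_rest - 11.0, abs=1e-9)
        assert f.junction_corrected
        assert f.ap_amplitude == f0.ap_amplitude  # amplitudes are differences


class TestThresholds:
    def test_inflection_matches_injected_threshold(self, cc_trace):
        assert threshold_inflection(cc_trace) == pytest.approx(-58.0, abs=1.0)

    def test_single_event_mean_is_that_event(self):
        tr = synthesize_wholecell_cc(np.array([30.0]), np.array([False]),
                                     seed=0, noise_sd=0.0)
        assert threshold_inflection(tr) == pytest.approx(-58.0, abs=1.0)

    def test_dc_offset_shifts_estimate_exactly(self, cc_trace):
        shifted = SweepRecording(cc_trace.samples + 5.0, cc_trace.sample_rate,
                                 cc_trace.mode)
        assert threshold_inflection(shifted) == pytest.approx(
            threshold_inflection(cc_trace) + 5.0, abs=0.2)

    def test_failure_threshold_order_statistic(self):
        rng = np.random.default_rng(1)
        peaks = rng.uniform(-70.0, -55.0, 400)
        ivs = rng.uniform(11.0, 200.0, 400)
        est = threshold_from_failures(peaks, ivs)
        assert est == pytest.approx(-55.0, abs=0.2)
        p99 = threshold_from_failures(peaks, ivs, statistic="p99")
        assert p99 <= est

    def test_failure_threshold_needs_long_intervals(self):
        with pytest.raises(ValueError, match="10"):
            threshold_from_failures(np.full(50, -60.0), np.full(50, 5.0))

    def test_failure_estimate_below_inflection_by_construction(self, cc_trace):
        # subthreshold peaks were drawn strictly below the spike threshold
        rng = np.random.default_rng(2)
        peaks = rng.uniform(-70.0, -58.5, 100)
        ivs = rng.uniform(11.0, 100.0, 100)
        est = threshold_from_failures(peaks, ivs)
        assert est <= threshold_inflection(cc_trace) + 0.5


class TestNaRecovery:
    INTERVALS = np.array([0.2, 0.5, 1, 2, 5, 10, 20, 50, 100, 200, 400, 600])

    def test_amplitude_is_peak_minus_local_baseline(self):
        sweeps = synthesize_na_sweeps(50.0, np.array([100.0]), 2.0, 0.0,
                                      seed=0, baseline_offset=-0.1)
        amps = na_amplitude(sweeps[0])
        assert amps[0] == pytest.approx(2.0, abs=0.01)

    def test_recovery_tau_closure(self):
        sweeps = synthesize_na_sweeps(50.0, self.INTERVALS, 2.0, 0.0, seed=0)
        amps = np.array([na_amplitude(s) for s in sweeps])
        rel = amps[:, 1] / amps[:, 0]
        curve = fit_na_recovery(self.INTERVALS, rel, -95.0)
        assert curve.tau_rec == pytest.approx(50.0, abs=0.5)

    def test_monotone_recovery_noiseless(self):
        sweeps = synthesize_na_sweeps(30.0, self.INTERVALS, 2.0, 0.0, seed=0)
        amps = np.array([na_amplitude(s) for s in sweeps])
        rel = amps[:, 1] / amps[:, 0]
        assert np.all(np.diff(rel) >= -1e-6)

    def test_tau_under_noise_within_ten_percent(self):
        taus = []
        for seed in range(8):
            sweeps = synthesize_na_sweeps(50.0, self.INTERVALS, 2.0,
                                          0.05 * 2.0, seed=seed)
            amps = np.array([na_amplitude(s) for s in sweeps])
            taus.append(fit_na_recovery(self.INTERVALS,
                                        amps[:, 1] / amps[:, 0], -95.0).tau_rec)
        assert abs(np.mean(taus) / 50.0 - 1.0) < 0.10

    def test_no_inactivation_flagged(self):
        curve = fit_na_recovery(self.INTERVALS, np.ones(12), -95.0)
        assert curve.flags

    def test_holding_potential_ordering_preserved(self):
        fits = []
        for tau, vh in [(20.0, -95.0), (80.0, -60.0)]:
            sweeps = synthesize_na_sweeps(tau, self.INTERVALS, 2.0, 0.0, seed=3)
            amps = np.array([na_amplitude(s) for s in sweeps])
            fits.append(fit_na_recovery(self.INTERVALS,
                                        amps[:, 1] / amps[:, 0], vh))
        assert fits[0].tau_rec < fits[1].tau_rec
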