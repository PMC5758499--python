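import numpy as np
import pytest

from calyxkit.depletion import fit_depletion
from calyxkit.events import detect_events, measure_events
from calyxkit.protocol import make_stimulus_protocol
from calyxkit.synth import (simulate_event_series, simulate_spike_train,
                            synthesize_juxtacellular_trace,
                            wt_like_ground_truth)
from calyxkit.templates import (build_templates, corrected_prespike_series,
                                subtract_previous)

from conftest import make_trace


def detected(trace):
    det = detect_events(trace)
    return det, measure_events(trace, det)


class TestBuildTemplates:
    def test_identical_events_average_to_the_event(self):
        times = np.arange(25) * 40.0 + 20.0
        tr = make_trace(times, 8.0, 150.0, 0.5, False)
        det, evs = detected(tr)
        tmpls = build_templates(tr, evs, n_groups=4)
        # every template equals the (identical) event waveform, extracted
        # the same way the builder does (relative to the detected time)
        i0 = int(round((det[0] - 1.0) / tr.dt_ms))
        ref = tr.samples[i0: i0 + tmpls[0].waveform.size]
        ref = ref - np.median(ref[:25])
        for t in tmpls:
            assert np.max(np.abs(t.waveform - ref)) < 1e-6

    def test_two_populations_straddled_by_template_rates(self):
        times = np.arange(40) * 40.0 + 20.0
        dvdts = np.where(np.arange(40) % 2 == 0, 60.0, 160.0)
        tr = make_trace(times, 8.0, dvdts, 0.5, False)
        det, evs = detected(tr)
        tmpls = build_templates(tr, evs, n_groups=4)
        rates = sorted(t.mean_downward_rate for t in tmpls)
        # the most negative template comes from the large population, the
        # least negative from the small one
        assert rates[0] < -10.0 < rates[-1]

    def test_too_few_isolated_events_is_an_error(self):
        tr = make_trace([50.0], 8.0, 150.0, 0.5, False)
        det, evs = detected(tr)
        with pytest.raises(ValueError, match="fewer groups|isolated"):
            build_templates(tr, evs, n_groups=4)

    def test_group_count_bounds(self):
        times = np.arange(30) * 40.0 + 20.0
        tr = make_trace(times, 8.0, 150.0, 0.5, False)
        det, evs = detected(tr)
        with pytest.raises(ValueError):
            build_templates(tr, evs, n_groups=7)


class TestSubtraction:
    def _overlapping_pair_trace(self, dt_pair, prespike2=0.35, noise=0.0, seed=0):
        # isolated events to build templates from, then the pair under test
        iso = np.arange(25) * 40.0 + 20.0
        times = np.concatenate([iso, [1500.0, 1500.0 + dt_pair]])
        pres = np.full(times.size, 0.5)
        pres[-1] = prespike2
        return make_trace(times, 8.0, 150.0, pres, False, noise_sd=noise,
                          seed=seed), times, pres

    def test_non_overlapping_pair_unchanged(self):
        tr, times, pres = self._overlapping_pair_trace(10.0, noise=0.0)
        det, evs = detected(tr)
        tmpls = build_templates(tr, evs)
        amps, status = corrected_prespike_series(tr, evs, tmpls)
        raw = np.array([e.prespike_amp for e in evs])
        # at 10 ms separation the after-wave has decayed: subtraction is a
        # no-op within a fraction of the noise floor
        assert abs(amps[-1] - raw[-1]) < 0.02

    @pytest.mark.parametrize("dt_pair", [1.2, 1.8, 2.2])
    def test_overlapping_pair_recovered_after_subtraction(self, dt_pair):
        tr, times, pres = self._overlapping_pair_trace(dt_pair)
        det, evs = detected(tr)
        tmpls = build_templates(tr, evs)
        amps, status = corrected_prespike_series(tr, evs, tmpls)
        raw = np.array([e.prespike_amp for e in evs])
        true = pres[-1]
        assert abs(amps[-1] - true) / true < 0.05
        assert abs(raw[-1] - true) / true > 0.20

    def test_previous_failure_needs_no_correction(self):
        iso = np.arange(25) * 40.0 + 20.0
        times = np.concatenate([iso, [1500.0, 1501.8]])
        fails = np.zeros(times.size, bool)
        fails[-2] = True  # the event before the measured one has no spike
        tr = make_trace(times, 8.0, 150.0, 0.5, fails)
        det, evs = detected(tr)
        tmpls = build_templates(tr, evs)
        amps, status = corrected_prespike_series(tr, evs, tmpls)
        assert status[-1] == "no-downward-phase"
        # only the failure's own EPSP tail perturbs the measurement
        assert abs(amps[-1] - 0.5) < 0.2

    def test_subtraction_is_idempotent(self):
        tr, times, pres = self._overlapping_pair_trace(1.5)
        det, evs = detected(tr)
        tmpls = build_templates(tr, evs)
        working = tr.samples.copy()
        before = working.copy()
        subtract_previous(working, evs[-2].t_event, tmpls, tr.dt_ms,
                          t_next=evs[-1].t_event)
        first_correction = np.abs(before - working).max()
        after_first = working.copy()
        subtract_previous(working, evs[-2].t_event, tmpls, tr.dt_ms,
                          t_next=evs[-1].t_event)
        second_correction = np.abs(after_first - working).max()
        assert second_correction < 0.05 * first_correction

    def test_no_templates_flagged_unmeasurable(self):
        tr, times, _ = self._overlapping_pair_trace(1.5)
        working = tr.samples.copy()
        assert subtract_previous(working, times[-2], [], tr.dt_ms) == "unmeasurable"


class TestRecoveryRegression:
    def test_prespike_tau_unbiased_only_with_subtraction(self):
        # the headline regression: the recovery constant fitted from
        # subtracted prespike amplitudes is close to the injected one;
        # the raw (unsubtracted) series gives a grossly biased fit
        protocol = make_stimulus_protocol()
        truth = wt_like_ground_truth()
        t_cor, a_cor, t_raw, a_raw = [], [], [], []
        for si, iv in enumerate(protocol.inter_burst_intervals):
            st = simulate_spike_train(protocol, truth, 10 + si, interval=iv)
            gt = simulate_event_series(st, truth, 50 + si)
            tr = synthesize_juxtacellular_trace(
                gt, truth.kernel, truth.noise_sd, truth.sample_rate,
                90 + si, duration=protocol.sweep_duration, protocol=protocol)
            det = detect_events(tr)
            evs = measure_events(tr, det)
            tmpls = build_templates(tr, evs)
            amps, _ = corrected_prespike_series(tr, evs, tmpls)
            ok = np.isfinite(amps) & (amps > 0.02)
            t_cor.append(det[ok])
            a_cor.append(amps[ok])
            raw = np.array([e.prespike_amp for e in evs])
            okr = np.isfinite(raw) & (raw > 0.02)
            t_raw.append(det[okr])
            a_raw.append(raw[okr])
        fit_c = fit_depletion(t_cor, np.concatenate(a_cor), n_states=1,
                              loss="soft_l1", f_scale=0.05, trim_mult=5.0)
        fit_r = fit_depletion(t_raw, np.concatenate(a_raw), n_states=1,
                              loss="soft_l1", f_scale=0.05, trim_mult=5.0)
        tau_true = truth.depletion_params_prespike.tau_fast
        assert abs(fit_c.params.tau_fast / tau_true - 1.0) < 0.25
        assert abs(fit_r.params.tau_fast / tau_true - 1.0) > 0.25
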