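# calyxkit

Simulation and analysis of in vivo recordings from the calyx of Held —
the giant axosomatic synapse onto principal neurons of the medial
nucleus of the trapezoid body (MNTB).  A juxtacellular electrode at this
synapse sees a *complex waveform* per transmission event: a small
**prespike** (the presynaptic spike), an **eEPSP** rise, and — when
transmission succeeds — a large **eAP** deflection.  The package is
aimed at electrophysiologists who study short-term depression and
excitability at this synapse and want a fully ground-truthed testbed for
the analysis chain:

* **synthetic data** (`calyxkit.synth`, `calyxkit.kernels`) — spike
  trains under the two-noise-burst auditory protocol, per-event
  amplitudes from resource-depletion dynamics, rendered juxtacellular
  and whole-cell traces, paired-pulse Na⁺-current sweeps, and
  confocal-like image stacks of the axon initial segment (AIS), all with
  stored ground truth and bit-reproducible seeding;
* **event analysis** (`calyxkit.events`) — detection of complex
  waveforms, per-event features (prespike amplitude, eEPSP′ = maximum
  rate of rise of the EPSP, eAP′ = maximum first derivative of the
  spike, halfwidth, delays), failure classification, PSTHs;
* **template subtraction** (`calyxkit.templates`) — removal of the
  previous event's downward phase so prespike amplitudes are measurable
  at short inter-event intervals;
* **model fitting** (`calyxkit.depletion`) — the resource-depletion
  model of short-term depression and the empirical exponential fits of
  depression onset and recovery;
* **intrinsic properties** (`calyxkit.intrinsics`) — series/input/
  membrane resistance from a voltage step, AP features, two
  spike-threshold estimators, Na⁺-current recovery from inactivation;
* **AIS morphology** (`calyxkit.ais`) — IsoData + 3D hysteresis
  thresholding + skeletonization length measurement;
* **orchestration** (`calyxkit.pipeline`, `calyxkit` CLI) — an
  end-to-end simulate → detect → subtract → fit → report run over
  simulated cohorts.

## The model at the core

Transmission strength without plasticity is `A`; one or two depression
states `D_k ∈ (0, 1]` multiply it.  At the *i*-th event

```
amplitude_i = A · Π_k D_k(t_i⁻),   D_k ← D_k (1 − f_k),
D_k(t) = 1 − (1 − D_k) e^(−Δt/τ_k)   between events,
```

with depletion fraction `f_k` and recovery constant `τ_k`.  Fitting the
event-time/amplitude series with one state (prespike, eEPSP′) or two
states (eAP′ — a fast constant of order 1.5 ms plus a slow one of order
100 ms) recovers the recovery kinetics of transmission and excitability
directly from irregular in vivo firing.  See `docs/methods.md` for the
full account, including every convention the source procedures leave
unstated.

## Worked example

```python
import numpy as np
from calyxkit import (make_stimulus_protocol, wt_like_ground_truth,
                      simulate_spike_train, simulate_event_series,
                      synthesize_juxtacellular_trace,
                      detect_events, measure_events, fit_depletion)

protocol = make_stimulus_protocol()        # 2 x 400 ms bursts, 6 gaps
truth = wt_like_ground_truth()             # group-mean parameters
trains, amps = [], []
for k, gap in enumerate(protocol.inter_burst_intervals):
    st = simulate_spike_train(protocol, truth, seed=3 * k, interval=gap)
    gt = simulate_event_series(st, truth, seed=3 * k + 1)
    trace = synthesize_juxtacellular_trace(gt, truth.kernel, truth.noise_sd,
                                           truth.sample_rate, seed=3 * k + 2,
                                           duration=protocol.sweep_duration)
    events = measure_events(trace, detect_events(trace))
    keep = [(e.t_event, e.eap_dvdt_max) for e in events
            if not e.is_failure and np.isfinite(e.eap_dvdt_max)]
    t, a = map(np.asarray, zip(*keep))
    trains.append(t); amps.append(a)

fit = fit_depletion(trains, np.concatenate(amps), n_states=2)
print(f"fast tau {fit.params.tau_fast:.2f} ms, slow tau "
      f"{fit.params.tau_slow:.0f} ms, variance explained "
      f"{100 * fit.variance_explained:.1f}%")
```

which prints (seed-dependent within a few percent)

```
fast tau 1.46 ms, slow tau 109 ms, variance explained 96.7%
```

— the two-state fit pulls the injected fast (1.58 ms) and slow (109 ms)
recovery constants of postsynaptic-spike depression back out of six
sound-evoked sweeps, explaining most of the amplitude variance exactly
as the model should when the data are generated by it.

The numbered scripts under `analysis/` run the same machinery as a
narrative: `01` simulates a two-group cohort (wild-type-like and
mutant-like cells plus Na⁺ sweeps and AIS stacks into `scratch/`),
`02`–`07` detect events, fit spike/prespike/EPSP recovery, extract
intrinsic properties and Na⁺ recovery, and measure AIS lengths, writing
tables under `results/`.

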