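#!/usr/bin/env python
"""Simulate the synthetic cohort used by the downstream analyses.

One wild-type-like and one mutant-like juxtacellular cell (all six
two-burst gap conditions each), a whole-cell step + current-clamp pair,
paired-pulse Na+ sweeps at three holding potentials, and AIS image
stacks for both groups.  Raw sweeps/stacks are bulky binaries and go to
scratch/; everything downstream re-reads them from there.
"""

from pathlib import Path

import numpy as np

from calyxkit import sweepio
from calyxkit.protocol import make_stimulus_protocol
from calyxkit.synth import (mutant_like_ground_truth, simulate_event_series,
                            simulate_spike_train, synthesize_ais_stack,
                            synthesize_juxtacellular_trace,
                            synthesize_na_sweeps, wt_like_ground_truth)

SEED = 20260923
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "cohort"

AIS_LENGTHS = {"wt": 12.7, "mutant": 15.9}  # group-mean lengths, um
NA_TAUS = {-95.0: 20.0, -65.0: 60.0, -60.0: 80.0}  # recovery tau per Vh, ms


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    protocol = make_stimulus_protocol()
    rng = np.random.default_rng(SEED)

    for name, truth in (("wt", wt_like_ground_truth()),
                        ("mutant", mutant_like_ground_truth())):
        sweeps = []
        for rep in range(3):
            for iv in protocol.inter_burst_intervals:
                s = int(rng.integers(2**31))
                train = simulate_spike_train(protocol, truth, s, interval=iv)
                gt = simulate_event_series(train, truth, s + 1)
                sw = synthesize_juxtacellular_trace(
                    gt, truth.kernel, truth.noise_sd, truth.sample_rate,
                    s + 2, duration=protocol.sweep_duration, protocol=protocol)
                sw.meta["interval_ms"] = float(iv)
                sweeps.append(sw)
        sweepio.write_sweeps(SCRATCH / f"juxta_{name}.h5", sweeps,
                             meta={"group": name, "seed": SEED})
        n_ev = sum(len(sw.ground_truth) for sw in sweeps)
        print(f"{name}: {len(sweeps)} juxtacellular sweeps, {n_ev} events")

        for vh, tau in NA_TAUS.items():
            na = synthesize_na_sweeps(
                tau, np.array([0.2, 0.5, 1, 2, 5, 10, 20, 50, 100, 200, 400, 600]),
                2.0, 0.02, seed=int(rng.integers(2**31)))
            sweepio.write_sweeps(SCRATCH / f"na_{name}_vh{int(vh)}.h5", na,
                                 meta={"group": name, "holding_mV": vh})

        for i in range(10):
            theta = rng.uniform(0, np.pi)
            stack = synthesize_ais_stack(
                AIS_LENGTHS[name], 0.4,
                (rng.uniform(-0.15, 0.15), np.sin(theta), np.cos(theta)),
                seed=int(rng.integers(2**31)))
            sweepio.write_stack(SCRATCH / f"ais_{name}_{i:02d}.tif", stack)
        print(f"{name}: Na sweeps at {list(NA_TAUS)} mV, 10 AIS stacks "
              f"(true length {AIS_LENGTHS[name]} um)")


if __name__ == "__main__":
    main()
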