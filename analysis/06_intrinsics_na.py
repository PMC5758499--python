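#!/usr/bin/env python
"""Whole-cell intrinsic properties and Na+-current recovery.

Simulates a whole-cell pair (voltage-clamp step + current-clamp
spontaneous activity) per group, extracts resistances, AP features and
both threshold estimators, then fits the recovery from inactivation of
the simulated Na+ currents at each holding potential.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from calyxkit import sweepio
from calyxkit.intrinsics import (ap_features, estimate_resistances,
                                 fit_na_recovery, na_amplitude,
                                 threshold_from_failures,
                                 threshold_inflection)
from calyxkit.synth import (EventGroundTruth, synthesize_wholecell_cc,
                            synthesize_wholecell_step)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

JUNCTION_IN_VIVO = -11.0  # mV
JUNCTION_SLICE = -13.0  # mV (protocol metadata, applied to Na recordings)

# group-level generator settings: the mutant-like cell rests lower, spikes
# bigger/briefer, and fails less
CC_PARAMS = {
    "wt": dict(v_rest=-61.8, v_thresh=-57.6, ap_amplitude=47.9,
               ap_halfwidth=0.55, fail_p=0.135),
    "mutant": dict(v_rest=-67.2, v_thresh=-60.2, ap_amplitude=54.9,
                   ap_halfwidth=0.44, fail_p=0.085),
}


def main() -> None:
    rng = np.random.default_rng(77)
    rows = []
    for name, prm in CC_PARAMS.items():
        # passive properties from a -10 mV step with spontaneous EPSCs
        ev = EventGroundTruth(np.sort(rng.uniform(30.0, 210.0, 4)),
                              np.ones(4), np.ones(4), np.ones(4),
                              np.zeros(4, bool))
        step = synthesize_wholecell_step(8.0, 72.4 if name == "wt" else 93.6,
                                         25.0, -10.0, spont_events=ev,
                                         seed=int(rng.integers(2**31)))
        r = estimate_resistances([step])

        # AP features and thresholds from spontaneous current-clamp activity
        times = np.sort(rng.uniform(20.0, 20_000.0, 500))
        times = times[np.diff(times, prepend=-20.0) > 3.0]
        fails = rng.random(times.size) < prm["fail_p"]
        sub_dv = np.where(
            fails, rng.uniform(4.0, prm["v_thresh"] - prm["v_rest"], times.size), 0.0)
        cc = synthesize_wholecell_cc(
            times, fails, seed=int(rng.integers(2**31)),
            v_rest=prm["v_rest"], v_thresh=prm["v_thresh"],
            ap_amplitude=prm["ap_amplitude"], ap_halfwidth=prm["ap_halfwidth"],
            sub_peak_dv=sub_dv)
        feats = ap_features(cc, junction_mv=JUNCTION_IN_VIVO)
        infl = threshold_inflection(cc, junction_mv=JUNCTION_IN_VIVO)
        # subthreshold peaks for the failure-based estimator
        dt = cc.dt_ms
        peaks, ivs = [], []
        prev = -1e9
        for j, (te, fl) in enumerate(zip(times, fails)):
            if fl:
                # keep the window clear of the next event's spike
                nxt = times[j + 1] if j + 1 < times.size else te + 10.0
                lo, hi = int(te / dt), int(min(te + 3.0, nxt - 0.5) / dt)
                peaks.append(cc.samples[lo:hi].max())
                ivs.append(te - prev)
            prev = te
        thr_fail = threshold_from_failures(np.array(peaks), np.array(ivs),
                                           junction_mv=JUNCTION_IN_VIVO)
        rows.append({
            "group": name, "R_series_MOhm": r.R_series,
            "Membrane resistance (MOhm)": r.R_membrane,
            "Resting potential (mV)": feats.v_rest,
            "AP amplitude": feats.ap_amplitude,
            "AP dVdt (V/s)": feats.dvdt_max,
            "AP half width (ms)": feats.halfwidth,
            "Inflection point (mV)": infl,
            "Estimated threshold (mV)": thr_fail,
        })
        print(f"{name}: Rm {r.R_membrane:.0f} MOhm, rest "
              f"{feats.v_rest:.1f} mV, AP {feats.ap_amplitude:.1f} mV / "
              f"{feats.halfwidth:.2f} ms, threshold {infl:.1f} mV "
              f"(inflection) vs {thr_fail:.1f} mV (failures)")
    pd.DataFrame(rows).to_csv(RESULTS / "intrinsics.csv", index=False)

    na_rows = []
    for name in ("wt", "mutant"):
        for vh in (-95, -65, -60):
            sweeps = sweepio.read_sweeps(SCRATCH / f"na_{name}_vh{vh}.h5")
            ivs = np.array([s.protocol["interval_ms"] for s in sweeps])
            amps = np.array([na_amplitude(s) for s in sweeps])
            curve = fit_na_recovery(ivs, amps[:, 1] / amps[:, 0], vh)
            na_rows.append({"group": name, "holding_mV": vh,
                            "tau_rec_ms": curve.tau_rec})
            print(f"{name} Vh {vh} mV: Na recovery tau {curve.tau_rec:.1f} ms")
    pd.DataFrame(na_rows).to_csv(RESULTS / "na_recovery.csv", index=False)


if __name__ == "__main__":
    main()
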