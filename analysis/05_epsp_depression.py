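#!/usr/bin/env python
"""Short-term depression and recovery of the EPSP rate of rise.

Three complementary readouts per group: the onset of depression in units
of sound-evoked event number, the steady-state depression level during
the last 50 ms of the burst relative to the pre-stimulus baseline, and
the recovery time constant fitted to post-burst events.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from calyxkit import sweepio
from calyxkit.depletion import (fit_onset_decay, fit_recovery_after_tone,
                                steady_state_depression)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    rows = []
    for name in ("wt", "mutant"):
        df = pd.read_csv(RESULTS / f"events_{name}.csv")
        sweeps = sweepio.read_sweeps(SCRATCH / f"juxta_{name}.h5")
        protocol = sweeps[0].protocol
        gaps = {si: sw.meta["interval_ms"] for si, sw in enumerate(sweeps)}
        (on1, off1), _ = protocol.burst_windows(protocol.inter_burst_intervals[0])

        # onset: mean eEPSP' by evoked event number within burst 1
        by_number = []
        for _, g in df.groupby("sweep"):
            evoked = g[(g["t_event"] >= on1) & (g["t_event"] < off1)]
            by_number.append(evoked["eepsp_slope_max"].to_numpy()[:25])
        n_max = max(len(v) for v in by_number)
        mat = np.full((len(by_number), n_max), np.nan)
        for i, v in enumerate(by_number):
            mat[i, :len(v)] = v
        with np.errstate(invalid="ignore"):
            mean_series = np.nanmean(mat, axis=0)
        onset = fit_onset_decay(mean_series[np.isfinite(mean_series)])

        # steady-state depression, averaged over sweeps
        ssd = []
        for _, g in df.groupby("sweep"):
            try:
                ssd.append(steady_state_depression(
                    g["t_event"].to_numpy(), g["eepsp_slope_max"].to_numpy(),
                    protocol))
            except ValueError:
                pass

        # recovery after the second burst (events in the trailing silence)
        t_rec, y_rec = [], []
        for si, g in df.groupby("sweep"):
            off2 = protocol.burst_windows(gaps[si])[1][1]
            post = g[g["t_event"] >= off2]
            t_rec.append(post["t_event"].to_numpy() - off2)
            y_rec.append(post["eepsp_slope_max"].to_numpy())
        rec = fit_recovery_after_tone(np.concatenate(t_rec),
                                      np.concatenate(y_rec))

        rows.append({"group": name,
                     "onset_tau_events": onset.tau,
                     "steady_state_percent": float(np.mean(ssd)),
                     "recovery_tau_ms": rec.tau})
        print(f"{name}: onset tau {onset.tau:.1f} events, steady state "
              f"{np.mean(ssd):.0f}% of control, recovery tau {rec.tau:.0f} ms")
    pd.DataFrame(rows).to_csv(RESULTS / "epsp_depression.csv", index=False)


if __name__ == "__main__":
    main()
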