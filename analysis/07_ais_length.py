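#!/usr/bin/env python
"""Measure AIS skeletal lengths and compare the two groups.

Runs the IsoData + 3D-hysteresis + skeletonization pipeline on every
simulated stack and reports per-group means with a rank-sum test (no
multiple-testing correction anywhere in this project).
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from calyxkit import sweepio
from calyxkit.ais import measure_ais

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    rows = []
    for path in sorted(SCRATCH.glob("ais_*.tif")):
        group = path.stem.split("_")[1]
        stack = sweepio.read_stack(path)
        m = measure_ais(stack)
        rows.append({"group": group, "stack": path.name,
                     "true_length_um": stack.meta.get("true_length_um"),
                     "length_um": m.length, "t_low": m.thresholds[0],
                     "branched": m.branched})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "ais_length.csv", index=False)

    wt = df[df["group"] == "wt"]["length_um"]
    mut = df[df["group"] == "mutant"]["length_um"]
    p = stats.mannwhitneyu(wt, mut).pvalue
    print(f"wt: {wt.mean():.2f} +/- {wt.sem():.2f} um (n={len(wt)}); "
          f"mutant: {mut.mean():.2f} +/- {mut.sem():.2f} um (n={len(mut)}); "
          f"Mann-Whitney p = {p:.3g}")


if __name__ == "__main__":
    main()
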