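"""Idealize every cohort trace and fit per-membrane activation curves.

For each trace: kernel density of the currents, threshold-current
detection from the intersecting power-law flanks, binary idealization and
open probability.  Per membrane the (voltage, p_open) points are fitted
with a Boltzmann activation curve.  Writes results/idealization.csv and
results/activation_fits.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from cohort import MEMBRANES, RESULTS, SCRATCH

from chanmem import io as cio
from chanmem.idealize import (detect_threshold, estimate_current_pdf,
                              fit_activation_curve, idealize_trace,
                              infer_sign, open_probability)


def main() -> None:
    manifest = pd.read_csv(RESULTS / "cohort_manifest.csv")
    rows = []
    for rec in manifest.itertuples():
        trace = cio.read_trace(SCRATCH / f"{rec.trace}.csv")
        pdf = estimate_current_pdf(trace)
        thr = detect_threshold(pdf)
        states = idealize_trace(trace, thr.tc, sign=infer_sign(pdf))
        rows.append({
            "trace": rec.trace, "membrane": rec.membrane,
            "voltage_mV": rec.voltage_mV, "patch": rec.patch,
            "tc_pA": thr.tc, "r2_left": thr.diagnostics["r2_left"],
            "r2_right": thr.diagnostics["r2_right"],
            "p_open": open_probability(states),
            "p_open_true": rec.p_open_true,
        })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "idealization.csv", index=False)
    err = np.abs(table.p_open - table.p_open_true)
    print(f"idealized {len(table)} traces; TC mean "
          f"{table.tc_pA.mean():.2f} pA; median |p_open error| "
          f"{err.median():.4f}")

    fits = []
    for membrane in MEMBRANES:
        sub = table[table.membrane == membrane]
        pts = sub.groupby("voltage_mV")["p_open"].mean().reset_index().values
        fit = fit_activation_curve(pts)
        fits.append({"membrane": membrane, "v_half_mV": fit.v_half,
                     "slope_k_mV": fit.slope_k, "p_max": fit.p_max,
                     "flagged": fit.flagged})
        lo = sub[sub.voltage_mV == sub.voltage_mV.min()].p_open.mean()
        hi = sub[sub.voltage_mV == sub.voltage_mV.max()].p_open.mean()
        print(f"{membrane}: p_open spans {lo:.3f} -> {hi:.3f}; "
              f"V1/2 = {fit.v_half:.1f} mV, k = {fit.slope_k:.1f} mV")
    pd.DataFrame(fits).to_csv(RESULTS / "activation_fits.csv", index=False)


if __name__ == "__main__":
    main()
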