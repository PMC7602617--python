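"""Focus-based MFDFA of the cohort current traces.

Each 2^15-sample current trace yields one singularity spectrum; widths
are tabulated per membrane and voltage and compared between membranes.
Writes results/mf_spectra.csv (one row per (trace, q)) and
results/mf_width.csv.
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from cohort import MEMBRANES, RESULTS, SCRATCH, VOLTAGES, N_PATCHES

from chanmem import io as cio
from chanmem.controls import compare_groups
from chanmem.mfdfa import mfdfa


def main() -> None:
    warnings.filterwarnings("ignore")
    spec_rows, width_rows = [], []
    for membrane in MEMBRANES:
        for voltage in VOLTAGES:
            for patch in range(N_PATCHES):
                stem = f"{membrane}_{int(voltage):+03d}mV_p{patch}"
                trace = cio.read_trace(SCRATCH / f"{stem}.csv")
                sp = mfdfa(trace.samples)
                width_rows.append({"membrane": membrane,
                                   "voltage_mV": voltage, "patch": patch,
                                   "delta": sp.delta, "concave": sp.concave})
                for q, hq, tau, h, d in zip(sp.q, sp.hq, sp.tau, sp.holder,
                                            sp.dims):
                    spec_rows.append({"trace": stem, "membrane": membrane,
                                      "voltage_mV": voltage, "q": q,
                                      "Hq": hq, "tau": tau, "h": h, "D": d})
    pd.DataFrame(spec_rows).to_csv(RESULTS / "mf_spectra.csv", index=False)
    widths = pd.DataFrame(width_rows)
    widths.to_csv(RESULTS / "mf_width.csv", index=False)

    print(widths.pivot_table(index="voltage_mV", columns="membrane",
                             values="delta").round(3))
    groups = {m: g.delta.to_numpy() for m, g in widths.groupby("membrane")}
    res = compare_groups(groups["mitochondrial"], groups["cellular"],
                         label_a="mitochondrial", label_b="cellular")
    print(f"\nspectrum width: median mito {res.median_a:.3f} vs cell "
          f"{res.median_b:.3f}; Mann-Whitney p = {res.p_value:.3g} "
          f"({res.method})")


if __name__ == "__main__":
    main()
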