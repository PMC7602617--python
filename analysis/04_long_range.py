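"""R/S and DFA exponents across the cohort; membrane-type comparison.

Every recording contributes current-series chunks (2^13 samples) and
dwell-time series in three variants (all sojourns at 2^12, open-only and
closed-only at 2^11).  Exponents are pooled over voltages and patches per
membrane type and compared with the exact Mann-Whitney test.  The
built-in effect — stronger slow rate modulation in the cellular-like
population — should surface as larger dwell-series exponents for
'cellular'.  Writes results/exponents.csv, results/exponent_medians.csv
and results/membrane_comparisons.csv.
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from cohort import MEMBRANES, RESULTS, SCRATCH, VOLTAGES, N_PATCHES

from chanmem import io as cio
from chanmem.controls import aggregate_exponents, compare_groups
from chanmem.core import OPEN
from chanmem.longmemory import (N_CURRENT, N_DWELL_ALL, N_DWELL_SINGLE,
                                chunk_series, dfa, rs_hurst)


def _records_for(series, length, variant, meta):
    out = []
    try:
        chunks = chunk_series(series, length)
    except ValueError:
        return out
    for k, chunk in enumerate(chunks):
        for fn in (rs_hurst, dfa):
            res = fn(chunk)
            out.append({**meta, "signal_variant": variant, "chunk": k,
                        "method": res.method, "exponent": res.exponent,
                        "r2": res.r2})
    return out


def main() -> None:
    warnings.filterwarnings("ignore", message="dropped")
    records = []
    for membrane in MEMBRANES:
        for voltage in VOLTAGES:
            for patch in range(N_PATCHES):
                stem = f"{membrane}_{int(voltage):+03d}mV_p{patch}"
                meta = {"membrane": membrane, "voltage_mV": voltage,
                        "patch": patch}
                trace = cio.read_trace(SCRATCH / f"{stem}.csv")
                records += _records_for(trace.samples, N_CURRENT, "current",
                                        meta)
                dur = np.load(SCRATCH / f"{stem}_dwells.npy")[1:-1]
                is_open = np.load(SCRATCH / f"{stem}_dwells_open.npy")[1:-1]
                records += _records_for(dur, N_DWELL_ALL, "all", meta)
                records += _records_for(dur[is_open], N_DWELL_SINGLE, "open",
                                        meta)
                records += _records_for(dur[~is_open], N_DWELL_SINGLE,
                                        "closed", meta)
    df = pd.DataFrame(records)
    df.to_csv(RESULTS / "exponents.csv", index=False)

    medians = aggregate_exponents(df.to_dict("records"))
    medians.to_csv(RESULTS / "exponent_medians.csv", index=False)
    print(medians.pivot_table(index=["method", "signal_variant"],
                              columns="membrane", values="median").round(3))

    comps = []
    for method in ("RS", "DFA"):
        for variant in ("current", "all", "open", "closed"):
            cell = df[(df.method == method) & (df.signal_variant == variant)]
            groups = {m: g.exponent.to_numpy()
                      for m, g in cell.groupby("membrane")}
            if len(groups) != 2:
                continue
            res = compare_groups(groups["mitochondrial"], groups["cellular"],
                                 label_a="mitochondrial", label_b="cellular")
            comps.append({"method": method, "signal_variant": variant,
                          "U": res.u_stat, "p": res.p_value,
                          "median_mito": res.median_a,
                          "median_cell": res.median_b,
                          "n_mito": res.n_a, "n_cell": res.n_b,
                          "significant": res.significant,
                          "test": res.method})
    comp_df = pd.DataFrame(comps)
    comp_df.to_csv(RESULTS / "membrane_comparisons.csv", index=False)
    dw = comp_df[comp_df.signal_variant == "all"]
    print("\ndwell-series (all states) comparison:")
    print(dw.to_string(index=False))


if __name__ == "__main__":
    main()
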