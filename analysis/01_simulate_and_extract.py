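#!/usr/bin/env python
"""Simulate a connectivity-assay cohort and extract per-pulse EPSP amplitudes.

Draws 50 pyramidal→interneuron connections (30 depressing / 20 facilitating,
mixed acute and culture preparations), renders paired sweeps at 20 and
50 Hz (8 induction + 4 recovery pulses, 250 ms recovery delay), plus a full
recovery-delay series (62.5 ms – 4 s) for six depressing connections, then
runs presynaptic QC, failure-inclusive averaging and EPSP measurement.

Writes results/connections.csv and results/cohort_truth.csv; bulky sweep
HDF5 goes to scratch/ as a format demonstration.
"""

import sys
import time
from pathlib import Path

import numpy as np

from stpkit import (
    EPSPKinetics,
    RECOVERY_DELAYS_S,
    StimProtocol,
    draw_release_params,
    exclude_polysynaptic,
    extract_connection,
    simulate_connection,
)
from stpkit.io import save_records_csv, save_sweeps_h5

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
SEED = 1234
N_DEPRESSING, N_FACILITATING = 30, 20
N_SWEEPS = 6


def main() -> None:
    t0 = time.time()
    rng = np.random.default_rng(SEED)
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)

    records, truth_rows = [], []
    regimes = ["depressing"] * N_DEPRESSING + ["facilitating"] * N_FACILITATING
    demo_sweeps = {}
    for i, regime in enumerate(regimes):
        cid = f"conn{i:03d}"
        params = draw_release_params(regime, rng, noise_sd_frac=0.05)
        kin = EPSPKinetics(
            tau_rise=rng.uniform(1.5, 3.0),
            tau_decay=rng.uniform(15.0, 30.0),
            onset_delay=rng.uniform(0.8, 2.5),
        )
        prep = "culture" if rng.random() < 0.6 else "acute"
        meta = dict(
            prep=prep,
            disease="epilepsy" if rng.random() < 0.5 else "tumor",
            div=float(rng.uniform(2.5, 9.0)) if prep == "culture" else np.nan,
        )
        conditions = [(20.0, 0.25), (50.0, 0.25)]
        if regime == "depressing" and i < 6:  # recovery-delay series
            conditions += [(50.0, d) for d in RECOVERY_DELAYS_S if d != 0.25]
        for freq, delay in conditions:
            protocol = StimProtocol(frequency=freq, recovery_delay=delay,
                                    n_sweeps=N_SWEEPS)
            sweeps, _ = simulate_connection(
                params, protocol, kin, seed=int(rng.integers(0, 2**31 - 1))
            )
            records.append(extract_connection(sweeps, connection_id=cid, **meta))
            if i == 0 and freq == 50.0 and delay == 0.25:
                demo_sweeps[cid] = sweeps
        truth_rows.append(dict(connection_id=cid, regime=regime,
                               U=params.U, tau_rec=params.tau_rec,
                               tau_facil=params.tau_facil, A=params.A, **meta))

    n_before = len({r.connection_id for r in records})
    records = exclude_polysynaptic(records, max_onset_delay=4.0)
    n_after = len({r.connection_id for r in records})

    save_records_csv(records, RESULTS / "connections.csv")
    import pandas as pd

    pd.DataFrame(truth_rows).to_csv(RESULTS / "cohort_truth.csv", index=False)
    save_sweeps_h5(SCRATCH / "example_sweeps.h5", demo_sweeps)

    print(f"simulated {n_before} connections, {len(records)} condition records")
    print(f"polysynaptic exclusion (4 ms cutoff): {n_before - n_after} connections removed")
    print(f"wrote {RESULTS / 'connections.csv'} and cohort_truth.csv "
          f"({time.time() - t0:.1f} s)")


if __name__ == "__main__":
    sys.exit(main())
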