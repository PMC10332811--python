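#!/usr/bin/env python
"""Cohort statistics over the extracted connections.

Reads results/stp_metrics.csv and results/connections.csv and runs the
comparisons the cohort design calls for: EPSP amplitude of depressing vs
facilitating connections (rank-sum), acute vs culture amplitude
distributions (Kolmogorov–Smirnov), FDR-corrected per-pulse comparisons of
the normalized trains between preparations, a mixed-design ANOVA of pulse
profiles (prep × pulse), and the PPR ~ EPSP-amplitude regression.

Writes results/group_stats.json.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from stpkit import (
    compute_metrics,
    fdr_adjust,
    ks_two_sample,
    linear_regression,
    two_way_rm_anova,
    wilcoxon_rank_sum,
)
from stpkit.io import load_records_csv

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    metrics = pd.read_csv(RESULTS / "stp_metrics.csv")
    at50 = metrics[metrics.frequency == 50.0].dropna(subset=["epsp_amplitude"])
    out = {}

    dep = at50[at50.dynamics == "depressing"].epsp_amplitude
    fac = at50[at50.dynamics == "facilitating"].epsp_amplitude
    rs = wilcoxon_rank_sum(dep, fac)
    out["amplitude_dep_vs_fac"] = dict(p=rs.p_value, method=rs.method, n=rs.n)
    print(f"EPSP amplitude, depressing (median {dep.median():.2f} mV, n={len(dep)}) vs "
          f"facilitating (median {fac.median():.2f} mV, n={len(fac)}): "
          f"rank-sum p = {rs.p_value:.4f}")

    ks = ks_two_sample(at50[at50.prep == "acute"].epsp_amplitude,
                       at50[at50.prep == "culture"].epsp_amplitude)
    out["amplitude_acute_vs_culture_ks"] = dict(D=ks.statistic, p=ks.p_value, n=ks.n)
    print(f"acute vs culture amplitudes: KS D = {ks.statistic:.2f}, p = {ks.p_value:.4f}")

    records = [r for r in load_records_csv(RESULTS / "connections.csv")
               if r.frequency == 50.0 and r.recovery_delay == 0.25]
    trains = {r.connection_id: compute_metrics(r).normalized_train for r in records}
    prep = {r.connection_id: r.prep for r in records}
    raw_p = []
    for k in range(1, 8):  # pulses 2..8
        a = [trains[c][k] for c in trains if prep[c] == "acute"]
        c = [trains[c][k] for c in trains if prep[c] == "culture"]
        raw_p.append(wilcoxon_rank_sum(a, c).p_value)
    adj = fdr_adjust(raw_p)
    out["per_pulse_prep_fdr"] = dict(
        pulses=list(range(2, 9)), p_raw=list(map(float, raw_p)),
        p_fdr=list(map(float, adj)),
    )
    sig = [p + 2 for p in range(7) if adj[p] < 0.05]
    print(f"per-pulse acute/culture rank-sum (FDR-corrected): "
          f"significant pulses {sig if sig else 'none'}")

    rows = []
    for cid, tr in trains.items():
        for k in range(1, 8):
            rows.append(dict(subject=cid, prep=prep[cid], pulse=f"p{k + 1}", y=tr[k]))
    anova = two_way_rm_anova(pd.DataFrame(rows), "y", "pulse", "subject", "prep")
    out["rm_anova_prep_by_pulse"] = {
        row.effect: dict(F=float(row.F), p=float(row.p))
        for row in anova.itertuples()
    }
    p_between = anova.loc[anova.effect == "between", "p"].iloc[0]
    print(f"mixed ANOVA (prep × pulse): between-prep p = {p_between:.4f}")

    reg = linear_regression(at50.epsp_amplitude, at50.ppr)
    out["ppr_vs_amplitude"] = dict(slope=reg.slope, r_squared=reg.r_squared,
                                   p=reg.p_value, n=reg.n)
    print(f"PPR ~ amplitude: slope {reg.slope:+.4f}, R² {reg.r_squared:.4f}, "
          f"p = {reg.p_value:.4f}")

    (RESULTS / "group_stats.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    sys.exit(main())
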