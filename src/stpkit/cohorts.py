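"""Simulated connection cohorts with the study's statistical structure.

A cohort mixes depressing (pyramidal → PVALB-like: high initial release
probability, slow resource recovery, larger EPSPs) and facilitating
(pyramidal → non-PVALB-like: low initial release, slow facilitation decay,
smaller EPSPs) connections, split across acute and culture preparations and
epilepsy and tumor donors, and is pushed through the full render → extract
pipeline so downstream metrics see realistic measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .extraction import ConnectionRecord, extract_connection
from .protocols import StimProtocol
from .release import ReleaseModelParams
from .sweeps import EPSPKinetics, simulate_connection


def draw_release_params(
    regime: str,
    rng: np.random.Generator,
    noise_sd_frac: float = 0.05,
    p_fail: float = 0.0,
) -> ReleaseModelParams:
    """Random parameters within the depressing or facilitating regime.

    Amplitude distributions follow the cohort asymmetry in which depressing
    connections have larger initial EPSPs than facilitating ones.
    """
    if regime == "depressing":
        U = rng.uniform(0.35, 0.7)
        tau_rec = rng.uniform(0.3, 0.8)
        tau_facil = rng.uniform(0.005, 0.05)
        A = np.exp(rng.uniform(np.log(0.8), np.log(8.0)))
    elif regime == "facilitating":
        U = rng.uniform(0.05, 0.15)
        tau_rec = rng.uniform(0.02, 0.1)
        tau_facil = rng.uniform(0.3, 0.8)
        A = np.exp(rng.uniform(np.log(0.5), np.log(3.0)))
    else:
        raise ValueError("regime must be 'depressing' or 'facilitating'")
    return ReleaseModelParams(
        U=U, tau_rec=tau_rec, tau_facil=tau_facil, A=A,
        p_fail=p_fail, noise_sd=noise_sd_frac * A,
    )


@dataclass
class SimulatedCohort:
    records: list[ConnectionRecord]
    truth: pd.DataFrame  # per connection: regime, U, tau_rec, tau_facil, A


def linked_intrinsic_features(
    cohort: "SimulatedCohort", seed: int = 0
) -> pd.DataFrame:
    """Intrinsic features for each postsynaptic cell, tied to its regime.

    Depressing connections get PVALB-like postsynaptic cells, facilitating
    connections non-PVALB-like ones, reproducing the target-cell specificity
    the assay is designed to reveal.  Rows are indexed by connection id; the
    true subclass is kept in a ``subclass`` column for scoring only.
    """
    from .populations import IntrinsicPopulationSpec, simulate_intrinsic_features

    spec = IntrinsicPopulationSpec(n_per_class=len(cohort.records))
    pool = simulate_intrinsic_features(spec, seed=seed)
    pool["protocol"] = "connectivity"
    by_class = {
        "PVALB": pool[pool.subclass == "PVALB"].reset_index(drop=True),
        "non-PVALB": pool[pool.subclass == "non-PVALB"].reset_index(drop=True),
    }
    taken = {k: 0 for k in by_class}
    rows = []
    for cid, regime in cohort.truth["regime"].items():
        subclass = "PVALB" if regime == "depressing" else "non-PVALB"
        row = by_class[subclass].iloc[taken[subclass]].copy()
        taken[subclass] += 1
        row.name = cid
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_cohort(
    n_depressing: int = 30,
    n_facilitating: int = 20,
    frequency: float = 50.0,
    recovery_delay: float = 0.25,
    n_sweeps: int = 10,
    noise_sd_frac: float = 0.05,
    p_fail: float = 0.0,
    sampling_rate: float = 20_000.0,
    culture_fraction: float = 0.6,
    seed: int = 0,
) -> SimulatedCohort:
    """Simulate, render and extract a mixed cohort at one protocol condition."""
    rng = np.random.default_rng(seed)
    protocol = StimProtocol(
        frequency=frequency, recovery_delay=recovery_delay, n_sweeps=n_sweeps
    )
    records, rows = [], []
    regimes = ["depressing"] * n_depressing + ["facilitating"] * n_facilitating
    for i, regime in enumerate(regimes):
        params = draw_release_params(regime, rng, noise_sd_frac, p_fail)
        kin = EPSPKinetics(
            tau_rise=rng.uniform(1.5, 3.0),
            tau_decay=rng.uniform(15.0, 30.0),
            onset_delay=rng.uniform(0.8, 2.5),
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sweeps, _ = simulate_connection(
            params, protocol, kin, sampling_rate=sampling_rate, seed=sub_seed
        )
        prep = "culture" if rng.random() < culture_fraction else "acute"
        rec = extract_connection(
            sweeps,
            connection_id=f"conn{i:03d}",
            prep=prep,
            disease="epilepsy" if rng.random() < 0.5 else "tumor",
            div=float(rng.uniform(2.5, 9.0)) if prep == "culture" else np.nan,
        )
        records.append(rec)
        rows.append(
            dict(
                connection_id=rec.connection_id,
                regime=regime,
                U=params.U,
                tau_rec=params.tau_rec,
                tau_facil=params.tau_facil,
                A=params.A,
                tau_rise=kin.tau_rise,
                tau_decay=kin.tau_decay,
                onset_delay=kin.onset_delay,
                prep=prep,
            )
        )
    return SimulatedCohort(records, pd.DataFrame(rows).set_index("connection_id"))
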