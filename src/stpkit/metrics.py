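"""Short-term plasticity metrics and cohort-level structures.

Per connection: paired-pulse ratio (PPR, pulse 2 / pulse 1), 1:8 ratio,
1:6–8 ratio (mean of pulses 6–8 over pulse 1), the pulse-1-normalised train,
a recovery curve over probe delays, and a depressing/facilitating call.
Ratios are oriented later/first, so facilitation ⇔ ratio > 1; a ratio of
exactly 1 is called depressing (non-facilitating), keeping reported
facilitation fractions conservative.  Across connections: amplitude-sorted
heatmaps, per-frequency dynamics summaries and a PPR-vs-days-in-culture
regression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extraction import ConnectionRecord
from .stats import linear_regression

log = logging.getLogger(__name__)


@dataclass
class STPMetrics:
    connection_id: str
    ppr: float  # pulse2 / pulse1
    ratio_1_8: float  # pulse8 / pulse1
    ratio_1_6_8: float  # mean(pulses 6-8) / pulse1
    normalized_train: np.ndarray  # each pulse / pulse1
    dynamics_call: str  # {depressing, facilitating}
    early_recovery: float = np.nan  # 9th pulse / pulse1 at 250 ms delay
    flagged: bool = False


@dataclass
class RecoveryCurve:
    connection_id: str
    delays_ms: np.ndarray  # sorted ascending
    recovery: np.ndarray  # normalised 9th-pulse amplitude per delay


@dataclass
class DynamicsHeatmap:
    matrix: np.ndarray  # (n_connections, n_pulses) normalised amplitudes
    connection_ids: list[str]
    first_amplitudes: np.ndarray  # raw pulse-1 amplitude, descending
    frequency: float
    prep: str | None = None


def compute_metrics(
    record: ConnectionRecord, classify_by: str = "ppr"
) -> STPMetrics:
    """Per-connection STP metrics from the 12 per-pulse mean amplitudes.

    ``classify_by`` selects the ratio used for the depressing/facilitating
    call ("ppr", "ratio_1_8" or "ratio_1_6_8"); facilitating iff that ratio
    is strictly greater than 1.
    """
    a = np.asarray(record.amplitudes, dtype=float)
    if a.size < 8:
        raise ValueError("need at least the 8 induction pulses")
    if not np.isfinite(a[0]) or a[0] <= 0:
        log.warning("connection %s flagged: first pulse amplitude <= 0", record.connection_id)
        nanv = np.full(a.size, np.nan)
        return STPMetrics(record.connection_id, np.nan, np.nan, np.nan, nanv,
                          "depressing", flagged=True)
    norm = a / a[0]
    ratios = {
        "ppr": norm[1],
        "ratio_1_8": norm[7],
        "ratio_1_6_8": norm[5:8].mean(),
    }
    call = "facilitating" if ratios[classify_by] > 1.0 else "depressing"
    early = norm[8] if a.size > 8 and record.recovery_delay == 0.25 else np.nan
    return STPMetrics(
        record.connection_id,
        ppr=float(ratios["ppr"]),
        ratio_1_8=float(ratios["ratio_1_8"]),
        ratio_1_6_8=float(ratios["ratio_1_6_8"]),
        normalized_train=norm,
        dynamics_call=call,
        early_recovery=float(early),
    )


def recovery_curve(records: list[ConnectionRecord]) -> RecoveryCurve:
    """Recovery-from-depression curve across delay conditions.

    ``records`` are the same connection measured at different
    ``recovery_delay`` values; the curve is the 9th-pulse amplitude divided
    by the 1st-pulse amplitude at each delay, sorted ascending.
    """
    if not records:
        raise ValueError("no records")
    ids = {r.connection_id for r in records}
    if len(ids) > 1:
        raise ValueError("recovery_curve expects one connection across delays")
    delays, vals = [], []
    for r in records:
        a = np.asarray(r.amplitudes, float)
        if a.size <= 8 or not np.isfinite(a[0]) or a[0] <= 0:
            continue
        delays.append(r.recovery_delay * 1e3)
        vals.append(a[8] / a[0])
    order = np.argsort(delays)
    return RecoveryCurve(
        records[0].connection_id,
        np.asarray(delays)[order],
        np.asarray(vals)[order],
    )


def build_heatmap(
    records: list[ConnectionRecord],
    frequency: float,
    prep: str | None = None,
) -> DynamicsHeatmap:
    """Cohort heatmap of normalised trains, rows sorted by first-pulse
    amplitude descending (ties broken by connection id for stability)."""
    sel = [r for r in records if r.frequency == frequency]
    if prep is not None:
        sel = [r for r in sel if r.prep == prep]
    if not sel:
        raise ValueError("no records for requested condition")
    firsts = np.array([r.amplitudes[0] for r in sel])
    order = sorted(range(len(sel)), key=lambda i: (-firsts[i], sel[i].connection_id))
    mat = np.vstack([sel[i].amplitudes / sel[i].amplitudes[0] for i in order])
    return DynamicsHeatmap(
        matrix=mat,
        connection_ids=[sel[i].connection_id for i in order],
        first_amplitudes=firsts[order],
        frequency=frequency,
        prep=prep,
    )


def frequency_comparison(
    records: list[ConnectionRecord],
    frequencies: tuple[float, float] = (20.0, 50.0),
    n_pulses: int = 8,
    classify_by: str = "ppr",
) -> pd.DataFrame:
    """Per-pulse mean ± s.e.m. of normalised trains per dynamics class per
    frequency.  Class membership is recomputed at each frequency — the same
    connection may be depressing at 50 Hz and facilitating at 20 Hz."""
    rows = []
    for freq in frequencies:
        sel = [r for r in records if r.frequency == freq]
        calls = {}
        for r in sel:
            m = compute_metrics(r, classify_by=classify_by)
            if not m.flagged:
                calls.setdefault(m.dynamics_call, []).append(m.normalized_train[:n_pulses])
        for cls in ("depressing", "facilitating"):
            trains = calls.get(cls)
            if not trains:
                warnings.warn(
                    f"no {cls} connections at {freq:g} Hz; summary omitted",
                    stacklevel=2,
                )
                continue
            trains = np.vstack(trains)
            for p in range(n_pulses):
                rows.append(
                    dict(
                        frequency=freq,
                        dynamics=cls,
                        pulse=p + 1,
                        mean=trains[:, p].mean(),
                        sem=trains[:, p].std(ddof=1) / np.sqrt(trains.shape[0])
                        if trains.shape[0] > 1
                        else np.nan,
                        n=trains.shape[0],
                    )
                )
    return pd.DataFrame(rows)


def ppr_vs_div(records: list[ConnectionRecord]):
    """OLS regression of PPR on days in vitro over culture connections.

    Tests whether short-term dynamics drift with time in organotypic
    culture; requires ≥3 culture records with DIV and PPR defined.
    """
    xs, ys = [], []
    for r in records:
        if r.prep != "culture" or not np.isfinite(r.div):
            continue
        m = compute_metrics(r)
        if not m.flagged:
            xs.append(r.div)
            ys.append(m.ppr)
    if len(xs) < 3:
        raise ValueError("need at least 3 culture records with DIV")
    return linear_regression(np.asarray(xs), np.asarray(ys))


def records_to_frame(records: list[ConnectionRecord]) -> pd.DataFrame:
    """Flatten records to a tidy table (one row per connection/condition)."""
    rows = []
    for r in records:
        row = dict(
            connection_id=r.connection_id,
            frequency=r.frequency,
            recovery_delay_ms=r.recovery_delay * 1e3,
            prep=r.prep,
            disease=r.disease,
            div=r.div,
            postsynaptic=r.postsynaptic,
        )
        for k, a in enumerate(r.amplitudes):
            row[f"amp_{k + 1}"] = a
        if r.first_epsp is not None:
            row.update(
                epsp_amplitude=r.first_epsp.amplitude,
                epsp_onset_ms=r.first_epsp.onset_delay,
                epsp_rise_ms=r.first_epsp.rise_time,
                epsp_decay_tau_ms=r.first_epsp.decay_tau,
            )
        rows.append(row)
    return pd.DataFrame(rows)
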