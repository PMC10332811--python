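"""EPSP extraction from paired sweeps: QC, averaging, feature measurement.

Turns multi-sweep paired recordings into per-connection averaged per-pulse
EPSP amplitudes with kinetic features of the first response.  Presynaptic
spike quality control replaces the original manual check with an automated
rule on spike slope and absolute peak; postsynaptic transmission failures
are deliberately *included* in the average, so mean amplitudes reflect
release probability as well as quantal size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .protocols import StimProtocol
from .sweeps import SweepSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCConfig:
    """Automated presynaptic spike quality control thresholds."""

    dvdt_threshold: float = 20.0  # V/s, minimum upstroke within the window
    min_peak: float = 0.0  # mV absolute, minimum spike peak
    window_ms: float = 5.0  # search window after each stimulus


@dataclass(frozen=True)
class MeasureConfig:
    """EPSP measurement conventions (all configurable, defaults logged)."""

    baseline_ms: float = 5.0  # pre-stimulus baseline window
    onset_sd_mult: float = 2.0  # onset = baseline + mult * baseline sd
    onset_sustain_ms: float = 0.5  # must stay above criterion this long
    rise_lo: float = 0.2  # rise-time bounds as fractions of amplitude
    rise_hi: float = 0.8
    fit_window_ms: float = 50.0  # decay-fit window cap after the peak
    smooth_ms: float = 1.0  # boxcar smoothing before measurement
    fit_start_frac: float = 0.95  # decay fit starts once below this * peak


@dataclass
class EPSPFeatures:
    amplitude: float  # mV
    onset_delay: float  # ms from presynaptic spike peak
    rise_time: float  # ms, 20-80% by default
    decay_tau: float  # ms; NaN when the fit fails
    fit_quality: float  # R^2 of the decay fit
    flags: list[str] = field(default_factory=list)


@dataclass
class ConnectionRecord:
    """Averaged per-pulse amplitudes plus metadata for one connection."""

    connection_id: str
    amplitudes: np.ndarray  # (n_pulses,) mV, failure-inclusive means
    frequency: float
    recovery_delay: float
    first_epsp: EPSPFeatures | None = None
    prep: str = "acute"  # {acute, culture}
    disease: str = "epilepsy"  # {epilepsy, tumor}
    div: float = np.nan  # days in vitro (culture only)
    postsynaptic: str = "unknown"
    flags: list[str] = field(default_factory=list)

    PREPS = ("acute", "culture")
    DISEASES = ("epilepsy", "tumor")
    IDENTITIES = (
        "PVALB",
        "SST",
        "VIP",
        "unknown",
        "predicted-PVALB",
        "predicted-nonPVALB",
        "uncertain",
    )

    def __post_init__(self) -> None:
        if self.prep not in self.PREPS:
            raise ValueError(f"prep must be one of {self.PREPS}")
        if self.disease not in self.DISEASES:
            raise ValueError(f"disease must be one of {self.DISEASES}")
        if self.postsynaptic not in self.IDENTITIES:
            raise ValueError(f"unknown postsynaptic identity {self.postsynaptic!r}")


def qc_presynaptic_spikes(
    sweeps: SweepSet, config: QCConfig = QCConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sweep, per-pulse spike QC → ``(passed, peak_times)``.

    A pulse passes when, within ``config.window_ms`` after its stimulus, the
    presynaptic trace reaches a dV/dt of at least ``config.dvdt_threshold``
    and a peak of at least ``config.min_peak`` (absolute mV).  ``peak_times``
    holds the spike-peak time (s) per sweep/pulse, NaN where QC failed.
    """
    sr = sweeps.sampling_rate
    win = int(config.window_ms * 1e-3 * sr)
    n_sweeps, n_pulses = sweeps.n_sweeps, sweeps.stim_times.size
    passed = np.zeros((n_sweeps, n_pulses), dtype=bool)
    peaks = np.full((n_sweeps, n_pulses), np.nan)
    for s in range(n_sweeps):
        v = sweeps.v_pre[s]
        dvdt = np.gradient(v) * sr * 1e-3  # mV/sample → V/s
        for k, t0 in enumerate(sweeps.stim_times):
            i0 = int(round(t0 * sr))
            seg = slice(i0, min(i0 + win, v.size))
            if v[seg].size < 2:
                continue
            if dvdt[seg].max() >= config.dvdt_threshold and v[seg].max() >= config.min_peak:
                passed[s, k] = True
                peaks[s, k] = (i0 + int(np.argmax(v[seg]))) / sr
    if not passed.any():
        log.warning("connection flagged: no QC-passing presynaptic spikes")
    return passed, peaks


def average_response(
    sweeps: SweepSet,
    passed: np.ndarray,
    peak_times: np.ndarray,
    window_ms: float | None = None,
    baseline_ms: float = 5.0,
) -> tuple[np.ndarray, float]:
    """Mean baseline-subtracted postsynaptic segment per pulse.

    Segments run from ``baseline_ms`` before to ``window_ms`` after each
    presynaptic spike peak and are averaged pointwise over QC-passing sweeps.
    Transmission failures are included.  Returns ``(segments, t0_offset)``
    where ``segments`` is (n_pulses, n_samples) and ``t0_offset`` (s) is the
    spike-peak position within each segment.
    """
    if not passed.any():
        raise ValueError("no QC-passing sweeps to average")
    sr = sweeps.sampling_rate
    if window_ms is None:
        isi_ms = 1e3 / sweeps.protocol.frequency
        window_ms = min(50.0, isi_ms * 0.95)
    pre = int(baseline_ms * 1e-3 * sr)
    post = int(window_ms * 1e-3 * sr)
    n_pulses = sweeps.stim_times.size
    out = np.full((n_pulses, pre + post), np.nan)
    for k in range(n_pulses):
        segs = []
        for s in range(sweeps.n_sweeps):
            if not passed[s, k]:
                continue
            ip = int(round(peak_times[s, k] * sr))
            if ip - pre < 0 or ip + post > sweeps.v_post.shape[1]:
                continue
            seg = sweeps.v_post[s, ip - pre : ip + post]
            segs.append(seg - seg[:pre].mean())
        if segs:
            out[k] = np.mean(segs, axis=0)
    return out, pre / sr


def measure_epsp(
    segment: np.ndarray,
    sampling_rate: float,
    peak_offset_s: float,
    config: MeasureConfig = MeasureConfig(),
) -> EPSPFeatures:
    """Measure one averaged EPSP aligned to the presynaptic spike peak.

    ``segment`` must contain ``peak_offset_s`` seconds of pre-spike baseline.
    Onset is the first sustained crossing of a noise-scaled criterion above
    baseline; amplitude is peak minus baseline; rise time spans the 20–80%
    amplitude levels; decay tau comes from a single-exponential fit from the
    peak, reported NaN (flagged) when the fit does not converge.
    """
    flags: list[str] = []
    sr = sampling_rate
    w = max(int(config.smooth_ms * 1e-3 * sr), 1)
    if w > 1:  # causal boxcar: suppresses peak-picking bias, keeps onsets late
        kernel = np.ones(w) / w
        padded = np.concatenate([np.full(w - 1, segment[0]), segment])
        segment = np.convolve(padded, kernel, mode="valid")
    ip = int(round(peak_offset_s * sr))
    nb = int(config.baseline_ms * 1e-3 * sr)
    base_seg = segment[max(0, ip - nb) : ip]
    baseline = base_seg.mean()
    base_sd = base_seg.std()

    resp = segment[ip:] - baseline
    peak_idx = int(np.argmax(resp))
    amplitude = float(resp[peak_idx])

    criterion = max(config.onset_sd_mult * base_sd, 1e-9)
    sustain = max(int(config.onset_sustain_ms * 1e-3 * sr), 1)
    above = resp > criterion
    onset_idx = None
    run = 0
    for i in range(peak_idx + 1):
        run = run + 1 if above[i] else 0
        if run >= sustain:
            onset_idx = i - sustain + 1
            break
    if onset_idx is None or amplitude <= criterion:
        flags.append("no-onset")
        return EPSPFeatures(max(amplitude, 0.0), np.nan, np.nan, np.nan, np.nan, flags)
    onset_delay = onset_idx / sr * 1e3

    # 20-80% rise time between onset and peak
    lo, hi = config.rise_lo * amplitude, config.rise_hi * amplitude
    seg_rise = resp[onset_idx : peak_idx + 1]
    t_lo = onset_idx + np.argmax(seg_rise >= lo)
    t_hi = onset_idx + np.argmax(seg_rise >= hi)
    rise_time = (t_hi - t_lo) / sr * 1e3

    # single-exponential decay fit, skipping the mixed rise/decay region
    # immediately around the peak
    fit_from = peak_idx
    while fit_from < resp.size - 1 and resp[fit_from] > config.fit_start_frac * amplitude:
        fit_from += 1
    fit_n = min(int(config.fit_window_ms * 1e-3 * sr), resp.size - fit_from)
    decay_tau, fit_q = np.nan, np.nan
    if fit_n > 5:
        t_ms = np.arange(fit_n) / sr * 1e3
        y = resp[fit_from : fit_from + fit_n]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    lambda t, a, tau: a * np.exp(-t / tau),
                    t_ms,
                    y,
                    p0=(amplitude, 10.0),
                    bounds=([0, 0.1], [np.inf, 1e3]),
                    maxfev=2000,
                )
            decay_tau = float(popt[1])
            resid = y - popt[0] * np.exp(-t_ms / popt[1])
            ss_tot = ((y - y.mean()) ** 2).sum()
            fit_q = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else np.nan
        except RuntimeError:
            flags.append("decay-fit-failed")
    else:
        flags.append("window-too-short")
    return EPSPFeatures(amplitude, onset_delay, rise_time, decay_tau, fit_q, flags)


def extract_connection(
    sweeps: SweepSet,
    connection_id: str = "conn",
    qc: QCConfig = QCConfig(),
    measure: MeasureConfig = MeasureConfig(),
    **metadata,
) -> ConnectionRecord:
    """Full per-connection pipeline: QC → average → per-pulse amplitudes."""
    passed, peaks = qc_presynaptic_spikes(sweeps, qc)
    flags = [] if passed.any() else ["qc-failed"]
    if not passed.any():
        return ConnectionRecord(
            connection_id,
            np.full(sweeps.stim_times.size, np.nan),
            sweeps.protocol.frequency,
            sweeps.protocol.recovery_delay,
            flags=flags,
            **metadata,
        )
    segments, t0 = average_response(sweeps, passed, peaks, baseline_ms=measure.baseline_ms)
    feats = [
        measure_epsp(segments[k], sweeps.sampling_rate, t0, measure)
        for k in range(segments.shape[0])
    ]
    amps = np.array([f.amplitude for f in feats])
    # kinetics from the first pulse, where the fit window is clean;
    # re-measure with a long window on the final pulse tail if needed
    return ConnectionRecord(
        connection_id,
        amps,
        sweeps.protocol.frequency,
        sweeps.protocol.recovery_delay,
        first_epsp=feats[0],
        flags=flags,
        **metadata,
    )


def exclude_polysynaptic(
    records: list[ConnectionRecord], max_onset_delay: float = 4.0
) -> list[ConnectionRecord]:
    """Drop connections whose first-EPSP onset delay exceeds the cutoff (ms).

    Long postsynaptic latencies indicate polysynaptic (indirect) responses.
    The cutoff is configurable; the number removed is logged.
    """
    kept = [
        r
        for r in records
        if r.first_epsp is not None
        and np.isfinite(r.first_epsp.onset_delay)
        and r.first_epsp.onset_delay <= max_onset_delay
    ]
    n_removed = len(records) - len(kept)
    log.info(
        "polysynaptic exclusion: removed %d of %d connections (cutoff %.1f ms)",
        n_removed,
        len(records),
        max_onset_delay,
    )
    if not kept and records:
        warnings.warn("all connections excluded as polysynaptic", stacklevel=2)
    return kept
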