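"""Intrinsic membrane feature extraction from current-clamp sweeps.

Subthreshold features (input resistance, sag, membrane time constant,
rheobase), train features (f-I slope, adaptation index, ISI adaptation
ratio), single-spike features measured on the first spike at rheobase
(threshold, height, width at half-height, upstroke/downstroke, AHP), spike
adaptation ratios (3rd vs 1st spike), and chirp impedance features (peak
frequency and peak ratio).  Missing protocols yield NaN features; the
classifier's imputation step handles them.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .cells import Sweep

SPIKE_DETECT_MV = -20.0  # spikes must peak above this
DVDT_THRESHOLD = 20.0  # V/s, spike threshold criterion


def detect_spikes(sweep: Sweep) -> np.ndarray:
    """Spike peak indices within the stimulus window."""
    v = sweep.voltage
    sr = sweep.sampling_rate
    i0, i1 = int(sweep.stim_start * sr), int(sweep.stim_end * sr)
    above = v > SPIKE_DETECT_MV
    peaks = []
    i = i0
    while i < min(i1 + int(0.01 * sr), v.size):
        if above[i]:
            j = i
            while j < v.size and above[j]:
                j += 1
            peaks.append(i + int(np.argmax(v[i:j])))
            i = j
        else:
            i += 1
    return np.asarray(peaks, dtype=int)


def _steady_state(sweep: Sweep) -> float:
    sr = sweep.sampling_rate
    i1 = int(sweep.stim_end * sr)
    n = int(0.1 * (sweep.stim_end - sweep.stim_start) * sr)
    return float(sweep.voltage[i1 - n : i1].mean())


def _baseline(sweep: Sweep) -> float:
    i0 = int(sweep.stim_start * sweep.sampling_rate)
    return float(sweep.voltage[: max(i0, 1)].mean())


def measure_spike(v: np.ndarray, peak_idx: int, sr: float) -> dict[str, float]:
    """Single-spike features around a peak index."""
    dvdt = np.gradient(v) * sr * 1e-3  # V/s
    # threshold: walk back from the maximum-upstroke point (dv/dt is ~0 at
    # the peak itself) to the last point below the dv/dt criterion
    lo = max(peak_idx - int(0.005 * sr), 0)
    up_idx = lo + int(np.argmax(dvdt[lo : peak_idx + 1])) if peak_idx > lo else peak_idx
    i = up_idx
    while i > 0 and dvdt[i - 1] >= DVDT_THRESHOLD:
        i -= 1
    thr_idx = i
    thr_v = v[thr_idx]
    peak_v = v[peak_idx]
    height = peak_v - thr_v
    half = thr_v + height / 2.0
    # width at half height
    i = peak_idx
    while i > thr_idx and v[i] > half:
        i -= 1
    left = i
    i = peak_idx
    while i < v.size - 1 and v[i] > half:
        i += 1
    right = i
    width = (right - left) / sr * 1e3
    win = slice(thr_idx, min(peak_idx + int(0.005 * sr), v.size))
    upstroke = float(dvdt[thr_idx:peak_idx + 1].max()) if peak_idx > thr_idx else np.nan
    downstroke = float(dvdt[win].min())
    ahp_win = v[peak_idx : peak_idx + int(0.01 * sr)]
    ahp = float(thr_v - ahp_win.min()) if ahp_win.size else np.nan
    return dict(
        threshold=float(thr_v),
        height=float(height),
        width=float(width),
        upstroke=upstroke,
        downstroke=downstroke,
        upstroke_downstroke_ratio=abs(upstroke / downstroke)
        if downstroke not in (0.0, np.nan)
        else np.nan,
        ahp=ahp,
    )


def extract_intrinsic_features(
    sweeps: list[Sweep], chirp: Sweep | None = None
) -> dict[str, float]:
    """Feature-table row from a set of long-square sweeps (+ optional chirp)."""
    feats = {k: np.nan for k in (
        "input_resistance", "sag", "rheobase", "membrane_tau",
        "fi_slope", "adaptation_index", "isi_adaptation_ratio",
        "upstroke_downstroke_ratio", "ahp", "spike_width", "spike_threshold",
        "spike_height", "upstroke_adaptation_ratio",
        "impedance_peak_freq", "impedance_peak_ratio",
    )}
    if len(sweeps) < 3:
        raise ValueError("need long-square sweeps at >= 3 current levels")
    spikes = {id(s): detect_spikes(s) for s in sweeps}
    sub = [s for s in sweeps if spikes[id(s)].size == 0]
    supra = [s for s in sweeps if spikes[id(s)].size > 0]

    # --- subthreshold: input resistance, tau, sag -----------------------
    if len(sub) >= 2:
        amps = np.array([s.amplitude for s in sub])
        dv = np.array([_steady_state(s) - _baseline(s) for s in sub])
        res = linregress(amps, dv)
        feats["input_resistance"] = float(res.slope * 1e3)  # mV/pA → MΩ
    hyper = [s for s in sub if s.amplitude < 0]
    if hyper:
        s = min(hyper, key=lambda s: s.amplitude)
        sr = s.sampling_rate
        i0 = int(s.stim_start * sr)
        base, ss = _baseline(s), _steady_state(s)
        v_min = s.voltage[i0 : int(s.stim_end * sr)].min()
        peak_defl, ss_defl = base - v_min, base - ss
        if peak_defl > 0:
            feats["sag"] = float((peak_defl - ss_defl) / peak_defl)
        # membrane tau from the step-onset charging curve
        n_fit = int(0.15 * sr)
        t_ms = np.arange(n_fit) / sr * 1e3
        y = s.voltage[i0 : i0 + n_fit]
        try:
            popt, _ = curve_fit(
                lambda t, v_inf, tau: v_inf + (base - v_inf) * np.exp(-t / tau),
                t_ms, y, p0=(ss, 20.0), maxfev=2000,
            )
            feats["membrane_tau"] = float(popt[1])
        except RuntimeError:
            pass

    # --- spike train features -------------------------------------------
    if supra:
        supra_sorted = sorted(supra, key=lambda s: s.amplitude)
        rheo_sweep = supra_sorted[0]
        feats["rheobase"] = float(rheo_sweep.amplitude)
        if len(supra) >= 2:
            rates, amps = [], []
            for s in supra:
                pk = spikes[id(s)]
                if pk.size >= 2:
                    rate = (pk.size - 1) / ((pk[-1] - pk[0]) / s.sampling_rate)
                else:
                    rate = pk.size / (s.stim_end - s.stim_start)
                rates.append(rate)
                amps.append(s.amplitude)
            if len(set(amps)) >= 2:
                feats["fi_slope"] = float(linregress(amps, rates).slope)
        # adaptation measured on the sweep with most spikes
        s_many = max(supra, key=lambda s: spikes[id(s)].size)
        pk = spikes[id(s_many)]
        if pk.size >= 3:
            isi = np.diff(pk) / s_many.sampling_rate
            feats["adaptation_index"] = float(
                np.mean((isi[1:] - isi[:-1]) / (isi[1:] + isi[:-1]))
            )
            feats["isi_adaptation_ratio"] = float(isi[1] / isi[0])
            sp1 = measure_spike(s_many.voltage, pk[0], s_many.sampling_rate)
            sp3 = measure_spike(s_many.voltage, pk[2], s_many.sampling_rate)
            if sp1["upstroke"] and np.isfinite(sp1["upstroke"]):
                feats["upstroke_adaptation_ratio"] = sp3["upstroke"] / sp1["upstroke"]
        # single-spike features: first spike at rheobase
        pk0 = spikes[id(rheo_sweep)]
        sp = measure_spike(rheo_sweep.voltage, pk0[0], rheo_sweep.sampling_rate)
        feats["spike_threshold"] = sp["threshold"]
        feats["spike_height"] = sp["height"]
        feats["spike_width"] = sp["width"]
        feats["upstroke_downstroke_ratio"] = sp["upstroke_downstroke_ratio"]
        feats["ahp"] = sp["ahp"]

    # --- chirp impedance -------------------------------------------------
    if chirp is not None:
        f, z = impedance_profile(chirp)
        peak = int(np.argmax(z))
        feats["impedance_peak_freq"] = float(f[peak])
        feats["impedance_peak_ratio"] = float(z[peak] / z[0])
    return feats


def impedance_profile(
    chirp: Sweep, f_lo: float = 0.5, f_hi: float = 20.0, smooth_hz: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Impedance magnitude |FFT(V)/FFT(I)| over the chirp band (MΩ)."""
    v = chirp.voltage - chirp.voltage.mean()
    i = chirp.current - chirp.current.mean()
    n = v.size
    freqs = np.fft.rfftfreq(n, d=1.0 / chirp.sampling_rate)
    z = np.abs(np.fft.rfft(v) / np.fft.rfft(i)) * 1e3  # mV/pA → MΩ
    band = (freqs >= f_lo) & (freqs <= f_hi)
    f, z = freqs[band], z[band]
    # box smoothing over ~smooth_hz
    df = f[1] - f[0] if f.size > 1 else 1.0
    w = max(int(smooth_hz / df), 1)
    if w > 1:
        kernel = np.ones(w) / w
        z = np.convolve(z, kernel, mode="same")
    return f, z
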