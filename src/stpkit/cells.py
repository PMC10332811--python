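"""Phenomenological single-cell models for intrinsic-property sweeps.

These generators produce the long-square and chirp current-clamp sweeps from
which intrinsic membrane features are extracted, with every generating
parameter known, so feature extraction can be scored against ground truth.
The membrane is an RC compartment with an optional slow sag conductance;
spiking is phenomenological (a stereotyped waveform pasted at rate-model
spike times), not conductance-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

REST_MV = -70.0


@dataclass(frozen=True)
class CellParams:
    """Ground-truth intrinsic parameters of a simulated cell."""

    input_resistance: float = 150.0  # MΩ
    membrane_tau: float = 20.0  # ms
    sag_ratio: float = 0.0  # (peak - steady) / peak deflection, hyperpolarizing
    sag_tau: float = 120.0  # ms, slow relaxation
    rheobase: float = 100.0  # pA
    fi_slope: float = 0.5  # Hz / pA above rheobase
    adaptation: float = 0.0  # fractional ISI growth per interval
    spike_threshold: float = -45.0  # mV
    spike_height: float = 75.0  # mV, threshold → peak
    spike_width: float = 1.0  # ms at half height
    ahp_depth: float = 12.0  # mV below threshold
    spike_adaptation: float = 1.0  # multiplies height of 3rd vs 1st spike


@dataclass
class Sweep:
    """One current-clamp sweep: time (s), stimulus (pA), voltage (mV)."""

    time: np.ndarray
    current: np.ndarray
    voltage: np.ndarray
    sampling_rate: float
    stim_start: float
    stim_end: float
    amplitude: float  # step amplitude (pA); 0 for chirp


def _spike_waveform(
    cell: CellParams, height: float, sampling_rate: float
) -> tuple[np.ndarray, int]:
    """Stereotyped spike (mV, relative to threshold) and its peak index."""
    dt_ms = 1e3 / sampling_rate
    rise_ms = cell.spike_width * 0.8
    fall_ms = cell.spike_width * 1.2
    ahp_ms = 10.0
    ramp_ms = 0.3  # slow approach to threshold, below dV/dt detection
    t_ramp = np.arange(0, ramp_ms, dt_ms)
    t_rise = np.arange(0, rise_ms, dt_ms)
    t_fall = np.arange(dt_ms, fall_ms + dt_ms, dt_ms)
    t_ahp = np.arange(dt_ms, ahp_ms, dt_ms)
    ramp = -2.0 + 2.0 * t_ramp / ramp_ms
    rise = height * np.sin(np.pi / 2 * t_rise / rise_ms) ** 2
    fall = height - (height + cell.ahp_depth) * np.sin(
        np.pi / 2 * t_fall / fall_ms
    ) ** 2
    ahp = -cell.ahp_depth * np.exp(-t_ahp / 5.0)
    w = np.concatenate([ramp, rise, fall, ahp])
    return w, int(np.argmax(w))


def _subthreshold_deflection(
    cell: CellParams, amplitude_pa: float, t_ms: np.ndarray
) -> np.ndarray:
    """Step-evoked deflection (mV) at ``t_ms`` after step onset."""
    r_gohm = cell.input_resistance * 1e-3  # MΩ·pA = µV → GΩ·pA = mV
    full = r_gohm * amplitude_pa
    d = full * (1.0 - np.exp(-t_ms / cell.membrane_tau))
    if cell.sag_ratio > 0 and amplitude_pa < 0:
        # after the membrane has charged (5 tau), relax toward the reduced
        # steady state with the slow sag time constant; keeps the measured
        # (peak - steady) / peak ratio close to the nominal sag_ratio
        t_x = 5.0 * cell.membrane_tau
        ss = full * (1.0 - cell.sag_ratio)
        d_x = full * (1.0 - np.exp(-t_x / cell.membrane_tau))
        late = t_ms >= t_x
        d[late] = ss + (d_x - ss) * np.exp(-(t_ms[late] - t_x) / cell.sag_tau)
    return d


def simulate_long_square(
    cell: CellParams,
    amplitude_pa: float,
    duration: float = 1.0,
    stim_start: float = 0.1,
    stim_dur: float = 0.6,
    sampling_rate: float = 50_000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Sweep:
    """Simulate one long-square current-step sweep.

    Below rheobase the response is the (sag-modified) RC step response;
    at or above rheobase, spikes are pasted at rate-model times
    ``f = fi_slope * (I - rheobase)`` with ISIs growing by the adaptation
    factor, and the 3rd and later spikes scaled by ``spike_adaptation``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    time = np.arange(n) / sampling_rate
    current = np.zeros(n)
    i0, i1 = int(stim_start * sampling_rate), int((stim_start + stim_dur) * sampling_rate)
    current[i0:i1] = amplitude_pa

    v = np.full(n, REST_MV)
    t_ms_on = (time[i0:i1] - stim_start) * 1e3
    v[i0:i1] += _subthreshold_deflection(cell, amplitude_pa, t_ms_on)
    # off-relaxation back to rest
    d_end = v[i1 - 1] - REST_MV if i1 > i0 else 0.0
    t_ms_off = (time[i1:] - (stim_start + stim_dur)) * 1e3
    v[i1:] += d_end * np.exp(-t_ms_off / cell.membrane_tau)

    spiking = amplitude_pa >= cell.rheobase
    if spiking:
        rate = max(cell.fi_slope * (amplitude_pa - cell.rheobase), 1.0 / stim_dur)
        isi = 1.0 / rate
        # depolarised plateau just below threshold while spiking
        v[i0:i1] = cell.spike_threshold - 2.0
        t_spk = stim_start + 0.6 * isi
        k = 0
        while t_spk < stim_start + stim_dur:
            height = cell.spike_height * (cell.spike_adaptation if k >= 2 else 1.0)
            w, _ = _spike_waveform(cell, height, sampling_rate)
            j = int(round(t_spk * sampling_rate))
            seg = min(w.size, n - j)
            v[j : j + seg] = cell.spike_threshold + w[:seg]
            t_spk += isi * (1.0 + cell.adaptation * k)
            k += 1
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n)
    return Sweep(time, current, v, sampling_rate, stim_start, stim_start + stim_dur,
                 amplitude_pa)


def simulate_chirp(
    cell: CellParams,
    sag_conductance: float = 0.0,
    f0: float = 0.2,
    f1: float = 20.0,
    duration: float = 20.0,
    amplitude_pa: float = 20.0,
    sampling_rate: float = 2_000.0,
) -> Sweep:
    """Subthreshold response to a logarithmic chirp stimulus.

    The membrane is the linear RC compartment plus an optional slow negative
    feedback (sag/Ih-like) of strength ``sag_conductance`` (nS) and time
    constant ``cell.sag_tau``, which produces subthreshold resonance:

        Z(s) = (1 + tau_h s) / ((g_L + g_h) + (g_L tau_h + C) s + C tau_h s^2)

    with g_L = 1/R (nS when R is in GΩ), C = tau_m / R.
    """
    n = int(duration * sampling_rate)
    time = np.arange(n) / sampling_rate
    stim = amplitude_pa * signal.chirp(time, f0=f0, f1=f1, t1=duration, method="logarithmic")
    r_gohm = cell.input_resistance * 1e-3
    g_l = 1.0 / r_gohm  # nS
    c = cell.membrane_tau * 1e-3 / r_gohm  # nF
    tau_h = cell.sag_tau * 1e-3  # s
    g_h = sag_conductance
    num = [tau_h, 1.0]
    den = [c * tau_h, g_l * tau_h + c, g_l + g_h]
    sys = signal.TransferFunction(num, den)
    _, v, _ = signal.lsim(sys, U=stim, T=time)
    return Sweep(time, stim, REST_MV + v, sampling_rate, 0.0, duration, 0.0)
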