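"""Rendering of paired current-clamp sweeps for simulated connections.

Each sweep holds a presynaptic trace (stereotyped action-potential waveforms
at the stimulus times) and a postsynaptic trace (a sum of difference-of-
exponential EPSP waveforms riding on a noisy baseline).  Ground truth —
per-pulse mean amplitudes, per-sweep transmission failures and the EPSP
kinetics — is returned alongside so that extraction code can be scored
against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocols import StimProtocol
from .release import ReleaseModelParams, simulate_release_train

RESTING_POTENTIAL_MV = -70.0

# Presynaptic spike template: ~2 ms triangular-exponential waveform, 100 mV
# amplitude (peak +30 mV from -70 mV rest) so automated QC thresholds on
# dV/dt and absolute peak are comfortably exceeded by intact spikes.
SPIKE_RISE_MS = 0.6
SPIKE_DECAY_TAU_MS = 0.5
SPIKE_AMPLITUDE_MV = 100.0
SPIKE_TEMPLATE_MS = 4.0


@dataclass(frozen=True)
class EPSPKinetics:
    """Shape of the postsynaptic potential.

    ``tau_rise`` and ``tau_decay`` (ms) parameterise a difference of
    exponentials, normalised so the waveform peak equals the requested
    amplitude; ``onset_delay`` (ms) is measured from the presynaptic spike
    peak to EPSP onset (synaptic latency).
    """

    tau_rise: float = 2.0
    tau_decay: float = 20.0
    onset_delay: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("require 0 < tau_rise < tau_decay")
        if self.onset_delay < 0:
            raise ValueError("onset_delay must be non-negative")

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        """Unit-peak EPSP waveform evaluated at ``t_ms`` after onset."""
        tr, td = self.tau_rise, self.tau_decay
        t_peak = tr * td / (td - tr) * np.log(td / tr)
        peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
        w = np.where(t_ms >= 0, np.exp(-t_ms / td) - np.exp(-t_ms / tr), 0.0)
        return w / peak


def spike_waveform(t_ms: np.ndarray) -> np.ndarray:
    """Stereotyped action-potential waveform (mV above rest) at ``t_ms``.

    Linear rise over ``SPIKE_RISE_MS`` to ``SPIKE_AMPLITUDE_MV``, then an
    exponential repolarisation.  Only the peak time is consumed downstream.
    """
    rise = SPIKE_AMPLITUDE_MV * t_ms / SPIKE_RISE_MS
    decay = SPIKE_AMPLITUDE_MV * np.exp(-(t_ms - SPIKE_RISE_MS) / SPIKE_DECAY_TAU_MS)
    w = np.where(t_ms < SPIKE_RISE_MS, rise, decay)
    return np.where((t_ms >= 0) & (t_ms <= SPIKE_TEMPLATE_MS), w, 0.0)


@dataclass
class SweepSet:
    """Paired voltage sweeps for one connection under one protocol."""

    time: np.ndarray  # (n_samples,) seconds
    v_pre: np.ndarray  # (n_sweeps, n_samples) mV
    v_post: np.ndarray  # (n_sweeps, n_samples) mV
    stim_times: np.ndarray  # (n_pulses,) seconds
    protocol: StimProtocol
    sampling_rate: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_sweeps(self) -> int:
        return self.v_pre.shape[0]


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery scoring."""

    mean_amplitudes: np.ndarray  # (n_pulses,) mV, deterministic release model
    success: np.ndarray  # (n_sweeps, n_pulses) bool, False = transmission failure
    kinetics: EPSPKinetics
    spike_peak_times: np.ndarray  # (n_pulses,) seconds
    params: ReleaseModelParams


def render_sweeps(
    amplitudes: np.ndarray,
    kinetics: EPSPKinetics,
    protocol: StimProtocol,
    params: ReleaseModelParams,
    sampling_rate: float = 20_000.0,
    seed: int = 0,
) -> tuple[SweepSet, GroundTruth]:
    """Render paired sweeps from per-pulse mean amplitudes.

    Per sweep, each pulse releases with probability ``1 - params.p_fail``; on
    success an EPSP of the deterministic mean amplitude is added at
    spike-peak time + ``kinetics.onset_delay``.  Gaussian noise of standard
    deviation ``params.noise_sd`` is added to every postsynaptic sample.
    Failures leave the trace flat (noise only), mimicking real transmission
    failures which are *included* when sweeps are averaged downstream.
    """
    rng = np.random.default_rng(seed)
    amplitudes = np.asarray(amplitudes, dtype=float)
    stim = protocol.pulse_times()
    if amplitudes.shape != stim.shape:
        raise ValueError("one amplitude per protocol pulse required")

    dt = 1.0 / sampling_rate
    n = int(round(protocol.sweep_duration() * sampling_rate))
    time = np.arange(n) * dt
    spike_peaks = stim + SPIKE_RISE_MS * 1e-3

    # presynaptic template trace, identical across sweeps
    pre = np.full(n, RESTING_POTENTIAL_MV)
    tmpl_len = int(SPIKE_TEMPLATE_MS * 1e-3 * sampling_rate) + 1
    tmpl = spike_waveform(np.arange(tmpl_len) * dt * 1e3)
    for t0 in stim:
        i0 = int(round(t0 * sampling_rate))
        pre[i0 : i0 + tmpl_len] += tmpl[: n - i0]

    # EPSP kernel long enough to decay to <1e-4 of peak
    kern_ms = kinetics.tau_decay * 10.0
    kern_len = int(kern_ms * 1e-3 * sampling_rate)
    kern = kinetics.waveform(np.arange(kern_len) * dt * 1e3)

    n_sweeps = protocol.n_sweeps
    success = rng.random((n_sweeps, stim.size)) >= params.p_fail
    v_post = rng.normal(0.0, params.noise_sd, size=(n_sweeps, n))
    v_post += RESTING_POTENTIAL_MV
    onset_idx = np.round(
        (spike_peaks + kinetics.onset_delay * 1e-3) * sampling_rate
    ).astype(int)
    for s in range(n_sweeps):
        for k, i0 in enumerate(onset_idx):
            if success[s, k]:
                seg = min(kern_len, n - i0)
                v_post[s, i0 : i0 + seg] += amplitudes[k] * kern[:seg]

    sweeps = SweepSet(
        time=time,
        v_pre=np.tile(pre, (n_sweeps, 1)),
        v_post=v_post,
        stim_times=stim,
        protocol=protocol,
        sampling_rate=sampling_rate,
    )
    truth = GroundTruth(
        mean_amplitudes=amplitudes,
        success=success,
        kinetics=kinetics,
        spike_peak_times=spike_peaks,
        params=params,
    )
    return sweeps, truth


def simulate_connection(
    params: ReleaseModelParams,
    protocol: StimProtocol,
    kinetics: EPSPKinetics | None = None,
    sampling_rate: float = 20_000.0,
    seed: int = 0,
) -> tuple[SweepSet, GroundTruth]:
    """Release model + rendering in one step (the usual entry point)."""
    kinetics = kinetics or EPSPKinetics()
    amps = simulate_release_train(params, protocol.pulse_times())
    return render_sweeps(amps, kinetics, protocol, params, sampling_rate, seed)
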