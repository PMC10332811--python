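"""Two-variable depression–facilitation model of synaptic release.

A presynaptic terminal is summarised by a releasable-resource fraction ``R``
(depleted by release, recovering with time constant ``tau_rec``) and a
utilisation variable ``u`` (incremented by each spike, decaying back to its
resting value ``U`` with time constant ``tau_facil``).  The EPSP evoked by
spike *k* has mean amplitude ``A * u_k * R_k``.  Large ``U`` with slow
resource recovery yields depressing trains; small ``U`` with slow facilitation
decay yields facilitating trains — the two phenotypes seen at pyramidal →
PVALB and pyramidal → SST/non-PVALB connections respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ReleaseModelParams:
    """Parameters of the release model plus trial-to-trial variability.

    ``U`` is the resting release fraction (unitless, in (0, 1]); ``tau_rec``
    and ``tau_facil`` are the resource-recovery and facilitation-decay time
    constants in seconds; ``A`` is the absolute synaptic efficacy in mV (the
    EPSP amplitude if all resources were released at once); ``p_fail`` is the
    per-pulse probability of complete transmission failure and ``noise_sd``
    the additive Gaussian amplitude noise (mV), both applied at rendering
    time, not in the deterministic recursion.
    """

    U: float
    tau_rec: float
    tau_facil: float
    A: float = 1.0
    p_fail: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.U <= 1.0:
            raise ValueError("U must be in (0, 1]")
        if self.tau_rec <= 0 or self.tau_facil <= 0:
            raise ValueError("time constants must be positive")
        if self.A <= 0:
            raise ValueError("A must be positive")
        if not 0.0 <= self.p_fail < 1.0:
            raise ValueError("p_fail must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_release_train(
    params: ReleaseModelParams, pulse_times: np.ndarray
) -> np.ndarray:
    """Deterministic per-pulse mean EPSP amplitudes (mV) for a spike train.

    The discrete recursion integrates the inter-spike dynamics exactly:
    with ``u_1 = U`` and ``R_1 = 1``, amplitude_k = ``A * u_k * R_k`` and for
    inter-spike interval ``dt``::

        u_{k+1} = U + u_k * (1 - U) * exp(-dt / tau_facil)
        R_{k+1} = 1 - (1 - R_k * (1 - u_k)) * exp(-dt / tau_rec)

    Failures and amplitude noise are *not* applied here; see
    :func:`stpkit.sweeps.render_sweeps`.
    """
    pulse_times = np.asarray(pulse_times, dtype=float)
    if pulse_times.ndim != 1 or pulse_times.size == 0:
        raise ValueError("pulse_times must be a non-empty 1-D array")
    if pulse_times.size > 1 and np.any(np.diff(pulse_times) <= 0):
        raise ValueError("pulse_times must be strictly increasing")

    U, tau_r, tau_f = params.U, params.tau_rec, params.tau_facil
    u, R = U, 1.0
    amps = np.empty(pulse_times.size)
    for k in range(pulse_times.size):
        amps[k] = params.A * u * R
        if k + 1 < pulse_times.size:
            dt = pulse_times[k + 1] - pulse_times[k]
            R_post = R * (1.0 - u)  # resources consumed by this spike
            u_post = U + u * (1.0 - U)  # facilitation increment
            u = U + (u_post - U) * np.exp(-dt / tau_f)
            R = 1.0 - (1.0 - R_post) * np.exp(-dt / tau_r)
    return amps


# Canonical parameter regimes used throughout the synthetic cohorts.  They are
# chosen to bracket the depressing (high initial release probability, slow
# resource recovery) and facilitating (low initial release, slow facilitation
# decay) phenotypes of pyramidal→PVALB and pyramidal→non-PVALB connections.
DEPRESSING_PARAMS = dict(U=0.5, tau_rec=0.5, tau_facil=0.01)
FACILITATING_PARAMS = dict(U=0.1, tau_rec=0.05, tau_facil=0.5)
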