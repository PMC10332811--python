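"""Pulse-train stimulation protocols for synaptic connectivity assays.

The standard assay drives a presynaptic pyramidal neuron with an induction
train (8 pulses at 10/20/50/100 Hz) followed by recovery pulses (4 pulses at
the train frequency) after a variable delay, repeated across sweeps with a
long inter-sweep interval so that short-term plasticity resets between sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recovery delays (seconds) interposed between induction and recovery pulses
#: when probing recovery from depression at 50 Hz.
RECOVERY_DELAYS_S: tuple[float, ...] = (0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0)

#: Induction-train frequencies (Hz) used in the connectivity assay.
TRAIN_FREQUENCIES_HZ: tuple[float, ...] = (10.0, 20.0, 50.0, 100.0)


@dataclass(frozen=True)
class StimProtocol:
    """Timing specification of one induction + recovery pulse train.

    Parameters
    ----------
    frequency : float
        Train frequency in Hz. Any positive value is accepted; the assay
        uses 10, 20, 50 and 100 Hz.
    n_induction : int
        Number of induction pulses (default 8).
    n_recovery : int
        Number of recovery pulses delivered after ``recovery_delay`` (default 4).
    recovery_delay : float
        Interval in seconds between the last induction pulse and the first
        recovery pulse.
    inter_sweep_interval : float
        Seconds between sweep starts (default 15 s).
    n_sweeps : int
        Number of repetitions of the train.
    """

    frequency: float
    n_induction: int = 8
    n_recovery: int = 4
    recovery_delay: float = 0.25
    inter_sweep_interval: float = 15.0
    n_sweeps: int = 10
    start_time: float = field(default=0.1, repr=False)

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.recovery_delay <= 0:
            raise ValueError("recovery_delay must be positive")
        if self.n_induction < 1 or self.n_recovery < 0:
            raise ValueError("pulse counts invalid")

    @property
    def n_pulses(self) -> int:
        return self.n_induction + self.n_recovery

    def pulse_times(self) -> np.ndarray:
        """Stimulus times (s) within one sweep, strictly increasing."""
        isi = 1.0 / self.frequency
        induction = self.start_time + isi * np.arange(self.n_induction)
        rec_start = induction[-1] + self.recovery_delay
        recovery = rec_start + isi * np.arange(self.n_recovery)
        return np.concatenate([induction, recovery])

    def sweep_duration(self) -> float:
        """Total trace duration (s), leaving a tail after the last pulse."""
        return float(self.pulse_times()[-1] + 0.2)
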