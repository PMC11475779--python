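"""Charge-balanced biphasic stimulation pulse.

The protocol pulse is cathodic-leading: 80 us at -A immediately followed
by 160 us at +A/2, so the net charge is exactly zero.  Waveforms are
sampled at the 5 us integration step over the 10 ms protocol window, with
the pulse onset 1 ms into the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PulseWaveform:
    cathodic_duration: float = 0.080  # ms
    anodic_duration: float = 0.160  # ms
    anodic_fraction: float = 0.5  # anodic amplitude = fraction * A
    onset: float = 1.0  # ms
    dt: float = 0.005  # ms
    duration: float = 10.0  # ms

    def sample(self, amplitude_ua: float) -> np.ndarray:
        """Current (uA) at step edges t = 0, dt, ..., duration."""
        if amplitude_ua < 0:
            raise ValueError("amplitude must be >= 0")
        nsteps = int(round(self.duration / self.dt))
        t = np.arange(nsteps + 1) * self.dt
        w = np.zeros(nsteps + 1)
        c0, c1 = self.onset, self.onset + self.cathodic_duration
        a1 = c1 + self.anodic_duration
        w[(t >= c0) & (t < c1)] = -amplitude_ua
        w[(t >= c1) & (t < a1)] = self.anodic_fraction * amplitude_ua
        return w

    def charge(self, amplitude_ua: float) -> float:
        """Net charge (uA*ms) of the sampled pulse; exactly zero.

        Each phase is summed separately (identical samples sum exactly in
        floating point) so the cathodic and anodic charges cancel to the
        last bit for any amplitude.
        """
        w = self.sample(amplitude_ua)[:-1]
        return float((np.sum(w[w < 0]) + np.sum(w[w > 0])) * self.dt)


def make_waveform(
    amplitude_ua: float,
    dt: float = 0.005,
    duration: float = 10.0,
    onset: float = 1.0,
) -> np.ndarray:
    """Sampled protocol pulse at the given amplitude (uA)."""
    return PulseWaveform(dt=dt, duration=duration, onset=onset).sample(amplitude_ua)
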