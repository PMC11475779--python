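"""Action-potential metrics and conduction-velocity measurement."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cable import integrate, resting_state
from .morphology import BR_PERIPHERAL, CompartmentModel

SPIKE_DETECT_MV = 0.0  # upward crossing that counts as a spike


@dataclass
class APMetrics:
    """Shape metrics of a single action potential.

    amplitude: resting-to-peak (mV); duration: spike width (ms) per the
    configured convention (base-to-base by default); ahp: resting-to-trough
    after the spike (mV); all None when no suprathreshold excursion.
    """

    amplitude: float | None = None
    duration: float | None = None
    ahp: float | None = None

    @property
    def has_spike(self) -> bool:
        return self.amplitude is not None


BASE_OFFSET_MV = 1.0  # base-duration level above rest


def measure_ap_metrics(
    trace: np.ndarray,
    dt: float,
    resting: float,
    duration_mode: str = "base",
) -> APMetrics:
    """Measure amplitude, duration and AHP of the first spike in a trace.

    ``duration_mode`` selects the width convention: "base" (default) is the
    base-to-base duration, measured where the trace crosses 1 mV above the
    resting potential; "half_width" is the width at half-maximal amplitude.
    """
    v = np.asarray(trace, dtype=float)
    if v.max() < SPIKE_DETECT_MV:
        return APMetrics()
    peak_i = int(np.argmax(v))
    amplitude = float(v[peak_i] - resting)
    ahp = float(resting - v[peak_i:].min())
    ahp = max(ahp, 0.0)

    if duration_mode == "half_width":
        level = resting + amplitude / 2.0
    elif duration_mode == "base":
        level = resting + BASE_OFFSET_MV
    else:
        raise ValueError(f"unknown duration_mode {duration_mode!r}")

    t_up = _crossing_time(v, level, peak_i, dt, direction=-1)
    t_down = _crossing_time(v, level, peak_i, dt, direction=+1)
    duration = t_down - t_up if (t_up is not None and t_down is not None) else None
    return APMetrics(amplitude=amplitude, duration=duration, ahp=ahp)


def _crossing_time(v, level, peak_i, dt, direction):
    """Sub-sample time where v crosses `level`, scanning from the peak."""
    if direction < 0:
        rng = range(peak_i, 0, -1)
    else:
        rng = range(peak_i, len(v) - 1)
    for i in rng:
        a, b = (v[i - 1], v[i]) if direction < 0 else (v[i], v[i + 1])
        if (a - level) * (b - level) <= 0 and a != b:
            frac = (level - a) / (b - a)
            i0 = (i - 1) if direction < 0 else i
            return (i0 + frac) * dt
    return None


def spike_time(trace: np.ndarray, dt: float, level: float = SPIKE_DETECT_MV):
    """Time of the first upward crossing of `level`, linearly interpolated."""
    v = np.asarray(trace, dtype=float)
    above = v >= level
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return None
    i = int(idx[0])
    frac = (level - v[i]) / (v[i + 1] - v[i])
    return (i + frac) * dt


def measure_cv(
    model: CompartmentModel,
    node_a: int | None = None,
    node_b: int | None = None,
    stim_node: int | None = None,
    stim_amp_na: float = 4000.0,
    dt: float = 0.005,
    duration: float = 10.0,
    branch: int = BR_PERIPHERAL,
) -> float:
    """Conduction velocity (m/s) from two-point spike timing.

    By default the stimulus is injected at a distal node of the chosen
    branch and arrival is timed at two mid-axon nodes at least 10 internodes
    apart and 10 internodes from the stimulated node, branch points and
    ends.  Node arguments are indices into ``model.node_indices(branch)``.
    """
    nodes = model.node_indices(branch)
    if nodes.size < 35:
        raise ValueError("branch too short for a CV measurement")
    if stim_node is None:
        stim_node = nodes.size - 3
    if node_a is None:
        node_a = 12
    if node_b is None:
        node_b = stim_node - 12
    for name, k in (("node_a", node_a), ("node_b", node_b)):
        if abs(k - stim_node) < 10:
            raise ValueError(f"{name} too close to the stimulated node")
    if abs(node_b - node_a) < 10:
        raise ValueError("measurement nodes closer than 10 internodes")
    ca, cb, cs = nodes[node_a], nodes[node_b], nodes[stim_node]
    vi, vp, gates = resting_state(model, cache_key=("cv", model.fiber_diameter,
                                                    branch, model.n))
    res = integrate(
        model, state=(vi, vp, gates),
        istim=(cs, stim_amp_na, 0.5, 0.6),
        dt=dt, duration=duration, record=np.array([ca, cb]),
    )
    ta = spike_time(res.traces[0], dt)
    tb = spike_time(res.traces[1], dt)
    if ta is None or tb is None:
        raise RuntimeError("spike did not reach both measurement nodes")
    dist_um = abs(model.arc[ca] - model.arc[cb])
    dt_ms = abs(ta - tb)
    return (dist_um * 1e-6) / (dt_ms * 1e-3)  # m/s
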