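"""Extracellular stimulation, activation detection and threshold search.

A neuron is considered activated when a propagating spike is present: some
compartment crosses the 0 mV detection level and at least five consecutive
nodes of Ranvier along one axon branch spike.  The initiation site is the
compartment with the earliest crossing (ties broken by maximal dV/dt, then
lowest compartment index), mapped onto the five reporting categories
{AIS, stem, t-junction, pseudounipolar axon, axon of passage}.  Somatic
crossings are never reported as initiation sites; if the soma crosses
first it is surfaced as a diagnostic and the earliest non-somatic site is
reported.

Thresholds are found by a bisection on stimulation amplitude (geometric
midpoints, assuming a monotone response) to a 1% relative bracket.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..neuron.cable import EARLY_QUIET, SimResult, integrate, resting_state
from ..neuron.morphology import SITE_SOMA, CompartmentModel
from ..volume.field import PotentialField
from .waveform import PulseWaveform

PROPAGATION_NODES = 5  # consecutive spiking axonal nodes required


@dataclass
class InitiationRecord:
    neuron_id: int
    site: str
    compartment: int
    time: float  # ms
    location: tuple | None = None  # mm
    distance_to_electrode: float | None = None  # mm
    soma_crossed_first: bool = False


@dataclass
class ThresholdResult:
    neuron_id: int
    threshold: float | None  # uA; None if not activated at the upper bound
    lower: float
    upper: float
    tolerance: float
    activated: bool
    initiation: InitiationRecord | None = None
    activated_at_lower_bound: bool = False


def compartment_potentials(model: CompartmentModel, fld: PotentialField) -> np.ndarray:
    """Unit transfer potential (V per mA) at each compartment.

    Compartments outside the solved volume (distal axon ends far along the
    roots) see zero potential; the field there has decayed to the grounded
    far-field level.
    """
    if model.coords is None:
        raise ValueError("model has no coordinates; call pose_coordinates first")
    pts = model.coords
    lo = np.array([ax[0] for ax in fld.axes])
    hi = np.array([ax[-1] for ax in fld.axes])
    inside = np.all((pts >= lo) & (pts <= hi), axis=1)
    phi = np.zeros(model.n)
    if inside.any():
        phi[inside] = fld.interpolate(pts[inside])
    return phi


def apply_stimulus(
    model: CompartmentModel,
    fld: PotentialField | np.ndarray,
    amplitude_ua: float,
    pulse: PulseWaveform | None = None,
    state=None,
    record=False,
    early_stop: bool = True,
) -> SimResult:
    """Integrate the neuron under the protocol pulse at a given amplitude.

    ``fld`` may be a solved PotentialField or a precomputed per-compartment
    unit-potential vector.  The per-compartment extracellular drive is the
    unit potential times the sampled pulse current.
    """
    pulse = pulse or PulseWaveform()
    unit_phi = (
        fld if isinstance(fld, np.ndarray) else compartment_potentials(model, fld)
    )
    wave = pulse.sample(amplitude_ua)
    if state is None:
        state = resting_state(model)
    quiet = pulse.onset + pulse.cathodic_duration + pulse.anodic_duration + 1.25
    return integrate(
        model,
        state=state,
        unit_phi=unit_phi,
        wave=wave,
        dt=pulse.dt,
        duration=pulse.duration,
        record=record,
        quiet_after=quiet if early_stop else None,
        # a spike spreading through the t-junction fills both branches in
        # parallel, so require enough crossings for a 5-node run on one
        stop_after_nodes=(2 * PROPAGATION_NODES + 4) if early_stop else 0,
    )


def detect_activation(
    result: SimResult,
    model: CompartmentModel,
    neuron_id: int = -1,
    electrode_center=None,
) -> tuple[bool, InitiationRecord | None]:
    """Classify a simulation outcome as activated/not and locate initiation."""
    crossed = result.first_cross_t >= 0
    if not crossed.any():
        return False, None
    if not _propagating(model, crossed):
        return False, None
    order = _initiation_order(result)
    soma_first = model.site_label(order[0]) == SITE_SOMA
    comp = None
    for i in order:
        if model.site_label(i) != SITE_SOMA:
            comp = int(i)
            break
    if comp is None:
        return False, None
    loc = tuple(model.coords[comp]) if model.coords is not None else None
    dist = None
    if loc is not None and electrode_center is not None:
        dist = float(np.linalg.norm(np.asarray(loc) - np.asarray(electrode_center)))
    rec = InitiationRecord(
        neuron_id=neuron_id,
        site=model.site_label(comp),
        compartment=comp,
        time=float(result.first_cross_t[comp]),
        location=loc,
        distance_to_electrode=dist,
        soma_crossed_first=soma_first,
    )
    return True, rec


def _propagating(model: CompartmentModel, crossed: np.ndarray) -> bool:
    """At least PROPAGATION_NODES consecutive spiking nodes on one branch."""
    from ..neuron.morphology import BR_DORSAL, BR_PASSAGE, BR_PERIPHERAL

    for br in (BR_PERIPHERAL, BR_DORSAL, BR_PASSAGE):
        nodes = model.node_indices(br)
        if nodes.size == 0:
            continue
        run = 0
        for i in nodes:
            run = run + 1 if crossed[i] else 0
            if run >= PROPAGATION_NODES:
                return True
    return False


def _initiation_order(result: SimResult) -> np.ndarray:
    """Compartments sorted by crossing time, then -dV/dt, then index."""
    crossed = np.flatnonzero(result.first_cross_t >= 0)
    key = np.lexsort(
        (crossed, -result.first_cross_dvdt[crossed], result.first_cross_t[crossed])
    )
    return crossed[key]


def find_threshold(
    model: CompartmentModel,
    fld: PotentialField | np.ndarray,
    neuron_id: int = -1,
    bounds: tuple = (0.1, 10000.0),
    tolerance: float = 0.01,
    pulse: PulseWaveform | None = None,
    hint: float | None = None,
    electrode_center=None,
    rest=None,
) -> ThresholdResult:
    """Bisection on stimulation amplitude for one neuron.

    The response is assumed monotone in amplitude (documented assumption;
    see the verify mode in run_thresholds).  ``hint`` warm-starts the
    bracket.  Returns the geometric midpoint of the final bracket, plus the
    initiation record observed at the lowest suprathreshold probe.
    """
    lo_b, hi_b = bounds
    if not (0 < lo_b < hi_b):
        raise ValueError("bounds must be positive with lower < upper")
    pulse = pulse or PulseWaveform()
    unit_phi = (
        fld if isinstance(fld, np.ndarray) else compartment_potentials(model, fld)
    )
    if rest is None:
        rest = resting_state(model)
    rvi, rvp, rg = rest
    if electrode_center is None and isinstance(fld, PotentialField):
        electrode_center = fld.contact_center

    probes = {}

    def activated(a):
        if a in probes:
            return probes[a][0]
        state = (rvi.copy(), rvp.copy(), rg.copy())
        res = apply_stimulus(model, unit_phi, a, pulse=pulse, state=state)
        ok, rec = detect_activation(res, model, neuron_id, electrode_center)
        probes[a] = (ok, rec)
        return ok

    if activated(lo_b):
        rec = probes[lo_b][1]
        return ThresholdResult(neuron_id, lo_b, lo_b, lo_b, tolerance, True,
                               rec, activated_at_lower_bound=True)

    # establish a bracket [lo not activated, hi activated]; very strong
    # stimuli can block, so the upper edge is found by scanning rather than
    # assuming activation at the upper bound
    hi = None
    if hint is not None:
        a = float(np.clip(2.0 * hint, lo_b, hi_b))
        if activated(a):
            hi = a
        else:
            while a < hi_b:
                a = min(a * 4.0, hi_b)
                if activated(a):
                    hi = a
                    break
    if hi is None:
        a = hi_b
        while a > lo_b:
            if activated(a):
                hi = a
                break
            a /= 4.0
        if hi is None:
            return ThresholdResult(neuron_id, None, lo_b, hi_b, tolerance, False)
    lo = hi
    while lo > lo_b:
        lo = max(lo / 4.0, lo_b)
        if not activated(lo):
            break
        hi = lo
    while hi / lo > 1.0 + tolerance:
        mid = float(np.sqrt(lo * hi))
        if activated(mid):
            hi = mid
        else:
            lo = mid
    rec = probes[hi][1]
    return ThresholdResult(
        neuron_id, float(np.sqrt(lo * hi)), lo, hi, tolerance, True, rec
    )
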