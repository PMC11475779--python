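"""Single-neuron validation: AP shape metrics, CV scaling, AIS sensitivity.

Reproduces the model's action-potential validation table (Abeta 7.3 um and
Aalpha 16.0 um neurons), the linear scaling of conduction velocity with
peripheral fiber diameter, and the sensitivity of epineural recruitment
thresholds to AIS channel densities (including the spontaneous-firing
regime when both proximal and intermediate densities are high).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .neuron.cable import integrate, resting_state
from .neuron.channels import ChannelKinetics
from .neuron.metrics import measure_ap_metrics, measure_cv
from .neuron.morphology import BR_PERIPHERAL, build_neuron, pose_coordinates
from .neuron.mrg import MorphologyFits

ABETA_DIAMETER = 7.3
AALPHA_DIAMETER = 16.0

# intracellular validation stimulus: 0.1 ms pulse at a distal peripheral
# node, roughly twice the intracellular threshold of the largest neurons
VALIDATION_STIM_NA = 10.0
VALIDATION_STIM_MS = 0.1


@dataclass
class NeuronValidation:
    diameter: float
    fiber_type: str
    soma_amplitude: float
    soma_duration: float
    soma_ahp: float
    axon_amplitude: float
    conduction_velocity: float
    soma_rest: float
    config: dict = field(default_factory=dict)


def validate_neuron(
    diameter: float,
    kinetics: ChannelKinetics | None = None,
    fits: MorphologyFits | None = None,
    dt: float = 0.005,
    duration: float = 10.0,
    stim_na: float = VALIDATION_STIM_NA,
    axon_node: int = 25,
) -> NeuronValidation:
    """AP metrics and CV for one neuron size under intracellular drive.

    The stimulus is delivered at a distal peripheral node; the somatic
    trace and a mid-peripheral node trace are measured.
    """
    kin = kinetics or ChannelKinetics()
    model = build_neuron(diameter, fits=fits, kinetics=kin)
    nodes = model.node_indices(BR_PERIPHERAL)
    stim = int(nodes[-3])
    mid = int(nodes[axon_node])
    vi, vp, gates = resting_state(model)
    rest_soma = float(vi[0] - vp[0])
    rest_mid = float(vi[mid] - vp[mid])
    res = integrate(
        model,
        state=(vi.copy(), vp.copy(), gates.copy()),
        istim=(stim, stim_na, 1.0, 1.0 + VALIDATION_STIM_MS),
        dt=dt,
        duration=duration,
        record=np.array([0, mid]),
    )
    soma = measure_ap_metrics(res.traces[0], dt, rest_soma)
    axon = measure_ap_metrics(res.traces[1], dt, rest_mid)
    if not soma.has_spike or not axon.has_spike:
        raise RuntimeError(
            f"validation stimulus did not elicit a spike (d={diameter} um)"
        )
    cv = measure_cv(model, stim_amp_na=stim_na, dt=dt)
    return NeuronValidation(
        diameter=diameter,
        fiber_type="Aalpha" if diameter >= 12.0 else "Abeta",
        soma_amplitude=soma.amplitude,
        soma_duration=soma.duration,
        soma_ahp=soma.ahp,
        axon_amplitude=axon.amplitude,
        conduction_velocity=cv,
        soma_rest=rest_soma,
        config=dict(dt=dt, duration=duration, stim_na=stim_na,
                    axon_node=axon_node),
    )


def run_ap_validation(kinetics: ChannelKinetics | None = None,
                      dt: float = 0.005) -> pd.DataFrame:
    """AP validation table for the Abeta (7.3 um) and Aalpha (16.0 um)
    neurons."""
    rows = []
    for d in (ABETA_DIAMETER, AALPHA_DIAMETER):
        v = validate_neuron(d, kinetics=kinetics, dt=dt)
        rows.append(
            dict(
                fiber_type=v.fiber_type,
                diameter_um=v.diameter,
                soma_ap_amplitude_mv=v.soma_amplitude,
                soma_ap_duration_ms=v.soma_duration,
                soma_ahp_mv=v.soma_ahp,
                axon_ap_amplitude_mv=v.axon_amplitude,
                conduction_velocity_m_s=v.conduction_velocity,
            )
        )
    return pd.DataFrame(rows)


def run_cv_scan(
    diameters=None,
    kinetics: ChannelKinetics | None = None,
    dt: float = 0.005,
) -> dict:
    """CV on a diameter grid plus the least-squares CV-diameter slope."""
    if diameters is None:
        diameters = np.linspace(6.0, 20.0, 8)
    diameters = np.asarray(diameters, dtype=float)
    if diameters.size < 8:
        raise ValueError("CV scan needs at least 8 grid points")
    kin = kinetics or ChannelKinetics()
    cvs = []
    for d in diameters:
        model = build_neuron(float(d), kinetics=kin)
        cvs.append(measure_cv(model, stim_amp_na=VALIDATION_STIM_NA, dt=dt))
    cvs = np.asarray(cvs)
    A = np.vstack([diameters, np.ones_like(diameters)]).T
    (slope, intercept), res, *_ = np.linalg.lstsq(A, cvs, rcond=None)[:2]
    pred = A @ [slope, intercept]
    r2 = 1.0 - np.sum((cvs - pred) ** 2) / np.sum((cvs - cvs.mean()) ** 2)
    return dict(
        diameters=diameters,
        cv=cvs,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
    )


def run_ais_sensitivity(
    field,
    poses: list,
    proximal_grid=(600.0, 800.0, 1000.0),
    intermediate_grid=(400.0, 600.0, 800.0, 1000.0),
    kinetics: ChannelKinetics | None = None,
    diameter: float = 9.0,
) -> pd.DataFrame:
    """Epineural threshold and spontaneous-firing flag over an AIS density
    grid.

    ``poses`` is a list of (soma_center, stem_dir) tuples for neurons that
    initiate at the AIS; each grid cell reports the median threshold over
    the sample and whether any neuron fired with zero extracellular drive
    during the 10 ms window.
    """
    from .stimulation.threshold import find_threshold

    base = kinetics or ChannelKinetics()
    rows = []
    for prox in proximal_grid:
        for inter in intermediate_grid:
            kin = dataclasses.replace(
                base,
                ais_proximal_density=float(prox),
                ais_intermediate_density=float(inter),
            )
            model = build_neuron(diameter, kinetics=kin)
            vi, vp, gates = resting_state(model)
            quiet = integrate(
                model, state=(vi.copy(), vp.copy(), gates.copy()),
                dt=0.005, duration=10.0, record=False,
            )
            spontaneous = bool((quiet.first_cross_t >= 0).any())
            thresholds = []
            if not spontaneous:
                for center, direction in poses:
                    pose_coordinates(model, np.asarray(center),
                                     np.asarray(direction))
                    res = find_threshold(
                        model, field,
                        rest=(vi.copy(), vp.copy(), gates.copy()),
                    )
                    if res.activated and res.threshold is not None:
                        thresholds.append(res.threshold)
            rows.append(
                dict(
                    proximal_density=prox,
                    intermediate_density=inter,
                    spontaneous=spontaneous,
                    median_threshold_ua=(float(np.median(thresholds))
                                         if thresholds else np.nan),
                    n_neurons=len(thresholds),
                )
            )
    return pd.DataFrame(rows)
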