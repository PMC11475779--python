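"""Membrane channel kinetics for the sensory (pseudounipolar) axon model.

The active backbone is the MRG fast/persistent sodium + slow potassium +
leak nodal membrane, evaluated at 36 C, with the modifications used for
sensory afferents: a fast potassium conductance (K_f) in nodes and
internodes, slow potassium / leak / HCN conductances in the internodal
axolemma, nodal leak raised from 6 to 8 mS/cm2, and the A parameter of the
K_s beta rate raised to 0.06 to shorten the afterhyperpolarization.

Per-area sodium conductances are tied to channel counts: 2000 channels/um2
at a node corresponds to 3 S/cm2 of fast sodium, and soma/AIS densities
scale proportionally (300 -> 0.45, 1000 -> 1.5, 600 -> 0.9 S/cm2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

# Reversal potentials (mV)
E_NA = 50.0
E_K = -90.0
E_H = -45.0
E_LEAK_NODAL = -90.0
E_LEAK_INTERNODAL = -80.0

V_REST = -80.0  # initialization potential (mV)

# Conversion: fast-sodium S/cm2 per (channel/um2); 2000 ch/um2 == 3 S/cm2
GNAF_PER_CHANNEL = 3.0 / 2000.0
GNAP_PER_CHANNEL = 0.01 / 2000.0

KS_BETA_A = 0.06  # sensory value; the motor-axon original is 0.03


@dataclass
class ChannelKinetics:
    """Maximal conductances (S/cm2) per compartment class.

    ``ais_*_density`` are fast-sodium channel counts per um2; persistent
    sodium scales with the same density.  All other values are direct
    conductances.
    """

    # nodal
    node_naf: float = 3.0
    node_nap: float = 0.01
    node_kf: float = 0.02737
    node_ks: float = 0.04106
    node_lk: float = 0.008
    # soma (node-like, 300 channels/um2)
    soma_density: float = 300.0
    # AIS channel densities (channels/um2)
    ais_proximal_density: float = 1000.0
    ais_intermediate_density: float = 600.0
    ais_distal_density: float = 2000.0
    # internodal axolemma (under the myelin)
    mysa_lk: float = 0.001
    flut_lk: float = 0.0005
    stin_lk: float = 0.0005
    mysa_kf: float = 0.01
    flut_kf: float = 0.02737
    stin_kf: float = 0.001
    internode_ks: float = 0.002
    internode_h: float = 0.0005
    # soma/AIS: leak reversals and HCN (DRG somata express prominent I_h)
    soma_e_leak: float = -80.0
    ais_e_leak: float = -80.0
    soma_h: float = 0.0
    # K_s beta rate A parameter
    ks_beta_a: float = KS_BETA_A
    # myelin, per lamella membrane
    myelin_g_per_lamella: float = 0.001  # S/cm2
    myelin_c_per_lamella: float = 0.1  # uF/cm2
    # passive
    axoplasmic_resistivity: float = 70.0  # Ohm*cm
    membrane_capacitance: float = 2.0  # uF/cm2

    def naf_from_density(self, density: float) -> float:
        return density * GNAF_PER_CHANNEL

    def nap_from_density(self, density: float) -> float:
        return density * GNAP_PER_CHANNEL

    def validate(self) -> None:
        for name, value in self.__dict__.items():
            if name.endswith("e_leak"):
                continue
            if isinstance(value, (int, float)) and value < 0:
                raise ValueError(f"conductance {name} must be >= 0, got {value}")


@njit(cache=True)
def _vtrap(x, s):
    """x / (1 - exp(-x/s)) with its analytic limit s at x = 0."""
    if abs(x / s) < 1e-6:
        return s * (1.0 + x / (2.0 * s))
    return x / (1.0 - np.exp(-x / s))


@njit(cache=True)
def gate_rates(v, ks_beta_a):
    """All voltage-dependent rate constants (1/ms) at 36 C.

    Returns (am, bm, ah, bh, ap, bp, as_, bs, an, bn, qinf, qtau) for the
    fast-Na activation/inactivation (m, h), persistent-Na (p), slow-K (s),
    fast-K (n) gates and the HCN gate (q, given as steady state + tau).
    """
    # fast Na activation / inactivation
    am = 6.57 * _vtrap(v + 20.4, 10.3)
    bm = 0.304 * _vtrap(-(v + 25.7), 9.16)
    ah = 0.34 * _vtrap(-(v + 114.0), 11.0)
    bh = 12.6 / (1.0 + np.exp(-(v + 31.8) / 13.4))
    # persistent Na
    ap = 0.0353 * _vtrap(v + 27.0, 10.2)
    bp = 0.000883 * _vtrap(-(v + 34.0), 10.0)
    # slow K
    as_ = 0.3 / (1.0 + np.exp(-(v + 53.0) / 5.0))
    bs = ks_beta_a / (1.0 + np.exp(-(v + 90.0) / 1.0))
    # fast K
    an = 0.0462 * _vtrap(v + 83.2, 1.1)
    bn = 0.0824 * _vtrap(-(v + 66.0), 10.5)
    # HCN (slow, hyperpolarization-activated; half-activation -94 mV)
    qinf = 1.0 / (1.0 + np.exp((v + 94.0) / 8.0))
    qtau = 100.0
    return am, bm, ah, bh, ap, bp, as_, bs, an, bn, qinf, qtau


@njit(cache=True)
def steady_state_gates(v, ks_beta_a):
    am, bm, ah, bh, ap, bp, as_, bs, an, bn, qinf, qtau = gate_rates(v, ks_beta_a)
    return (
        am / (am + bm),
        ah / (ah + bh),
        ap / (ap + bp),
        as_ / (as_ + bs),
        an / (an + bn),
        qinf,
    )
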