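"""Compartment-tree construction for pseudounipolar neurons and axons.

A pseudounipolar DRG neuron is assembled as a tree of cylindrical
compartments rooted at the soma:

    soma -> AIS (proximal 6 um, intermediate 194 um, distal 1 um)
         -> stem axon (four internodal regions with graded myelination,
            total stem length including the AIS fixed at 784 um)
         -> t-junction node
         -> peripheral axon (50 nodes of Ranvier, MRG internodes)
         -> dorsal root axon (50 nodes, diameter 0.87 x peripheral)

Internodes follow the MRG pattern MYSA - FLUT - 6xSTIN - FLUT - MYSA.  The
soma is a node-like compartment whose diameter and length scale with the
peripheral fiber diameter by 2.78.  Axons of passage are unbranched chains
of 100 nodes with MRG internodes and no soma or stem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import (
    ChannelKinetics,
    E_LEAK_INTERNODAL,
    E_LEAK_NODAL,
)
from .mrg import (
    DIAMETER_RANGE,
    MYSA_LENGTH,
    MorphologyFits,
    N_STIN,
    NODE_LENGTH,
    PERIAXONAL_WIDTH,
)

# compartment type codes
NODE = 0
MYSA = 1
FLUT = 2
STIN = 3
SOMA = 4
AIS_PROX = 5
AIS_INTER = 6
AIS_DIST = 7
STEM_NODE = 8
STEM_INTER = 9
T_JUNCTION = 10

CTYPE_NAMES = {
    NODE: "node",
    MYSA: "MYSA",
    FLUT: "FLUT",
    STIN: "STIN",
    SOMA: "soma",
    AIS_PROX: "AIS_proximal",
    AIS_INTER: "AIS_intermediate",
    AIS_DIST: "AIS_distal",
    STEM_NODE: "stem_node",
    STEM_INTER: "stem_internode",
    T_JUNCTION: "t_junction",
}

# branch codes
BR_SOMA_STEM = 0
BR_PERIPHERAL = 1
BR_DORSAL = 2
BR_PASSAGE = 3

# five initiation-site categories + soma diagnostic
SITE_AIS = "AIS"
SITE_STEM = "stem"
SITE_TJUNCTION = "t-junction"
SITE_PU_AXON = "pseudounipolar axon"
SITE_PASSAGE = "axon of passage"
SITE_SOMA = "soma"  # diagnostic only; never a reportable category

DORSAL_DIAMETER_RATIO = 0.87
SOMA_SCALE = 2.78
STEM_TOTAL_LENGTH = 784.0  # um, including the AIS
AIS_PROX_LENGTH = 6.0
AIS_INTER_LENGTH = 194.0
AIS_DIST_LENGTH = 1.0
N_STEM_REGIONS = 4
NODES_PER_BRANCH = 50
NODES_AXON_PASSAGE = 100


@dataclass
class CompartmentModel:
    """Flat-array description of one neuron or axon of passage.

    Arrays are ordered so that ``parent[i] < i`` (Hines ordering).  All
    conductances are absolute (uS), capacitances in nF, lengths in um.
    """

    parent: np.ndarray  # int32, -1 at root
    length: np.ndarray  # um
    diameter: np.ndarray  # um
    ctype: np.ndarray  # int8 type codes
    branch: np.ndarray  # int8 branch codes
    c_mem: np.ndarray  # axolemma capacitance, nF
    g_axial: np.ndarray  # axial conductance to parent, uS
    g_peri: np.ndarray  # periaxonal axial conductance to parent, uS
    x_g: np.ndarray  # myelin conductance, uS (0 where bare)
    x_c: np.ndarray  # myelin capacitance, nF (0 where bare)
    bare: np.ndarray  # bool; True -> no myelin, periaxonal potential = e_ext
    gnaf: np.ndarray  # uS
    gnap: np.ndarray
    gks: np.ndarray
    gkf: np.ndarray
    glk: np.ndarray
    gh: np.ndarray
    e_leak: np.ndarray  # mV
    arc: np.ndarray  # path position of compartment center from root, um
    fiber_diameter: float = 0.0
    coords: np.ndarray | None = None  # (n, 3) mm, set when posed
    ks_beta_a: float = 0.06

    @property
    def n(self) -> int:
        return self.parent.size

    @property
    def is_axon_node(self) -> np.ndarray:
        """Nodes of Ranvier on peripheral/dorsal/passage axons (for
        propagation checks)."""
        return (self.ctype == NODE) & (
            (self.branch == BR_PERIPHERAL)
            | (self.branch == BR_DORSAL)
            | (self.branch == BR_PASSAGE)
        )

    def node_indices(self, branch: int) -> np.ndarray:
        return np.flatnonzero((self.ctype == NODE) & (self.branch == branch))

    def site_label(self, i: int) -> str:
        t = self.ctype[i]
        if t in (AIS_PROX, AIS_INTER, AIS_DIST):
            return SITE_AIS
        if t in (STEM_NODE, STEM_INTER):
            return SITE_STEM
        if t == T_JUNCTION:
            return SITE_TJUNCTION
        if t == SOMA:
            return SITE_SOMA
        if self.branch[i] == BR_PASSAGE:
            return SITE_PASSAGE
        return SITE_PU_AXON

    def to_table(self):
        """Plain-text compartment table (id, parent, type, length, diameter,
        x, y, z) for inspection."""
        import pandas as pd

        coords = self.coords if self.coords is not None else np.zeros((self.n, 3))
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "parent": self.parent,
                "type": [CTYPE_NAMES[t] for t in self.ctype],
                "length_um": self.length,
                "diameter_um": self.diameter,
                "x_mm": coords[:, 0],
                "y_mm": coords[:, 1],
                "z_mm": coords[:, 2],
            }
        )


class _Builder:
    """Accumulates compartments; converts geometry to absolute electrical
    parameters at the end."""

    def __init__(self, kin: ChannelKinetics):
        self.kin = kin
        self.parent: list[int] = []
        self.length: list[float] = []
        self.diameter: list[float] = []
        self.ctype: list[int] = []
        self.branch: list[int] = []
        self.lamellae: list[float] = []  # 0 -> bare
        self.peri_width: list[float] = []
        self.dens: list[tuple] = []  # (gnaf, gnap, gks, gkf, glk, gh, e_leak) S/cm2

    def add(self, parent, length, diameter, ctype, branch, lamellae, peri_width, dens):
        i = len(self.parent)
        self.parent.append(parent)
        self.length.append(length)
        self.diameter.append(diameter)
        self.ctype.append(ctype)
        self.branch.append(branch)
        self.lamellae.append(lamellae)
        self.peri_width.append(peri_width)
        self.dens.append(dens)
        return i

    def nodal_dens(self, naf=None, nap=None, e_leak=None, gh=0.0):
        k = self.kin
        return (
            k.node_naf if naf is None else naf,
            k.node_nap if nap is None else nap,
            k.node_ks,
            k.node_kf,
            k.node_lk,
            gh,
            E_LEAK_NODAL if e_leak is None else e_leak,
        )

    def internodal_dens(self, ctype):
        k = self.kin
        lk = {MYSA: k.mysa_lk, FLUT: k.flut_lk}.get(ctype, k.stin_lk)
        kf = {MYSA: k.mysa_kf, FLUT: k.flut_kf}.get(ctype, k.stin_kf)
        return (0.0, 0.0, k.internode_ks, kf, lk, k.internode_h, E_LEAK_INTERNODAL)

    def finish(self, fiber_diameter: float) -> CompartmentModel:
        k = self.kin
        n = len(self.parent)
        parent = np.asarray(self.parent, dtype=np.int32)
        length = np.asarray(self.length)
        diameter = np.asarray(self.diameter)
        lam = np.asarray(self.lamellae)
        pw = np.asarray(self.peri_width)
        area = np.pi * diameter * length  # um2

        c_mem = k.membrane_capacitance * area * 1e-5  # nF
        x_g = np.zeros(n)
        x_c = np.zeros(n)
        myel = lam > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            x_g[myel] = (k.myelin_g_per_lamella / (2 * lam[myel])) * area[myel] * 1e-2
            x_c[myel] = (k.myelin_c_per_lamella / (2 * lam[myel])) * area[myel] * 1e-5

        dens = np.asarray(self.dens)  # (n, 7)
        conv = area * 1e-2  # S/cm2 * um2 -> uS
        gnaf = dens[:, 0] * conv
        gnap = dens[:, 1] * conv
        gks = dens[:, 2] * conv
        gkf = dens[:, 3] * conv
        glk = dens[:, 4] * conv
        gh = dens[:, 5] * conv
        e_leak = dens[:, 6].copy()

        # axial conductances: series combination of half-compartments
        rho_um = k.axoplasmic_resistivity * 1e4  # Ohm*um
        r_half = rho_um * (length / 2.0) / (np.pi * diameter**2 / 4.0)  # Ohm
        ann = np.pi * ((diameter / 2 + pw) ** 2 - (diameter / 2) ** 2)  # um2
        rp_half = rho_um * (length / 2.0) / ann
        g_axial = np.zeros(n)
        g_peri = np.zeros(n)
        for i in range(1, n):
            p = parent[i]
            g_axial[i] = 1e6 / (r_half[i] + r_half[p])  # uS
            g_peri[i] = 1e6 / (rp_half[i] + rp_half[p])

        arc = np.zeros(n)
        for i in range(1, n):
            p = parent[i]
            arc[i] = arc[p] + (length[p] + length[i]) / 2.0

        return CompartmentModel(
            parent=parent,
            length=length,
            diameter=diameter,
            ctype=np.asarray(self.ctype, dtype=np.int8),
            branch=np.asarray(self.branch, dtype=np.int8),
            c_mem=c_mem,
            g_axial=g_axial,
            g_peri=g_peri,
            x_g=x_g,
            x_c=x_c,
            bare=~myel,
            gnaf=gnaf,
            gnap=gnap,
            gks=gks,
            gkf=gkf,
            glk=glk,
            gh=gh,
            e_leak=e_leak,
            arc=arc,
            fiber_diameter=fiber_diameter,
            ks_beta_a=k.ks_beta_a,
        )


def _check_diameter(d: float):
    lo, hi = DIAMETER_RANGE
    if not (lo <= d <= hi):
        raise ValueError(f"fiber diameter {d} um outside supported range [{lo}, {hi}]")


def _add_internode(b: _Builder, parent: int, fiber_d: float, fits: MorphologyFits,
                   branch: int):
    """Append MYSA-FLUT-6xSTIN-FLUT-MYSA; return index of last compartment."""
    node_d = fits.node_diameter(fiber_d)
    axon_d = fits.axon_diameter(fiber_d)
    flut_l = fits.flut_length(fiber_d)
    stin_l = fits.stin_length(fiber_d)
    nl = fits.lamellae(fiber_d)
    p = b.add(parent, MYSA_LENGTH, node_d, MYSA, branch, nl,
              PERIAXONAL_WIDTH["mysa"], b.internodal_dens(MYSA))
    p = b.add(p, flut_l, axon_d, FLUT, branch, nl,
              PERIAXONAL_WIDTH["flut"], b.internodal_dens(FLUT))
    for _ in range(N_STIN):
        p = b.add(p, stin_l, axon_d, STIN, branch, nl,
                  PERIAXONAL_WIDTH["stin"], b.internodal_dens(STIN))
    p = b.add(p, flut_l, axon_d, FLUT, branch, nl,
              PERIAXONAL_WIDTH["flut"], b.internodal_dens(FLUT))
    p = b.add(p, MYSA_LENGTH, node_d, MYSA, branch, nl,
              PERIAXONAL_WIDTH["mysa"], b.internodal_dens(MYSA))
    return p


def _add_axon_branch(b: _Builder, parent: int, fiber_d: float, fits: MorphologyFits,
                     branch: int, n_nodes: int):
    """Append n_nodes x (internode + node) starting from `parent`."""
    node_d = fits.node_diameter(fiber_d)
    p = parent
    for _ in range(n_nodes):
        p = _add_internode(b, p, fiber_d, fits, branch)
        p = b.add(p, NODE_LENGTH, node_d, NODE, branch, 0.0,
                  PERIAXONAL_WIDTH["node"], b.nodal_dens())
    return p


def build_neuron(
    peripheral_diameter: float,
    fits: MorphologyFits | None = None,
    kinetics: ChannelKinetics | None = None,
    n_ais_inter_segments: int = 13,
    n_stem_segments: int = 3,
    stem_diameter_scale: float = 0.7,
    ais_diameter_scale: float | None = None,
) -> CompartmentModel:
    """Build a pseudounipolar neuron with the given peripheral fiber diameter.

    ``stem_diameter_scale`` scales the myelinated stem caliber and
    ``ais_diameter_scale`` the unmyelinated AIS caliber, both relative to
    the peripheral-axon fits (``ais_diameter_scale`` defaults to the stem
    value).
    """
    _check_diameter(peripheral_diameter)
    fits = fits or MorphologyFits()
    kin = kinetics or ChannelKinetics()
    kin.validate()
    if ais_diameter_scale is None:
        ais_diameter_scale = stem_diameter_scale
    b = _Builder(kin)
    d = peripheral_diameter
    d_dorsal = DORSAL_DIAMETER_RATIO * d
    soma_d = SOMA_SCALE * d
    node_d = fits.node_diameter(d) * stem_diameter_scale
    ais_d = fits.node_diameter(d) * ais_diameter_scale
    axon_d = fits.axon_diameter(d) * stem_diameter_scale
    nl_full = fits.lamellae(d)

    soma_dens = b.nodal_dens(
        naf=kin.naf_from_density(kin.soma_density),
        nap=kin.nap_from_density(kin.soma_density),
        e_leak=kin.soma_e_leak,
        gh=kin.soma_h,
    )
    soma = b.add(-1, soma_d, soma_d, SOMA, BR_SOMA_STEM, 0.0,
                 PERIAXONAL_WIDTH["node"], soma_dens)

    # AIS: unmyelinated, node-like channels at reduced density
    prox_dens = b.nodal_dens(
        naf=kin.naf_from_density(kin.ais_proximal_density),
        nap=kin.nap_from_density(kin.ais_proximal_density),
        e_leak=kin.ais_e_leak,
    )
    inter_dens = b.nodal_dens(
        naf=kin.naf_from_density(kin.ais_intermediate_density),
        nap=kin.nap_from_density(kin.ais_intermediate_density),
        e_leak=kin.ais_e_leak,
    )
    dist_dens = b.nodal_dens(
        naf=kin.naf_from_density(kin.ais_distal_density),
        nap=kin.nap_from_density(kin.ais_distal_density),
        e_leak=kin.ais_e_leak,
    )
    p = b.add(soma, AIS_PROX_LENGTH, ais_d, AIS_PROX, BR_SOMA_STEM, 0.0,
              PERIAXONAL_WIDTH["node"], prox_dens)
    seg_l = AIS_INTER_LENGTH / n_ais_inter_segments
    for _ in range(n_ais_inter_segments):
        p = b.add(p, seg_l, ais_d, AIS_INTER, BR_SOMA_STEM, 0.0,
                  PERIAXONAL_WIDTH["node"], inter_dens)
    p = b.add(p, AIS_DIST_LENGTH, ais_d, AIS_DIST, BR_SOMA_STEM, 0.0,
              PERIAXONAL_WIDTH["node"], dist_dens)

    # stem axon: four internodal regions, lamellae ramp from 1/3 to full
    ais_total = AIS_PROX_LENGTH + AIS_INTER_LENGTH + AIS_DIST_LENGTH
    n_stem_nodes = N_STEM_REGIONS - 1
    inter_l = (STEM_TOTAL_LENGTH - ais_total - n_stem_nodes * NODE_LENGTH) / N_STEM_REGIONS
    lam_ramp = np.linspace(nl_full / 3.0, nl_full, N_STEM_REGIONS)
    for j in range(N_STEM_REGIONS):
        seg = inter_l / n_stem_segments
        for _ in range(n_stem_segments):
            p = b.add(p, seg, axon_d, STEM_INTER, BR_SOMA_STEM, lam_ramp[j],
                      PERIAXONAL_WIDTH["stin"], b.internodal_dens(STIN))
        if j < N_STEM_REGIONS - 1:
            p = b.add(p, NODE_LENGTH, node_d, STEM_NODE, BR_SOMA_STEM, 0.0,
                      PERIAXONAL_WIDTH["node"], b.nodal_dens())

    tj = b.add(p, NODE_LENGTH, fits.node_diameter(d), T_JUNCTION, BR_SOMA_STEM,
               0.0, PERIAXONAL_WIDTH["node"], b.nodal_dens())

    _add_axon_branch(b, tj, d, fits, BR_PERIPHERAL, NODES_PER_BRANCH)
    _add_axon_branch(b, tj, d_dorsal, fits, BR_DORSAL, NODES_PER_BRANCH)
    return b.finish(d)


def pose_coordinates(
    model: CompartmentModel,
    position: np.ndarray,
    stem_dir: np.ndarray | None = None,
    axis: np.ndarray = (1.0, 0.0, 0.0),
) -> np.ndarray:
    """Compute 3D compartment-center coordinates (mm) for a posed model.

    For a pseudounipolar neuron, ``position`` is the soma center and
    ``stem_dir`` the unit vector from the soma toward the t-junction; the
    peripheral and dorsal axons run antiparallel/parallel to ``axis`` (the
    DRG long axis) from the t-junction.  For an axon of passage,
    ``position`` is the chain midpoint along ``axis``.
    """
    pos = np.asarray(position, dtype=float)
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    arc_mm = model.arc / 1000.0
    coords = np.empty((model.n, 3))
    if model.branch[0] == BR_PASSAGE:
        half = arc_mm[-1] / 2.0
        coords[:] = pos[None, :] + np.outer(arc_mm - half, ax)
        model.coords = coords
        return coords
    if stem_dir is None:
        raise ValueError("stem_dir is required for a pseudounipolar neuron")
    u = np.asarray(stem_dir, dtype=float)
    u = u / np.linalg.norm(u)
    tj = int(np.flatnonzero(model.ctype == T_JUNCTION)[0])
    stem_mask = model.branch == BR_SOMA_STEM
    coords[stem_mask] = pos[None, :] + np.outer(arc_mm[stem_mask], u)
    tj_point = pos + u * arc_mm[tj]
    for br, sign in ((BR_PERIPHERAL, -1.0), (BR_DORSAL, 1.0)):
        m = model.branch == br
        coords[m] = tj_point[None, :] + np.outer(
            sign * (arc_mm[m] - arc_mm[tj]), ax
        )
    model.coords = coords
    return coords


def build_axon_of_passage(
    diameter: float,
    fits: MorphologyFits | None = None,
    kinetics: ChannelKinetics | None = None,
    n_nodes: int = NODES_AXON_PASSAGE,
) -> CompartmentModel:
    """Build an unbranched 100-node axon with MRG internodes (no soma/AIS)."""
    _check_diameter(diameter)
    fits = fits or MorphologyFits()
    kin = kinetics or ChannelKinetics()
    kin.validate()
    b = _Builder(kin)
    node_d = fits.node_diameter(diameter)
    b.add(-1, NODE_LENGTH, node_d, NODE, BR_PASSAGE, 0.0,
          PERIAXONAL_WIDTH["node"], b.nodal_dens())
    p = 0
    for _ in range(n_nodes - 1):
        p = _add_internode(b, p, diameter, fits, BR_PASSAGE)
        p = b.add(p, NODE_LENGTH, node_d, NODE, BR_PASSAGE, 0.0,
                  PERIAXONAL_WIDTH["node"], b.nodal_dens())
    return b.finish(diameter)
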