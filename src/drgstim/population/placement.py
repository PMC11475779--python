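"""Stochastic packing of pseudounipolar neurons and axons into the DRG.

Three experimental configurations are supported:

* ``realistic`` — cell bodies concentrated in the outer annulus (90% of
  somata drawn at a random cross-sectional angle in (-30, 210) degrees and
  a radial position beyond a 2/3 or 4/5 cutoff of the local DRG radius;
  10% anywhere), somata oriented outward with stems pointing inward
  (+-10 degrees jitter), peripheral/dorsal axons running parallel to the
  long axis near the core.
* ``random`` — somata uniform in the DRG volume with isotropic random stem
  orientation.
* ``axon_only`` — axons of passage only.

Placement is rejection-sampled against collision rules: soma-soma and
soma-axon clearance (axon shafts are straight lines parallel to the long
axis; stems are thin and not collision-checked against each other).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..neuron.mrg import DIAMETER_RANGE
from ..neuron.morphology import SOMA_SCALE, STEM_TOTAL_LENGTH
from ..volume.geometry import TissueGeometry
from .diameters import DiameterDistribution, sample_diameters

UM_PER_MM = 1000.0
STEM_LENGTH_MM = STEM_TOTAL_LENGTH / UM_PER_MM

# subsampling regions for the axon-only model
CORE_RADIUS_MM = 0.8
DORSAL_BAND_Y_MM = 0.537


@dataclass
class PlacementConfig:
    """Parameters of the packing algorithm (angles deg, lengths mm)."""

    model: str = "realistic"
    n_neurons: int = 1000
    # passage axons per pseudounipolar neuron; each neuron already
    # contributes two axon shafts to the interior, so passage axons are a
    # minority addition
    axon_passage_ratio: float = 0.25
    clearance: float = 0.001  # mm between structures
    anywhere_fraction: float = 0.10
    angle_range: tuple = (-30.0, 210.0)
    steep_angle_range: tuple = (30.0, 150.0)
    cutoff_steep: float = 2.0 / 3.0
    cutoff_shallow: float = 4.0 / 5.0
    longitudinal_window: float = 2.0  # +- mm about the DRG midpoint
    orientation_jitter: float = 10.0  # deg
    rejection_budget: int = 1000
    type_boundary: float = 12.0  # um; Aalpha if diameter >= boundary
    # fraction of the DRG minor axis available to passage axons in the
    # realistic model (1.0 = throughout, matching the other models)
    passage_core_fraction: float = 1.0

    def validate(self) -> None:
        if self.model not in ("realistic", "random", "axon_only"):
            raise ValueError(f"unknown placement model {self.model!r}")
        for name in ("anywhere_fraction",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("cutoff_steep", "cutoff_shallow"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.angle_range[0] >= self.angle_range[1]:
            raise ValueError("angle range must be well-ordered")


class PackingError(RuntimeError):
    def __init__(self, placed: int, requested: int):
        super().__init__(
            f"packing failed: placed {placed} of {requested} entities within "
            f"the rejection budget"
        )
        self.placed = placed


@dataclass
class Population:
    """A placed set of neurons and axons of passage.

    ``table`` has one row per entity: kind ('neuron'|'passage'), diameter
    (um), fiber_type, soma position, stem direction, t-junction (or shaft
    center for passage axons).  Positions in mm, DRG-centered coordinates.
    """

    table: pd.DataFrame
    model: str
    seed: int | None = None
    geometry: TissueGeometry | None = None

    @property
    def n(self) -> int:
        return len(self.table)

    def neurons(self) -> pd.DataFrame:
        return self.table[self.table.kind == "neuron"]

    def to_csv(self, path) -> None:
        df = self.table.copy()
        df.insert(0, "model", self.model)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Population":
        df = pd.read_csv(path)
        model = df.pop("model").iloc[0] if "model" in df else "unknown"
        return cls(table=df, model=model)


def _fiber_type(diam, boundary):
    return np.where(diam >= boundary, "Aalpha", "Abeta")


def _soma_radius_mm(diam_um):
    return SOMA_SCALE * diam_um / 2.0 / UM_PER_MM


def _inside_spheroid(pts, geom, margin=0.0):
    a = geom.drg_semi_major - margin
    b = geom.drg_semi_minor - margin
    pts = np.atleast_2d(pts)
    return (pts[:, 0] / a) ** 2 + (pts[:, 1] ** 2 + pts[:, 2] ** 2) / b**2 <= 1.0


class _Occupancy:
    """Incremental collision bookkeeping."""

    def __init__(self, clearance):
        self.clear = clearance
        self.soma_c = []  # centers
        self.soma_r = []
        self.shaft_yz = []  # (y, z) of axon lines parallel to x
        self.shaft_r = []

    def soma_ok(self, c, r):
        if self.soma_c:
            sc = np.asarray(self.soma_c)
            sr = np.asarray(self.soma_r)
            if np.any(np.linalg.norm(sc - c, axis=1) < sr + r + self.clear):
                return False
        if self.shaft_yz:
            yz = np.asarray(self.shaft_yz)
            rr = np.asarray(self.shaft_r)
            d = np.linalg.norm(yz - c[1:], axis=1)
            if np.any(d < rr + r + self.clear):
                return False
        return True

    def shaft_ok(self, yz, r):
        if self.soma_c:
            sc = np.asarray(self.soma_c)
            sr = np.asarray(self.soma_r)
            d = np.linalg.norm(sc[:, 1:] - yz, axis=1)
            if np.any(d < sr + r + self.clear):
                return False
        if self.shaft_yz:
            syz = np.asarray(self.shaft_yz)
            srr = np.asarray(self.shaft_r)
            if np.any(np.linalg.norm(syz - yz, axis=1) < srr + r + self.clear):
                return False
        return True

    def add_soma(self, c, r):
        self.soma_c.append(np.asarray(c, dtype=float))
        self.soma_r.append(r)

    def add_shaft(self, yz, r):
        self.shaft_yz.append(np.asarray(yz, dtype=float))
        self.shaft_r.append(r)


def _place_neuron_rows(diams, geom, cfg, rng, realistic):
    occ = _Occupancy(cfg.clearance)
    rows = []
    a, b = geom.drg_semi_major, geom.drg_semi_minor
    for i, d in enumerate(diams):
        rs = _soma_radius_mm(d)
        shaft_r = d / 2.0 / UM_PER_MM
        placed = False
        annulus_branch = realistic and rng.random() >= cfg.anywhere_fraction
        for _ in range(cfg.rejection_budget):
            if annulus_branch:
                theta = np.deg2rad(rng.uniform(*cfg.angle_range))
                x = rng.uniform(-cfg.longitudinal_window, cfg.longitudinal_window)
                R = geom.local_radius(x)
                steep = (
                    np.deg2rad(cfg.steep_angle_range[0])
                    <= theta
                    <= np.deg2rad(cfg.steep_angle_range[1])
                )
                cutoff = (cfg.cutoff_steep if steep else cfg.cutoff_shallow) * R
                r_hi = min(R - rs, geom.local_radius(abs(x) + rs) - rs)
                if r_hi <= cutoff:
                    continue
                r = rng.uniform(cutoff, r_hi)
                c = np.array([x, r * np.sin(theta), r * np.cos(theta)])
                inward = np.array([0.0, -np.sin(theta), -np.cos(theta)])
                jit = np.deg2rad(rng.uniform(-cfg.orientation_jitter,
                                             cfg.orientation_jitter))
                cj, sj = np.cos(jit), np.sin(jit)
                u = np.array([
                    0.0,
                    inward[1] * cj - inward[2] * sj,
                    inward[1] * sj + inward[2] * cj,
                ])
                placed_by = "annulus"
            else:
                c = np.array([
                    rng.uniform(-a, a),
                    rng.uniform(-b, b),
                    rng.uniform(-b, b),
                ])
                if not _inside_spheroid(c, geom, margin=rs)[0]:
                    continue
                if realistic:
                    # interior somata still orient inward toward the axis
                    yz = c[1:]
                    nrm = np.linalg.norm(yz)
                    if nrm < 1e-6:
                        u = np.array([0.0, -1.0, 0.0])
                    else:
                        u = np.array([0.0, -yz[0] / nrm, -yz[1] / nrm])
                    placed_by = "uniform"
                else:
                    v = rng.normal(size=3)
                    u = v / np.linalg.norm(v)
                    placed_by = "uniform"
            tj = c + u * (rs + STEM_LENGTH_MM)
            if not _inside_spheroid(tj, geom)[0]:
                continue
            if not occ.soma_ok(c, rs):
                continue
            if not occ.shaft_ok(tj[1:], shaft_r):
                continue
            occ.add_soma(c, rs)
            occ.add_shaft(tj[1:], shaft_r)
            rows.append(
                dict(kind="neuron", diameter=d,
                     soma_x=c[0], soma_y=c[1], soma_z=c[2],
                     dir_x=u[0], dir_y=u[1], dir_z=u[2],
                     tj_x=tj[0], tj_y=tj[1], tj_z=tj[2],
                     placed_by=placed_by)
            )
            placed = True
            break
        if not placed:
            raise PackingError(len(rows), len(diams))
    return rows, occ


def _place_passage_rows(n, geom, cfg, rng, occ=None, core_fraction=1.0):
    occ = occ or _Occupancy(cfg.clearance)
    rows = []
    a, b = geom.drg_semi_major, geom.drg_semi_minor * core_fraction
    for i in range(n):
        d = float(sample_diameters(1, None, rng)[0])
        shaft_r = d / 2.0 / UM_PER_MM
        placed = False
        for _ in range(cfg.rejection_budget):
            c = np.array([
                rng.uniform(-a, a),
                rng.uniform(-b, b),
                rng.uniform(-b, b),
            ])
            if (c[0] / a) ** 2 + (c[1] ** 2 + c[2] ** 2) / b**2 > 1.0:
                continue
            if not occ.shaft_ok(c[1:], shaft_r):
                continue
            occ.add_shaft(c[1:], shaft_r)
            rows.append(
                dict(kind="passage", diameter=d,
                     soma_x=np.nan, soma_y=np.nan, soma_z=np.nan,
                     dir_x=np.nan, dir_y=np.nan, dir_z=np.nan,
                     tj_x=c[0], tj_y=c[1], tj_z=c[2],
                     placed_by="uniform")
            )
            placed = True
            break
        if not placed:
            raise PackingError(len(rows), n)
    return rows


def _finish(rows, model, cfg, geom, seed):
    df = pd.DataFrame(rows)
    if len(df):
        df["fiber_type"] = _fiber_type(df.diameter.to_numpy(), cfg.type_boundary)
        df.insert(0, "id", np.arange(len(df)))
    else:
        df = pd.DataFrame(
            columns=["id", "kind", "diameter", "soma_x", "soma_y", "soma_z",
                     "dir_x", "dir_y", "dir_z", "tj_x", "tj_y", "tj_z",
                     "placed_by", "fiber_type"]
        )
    return Population(table=df, model=model, seed=seed, geometry=geom)


def place_realistic(
    n: int,
    geometry: TissueGeometry | None = None,
    config: PlacementConfig | None = None,
    seed: int = 0,
    diameters: DiameterDistribution | None = None,
) -> Population:
    """Realistic packing: annulus-concentrated somata, inward stems."""
    geom = geometry or TissueGeometry()
    cfg = config or PlacementConfig(model="realistic")
    cfg.validate()
    rng = np.random.default_rng(seed)
    diams = sample_diameters(n, diameters, rng)
    rows, occ = _place_neuron_rows(diams, geom, cfg, rng, realistic=True)
    rows += _place_passage_rows(int(round(cfg.axon_passage_ratio * n)),
                                geom, cfg, rng, occ,
                                core_fraction=cfg.passage_core_fraction)
    return _finish(rows, "realistic", cfg, geom, seed)


def place_random(
    n: int,
    geometry: TissueGeometry | None = None,
    config: PlacementConfig | None = None,
    seed: int = 0,
    diameters: DiameterDistribution | None = None,
) -> Population:
    """Uniform soma positions and isotropic stem orientations."""
    geom = geometry or TissueGeometry()
    cfg = config or PlacementConfig(model="random")
    cfg.validate()
    rng = np.random.default_rng(seed)
    diams = sample_diameters(n, diameters, rng)
    rows, occ = _place_neuron_rows(diams, geom, cfg, rng, realistic=False)
    rows += _place_passage_rows(int(round(cfg.axon_passage_ratio * n)),
                                geom, cfg, rng, occ)
    return _finish(rows, "random", cfg, geom, seed)


def place_axon_only(
    n: int,
    geometry: TissueGeometry | None = None,
    seed: int = 0,
    config: PlacementConfig | None = None,
) -> Population:
    """Axons of passage only, uniform within the DRG volume."""
    geom = geometry or TissueGeometry()
    cfg = config or PlacementConfig(model="axon_only")
    cfg.validate()
    rng = np.random.default_rng(seed)
    rows = _place_passage_rows(n, geom, cfg, rng)
    return _finish(rows, "axon_only", cfg, geom, seed)


def region_filter(population: Population, electrode_kind: str) -> np.ndarray:
    """Indices of entities eligible for subsampling near an electrode.

    Axon-only model: the penetrating electrode samples entities whose shaft
    passes within the 800 um core about the DRG center; the epineural
    electrode samples the dorsal band more than 537 um above the center
    line.  Other models are returned unfiltered.
    """
    df = population.table
    if population.model != "axon_only":
        return df.index.to_numpy()
    if electrode_kind == "penetrating":
        keep = np.hypot(df.tj_y, df.tj_z) <= CORE_RADIUS_MM
    elif electrode_kind == "epineural":
        keep = df.tj_y > DORSAL_BAND_Y_MM
    else:
        raise ValueError(f"unknown electrode kind {electrode_kind!r}")
    return df.index.to_numpy()[keep.to_numpy()]
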