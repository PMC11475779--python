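"""Tissue geometry, conductivities and voxelized volume construction.

The DRG is a prolate spheroid (semi-major 3.7 mm along x, semi-minor
1.5 mm) with peripheral and dorsal roots as 0.75 mm radius cylinders along
the long axis, wrapped in a 20 um epineurium, inside concentric cylinders
of intraforaminal tissue (3.25 mm) and bone (17.2 mm), immersed in saline
whose outer faces are the 0 V boundary.  DRG and root conductivity is a
rank-2 tensor aligned with the long (x) axis; all other tissues are
isotropic.  Axes: x longitudinal (peripheral -> central), y dorso-ventral
(dorsal = +y), z medio-lateral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# voxel labels
EXTRANEURAL = 0
DRG = 1
EPINEURIUM = 2
BONE = 3
SALINE = 4
INSULATION = 5
CONTACT = 6
ENCAPSULATION = 7
GRAY_MATTER = 8

LABEL_NAMES = {
    EXTRANEURAL: "extraneural",
    DRG: "DRG",
    EPINEURIUM: "epineurium",
    BONE: "bone",
    SALINE: "saline",
    INSULATION: "insulation",
    CONTACT: "contact",
    ENCAPSULATION: "encapsulation",
    GRAY_MATTER: "gray matter",
}


@dataclass
class TissueGeometry:
    """Anatomical dimensions in mm."""

    drg_semi_major: float = 3.7
    drg_semi_minor: float = 1.5
    root_length: float = 150.0
    root_radius: float = 0.75
    root_attach_offset: float = 3.25
    epineurium_thickness: float = 0.020
    intraforaminal_radius: float = 3.25
    bone_radius: float = 17.2
    # solved-domain half extents (the saline/bone box is truncated here and
    # the Dirichlet 0 V boundary applied at the box faces)
    box_halfwidth_x: float = 8.0
    box_halfwidth_yz: float = 5.2

    def validate(self) -> None:
        if not (0 < self.drg_semi_minor < self.drg_semi_major):
            raise ValueError("spheroid axes must satisfy 0 < minor < major")
        if not (
            self.drg_semi_minor + self.epineurium_thickness
            < self.intraforaminal_radius
            < self.bone_radius
        ):
            raise ValueError(
                "nested regions must be strictly ordered: "
                "DRG+epineurium < intraforaminal < bone"
            )
        if self.root_radius >= self.drg_semi_minor:
            raise ValueError("root radius must be smaller than the DRG minor axis")
        if self.epineurium_thickness < 0:
            raise ValueError("epineurium thickness must be >= 0")

    def local_radius(self, x) -> np.ndarray:
        """Cross-section radius R(x) of the DRG spheroid at longitudinal x
        (mm); zero outside |x| < semi-major."""
        x = np.asarray(x, dtype=float)
        a, b = self.drg_semi_major, self.drg_semi_minor
        r2 = 1.0 - (x / a) ** 2
        return b * np.sqrt(np.clip(r2, 0.0, None))

    def dorsal_surface_y(self, x, z) -> float:
        """Dorsal (top) surface height of the epineurium at (x, z)."""
        a = self.drg_semi_major + self.epineurium_thickness
        b = self.drg_semi_minor + self.epineurium_thickness
        r2 = 1.0 - (np.asarray(x) / a) ** 2 - (np.asarray(z) / b) ** 2
        return b * np.sqrt(np.clip(r2, 0.0, None))


@dataclass
class ConductivityTable:
    """Tissue conductivities in S/m."""

    gray_matter: float = 0.23
    drg_longitudinal: float = 0.6
    drg_transverse: float = 0.083
    epineurium: float = 0.6
    bone: float = 0.02
    extraneural: float = 0.25
    encapsulation: float = 0.17
    platinum: float = 9.4e6
    saline: float = 2.0
    insulation: float = 1e-10

    def validate(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"conductivity {name} must be > 0, got {value}")
        if self.drg_longitudinal <= self.drg_transverse:
            raise ValueError("DRG longitudinal conductivity must exceed transverse")


@dataclass
class ElectrodeSpec:
    """Stimulating electrode description.

    ``kind`` is "epineural" (375 um diameter disk on the dorsal epineural
    surface) or "penetrating" (shank inserted 1 mm from the dorsal surface
    with a 50 um exposed tip).  ``shift`` moves the electrode in mm.
    """

    kind: str = "epineural"
    shift: tuple = (0.0, 0.0, 0.0)
    contact_diameter: float = 0.375  # mm, epineural disk
    insertion_depth: float = 1.0  # mm below the dorsal DRG surface
    tip_height: float = 0.050  # mm exposed tip
    tip_diameter: float = 0.0225  # mm at the tip base
    encapsulation_thickness: float = 0.0  # mm, optional layer around contact

    def validate(self) -> None:
        if self.kind not in ("epineural", "penetrating"):
            raise ValueError(f"unknown electrode kind {self.kind!r}")
        if len(self.shift) != 3:
            raise ValueError("shift must be (dx, dy, dz) in mm")


@dataclass
class TissueModel:
    """Voxelized conductivity volume on a regular cell-centered grid."""

    labels: np.ndarray  # (nx, ny, nz) int8
    sigma_x: np.ndarray  # S/m, longitudinal conductivity per voxel
    sigma_t: np.ndarray  # S/m, transverse conductivity per voxel
    axes: tuple  # (x, y, z) voxel-center coordinates, mm
    resolution: float  # mm
    geometry: TissueGeometry | None = None
    conductivities: ConductivityTable | None = None

    @property
    def shape(self):
        return self.labels.shape

    def label_at(self, point) -> int:
        """Tissue label of the voxel containing a point (mm)."""
        idx = []
        for c, ax in zip(point, self.axes):
            i = int(np.argmin(np.abs(ax - c)))
            idx.append(i)
        return int(self.labels[tuple(idx)])


def build_tissue_model(
    geometry: TissueGeometry | None = None,
    conductivities: ConductivityTable | None = None,
    resolution: float = 0.05,
    bounds: tuple | None = None,
) -> TissueModel:
    """Label every voxel of the domain box with its tissue and conductivity.

    ``resolution`` is the voxel edge (mm); it must resolve the DRG minor
    axis with at least 20 voxels.  ``bounds`` = ((xlo, xhi), (ylo, yhi),
    (zlo, zhi)) in mm overrides the default centered box (used for local
    refinement around an electrode).
    """
    geom = geometry or TissueGeometry()
    cond = conductivities or ConductivityTable()
    geom.validate()
    cond.validate()
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if 2 * geom.drg_semi_minor / resolution < 20:
        raise ValueError(
            f"resolution {resolution} mm too coarse: DRG minor axis spans "
            f"{2 * geom.drg_semi_minor / resolution:.1f} voxels (< 20)"
        )

    h = resolution
    if bounds is None:
        ax_x = _centered_axis(geom.box_halfwidth_x, h)
        ax_y = _centered_axis(geom.box_halfwidth_yz, h)
        ax_z = _centered_axis(geom.box_halfwidth_yz, h)
    else:
        ax_x = _range_axis(*bounds[0], h)
        ax_y = _range_axis(*bounds[1], h)
        ax_z = _range_axis(*bounds[2], h)
    X = ax_x[:, None, None]
    Y = ax_y[None, :, None]
    Z = ax_z[None, None, :]

    labels = np.full((ax_x.size, ax_y.size, ax_z.size), BONE, dtype=np.int8)
    r_yz = np.sqrt(Y**2 + Z**2)

    labels[np.broadcast_to(r_yz > geom.bone_radius, labels.shape)] = SALINE
    labels[np.broadcast_to(r_yz <= geom.intraforaminal_radius, labels.shape)] = (
        EXTRANEURAL
    )

    # roots: cylinders along x beyond the attachment offset (with epineurium)
    t = geom.epineurium_thickness
    in_root_epi = (np.abs(X) >= geom.root_attach_offset) & (
        r_yz <= geom.root_radius + t
    )
    labels[in_root_epi] = EPINEURIUM
    in_root = (np.abs(X) >= geom.root_attach_offset) & (r_yz <= geom.root_radius)
    labels[in_root] = DRG  # nerve tissue shares the DRG tensor

    # DRG spheroid with epineurium shell
    a, b = geom.drg_semi_major, geom.drg_semi_minor
    in_epi = (X / (a + t)) ** 2 + (Y**2 + Z**2) / (b + t) ** 2 <= 1.0
    labels[in_epi & (labels != DRG)] = EPINEURIUM
    in_drg = (X / a) ** 2 + (Y**2 + Z**2) / b**2 <= 1.0
    labels[in_drg] = DRG

    sigma_map_iso = {
        EXTRANEURAL: cond.extraneural,
        EPINEURIUM: cond.epineurium,
        BONE: cond.bone,
        SALINE: cond.saline,
        INSULATION: cond.insulation,
        CONTACT: cond.platinum,
        ENCAPSULATION: cond.encapsulation,
        GRAY_MATTER: cond.gray_matter,
    }
    sigma_x = np.empty(labels.shape)
    sigma_t = np.empty(labels.shape)
    for lab, s in sigma_map_iso.items():
        m = labels == lab
        sigma_x[m] = s
        sigma_t[m] = s
    m = labels == DRG
    sigma_x[m] = cond.drg_longitudinal
    sigma_t[m] = cond.drg_transverse

    return TissueModel(
        labels=labels,
        sigma_x=sigma_x,
        sigma_t=sigma_t,
        axes=(ax_x, ax_y, ax_z),
        resolution=h,
        geometry=geom,
        conductivities=cond,
    )


def _centered_axis(halfwidth: float, h: float) -> np.ndarray:
    n = max(int(round(2 * halfwidth / h)), 3)
    return (np.arange(n) - (n - 1) / 2.0) * h


def _range_axis(lo: float, hi: float, h: float) -> np.ndarray:
    n = max(int(round((hi - lo) / h)), 3)
    return lo + (np.arange(n) + 0.5) * h


def uniform_tissue(sigma_x: float, sigma_t: float | None = None,
                   halfwidth: float = 3.0, resolution: float = 0.1) -> TissueModel:
    """Homogeneous cube of tissue, for closed-form oracle comparisons."""
    if sigma_t is None:
        sigma_t = sigma_x
    h = resolution
    ax = _centered_axis(halfwidth, h)
    shape = (ax.size, ax.size, ax.size)
    return TissueModel(
        labels=np.zeros(shape, dtype=np.int8),
        sigma_x=np.full(shape, float(sigma_x)),
        sigma_t=np.full(shape, float(sigma_t)),
        axes=(ax, ax, ax),
        resolution=h,
    )


def place_electrode(tissue: TissueModel, electrode: ElectrodeSpec) -> np.ndarray:
    """Mark contact (and shank insulation) voxels; returns the contact mask.

    The epineural contact is the set of dorsal surface voxels of the
    epineurium/DRG within the disk radius; the penetrating contact is the
    exposed tip at 1 mm depth, with the shank above it insulated.
    """
    electrode.validate()
    geom = tissue.geometry
    if geom is None:
        raise ValueError("tissue model lacks geometry metadata")
    ax_x, ax_y, ax_z = tissue.axes
    labels = tissue.labels
    dx, dy, dz = electrode.shift
    contact = np.zeros(labels.shape, dtype=bool)

    if electrode.kind == "epineural":
        r = electrode.contact_diameter / 2.0
        cols = np.flatnonzero(np.abs(ax_x - dx) <= r)
        surf_found = False
        for i in cols:
            for k in np.flatnonzero(np.abs(ax_z - dz) <= r):
                if (ax_x[i] - dx) ** 2 + (ax_z[k] - dz) ** 2 > r**2:
                    continue
                col = labels[i, :, k]
                tops = np.flatnonzero((col == DRG) | (col == EPINEURIUM))
                if tops.size == 0:
                    continue
                contact[i, tops[-1], k] = True
                surf_found = True
        if not surf_found:
            raise ValueError("epineural contact does not touch the DRG surface")
    else:
        xi = int(np.argmin(np.abs(ax_x - dx)))
        zi = int(np.argmin(np.abs(ax_z - dz)))
        col = labels[xi, :, zi]
        tops = np.flatnonzero((col == DRG) | (col == EPINEURIUM))
        if tops.size == 0:
            raise ValueError("penetrating electrode column misses the DRG")
        y_surf = ax_y[tops[-1]]
        y_tip = y_surf - electrode.insertion_depth + dy
        tip_lo = int(np.argmin(np.abs(ax_y - y_tip)))
        tip_hi = int(np.argmin(np.abs(ax_y - (y_tip + electrode.tip_height))))
        tip_hi = max(tip_hi, tip_lo)
        if labels[xi, tip_lo, zi] != DRG:
            raise ValueError("penetrating tip is not inside the DRG after shifting")
        contact[xi, tip_lo : tip_hi + 1, zi] = True
        # insulated shank from above the tip out through the dorsal surface
        shank = slice(tip_hi + 1, tops[-1] + 1)
        labels[xi, shank, zi] = INSULATION
        tissue.sigma_x[xi, shank, zi] = tissue.conductivities.insulation
        tissue.sigma_t[xi, shank, zi] = tissue.conductivities.insulation

    labels[contact] = CONTACT
    if tissue.conductivities is not None:
        tissue.sigma_x[contact] = tissue.conductivities.platinum
        tissue.sigma_t[contact] = tissue.conductivities.platinum

    # optional encapsulation layer around the contact (default off)
    if electrode.encapsulation_thickness > 0:
        from scipy import ndimage

        n_dil = max(int(np.ceil(electrode.encapsulation_thickness
                                / tissue.resolution)), 1)
        shell = ndimage.binary_dilation(contact, iterations=n_dil) & ~contact
        shell &= labels != INSULATION
        labels[shell] = ENCAPSULATION
        if tissue.conductivities is not None:
            tissue.sigma_x[shell] = tissue.conductivities.encapsulation
            tissue.sigma_t[shell] = tissue.conductivities.encapsulation
    return contact
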