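"""Finite-difference solve of the quasi-static potential field.

Solves div(sigma grad phi) = 0 on the voxel grid with the contact surface
held at a fixed potential and 0 V on the domain boundary, then rescales the
solution so the net current leaving the contact is exactly 1 mA.  Because
the problem is linear this yields both an equipotential contact (the
electrode is platinum) and a unit-current transfer field.  Face
conductances use the harmonic mean of the adjacent voxel conductivities
(longitudinal component across x faces, transverse across y/z), which
handles the anisotropic DRG tensor aligned with the long axis.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from .field import PotentialField
from .geometry import ElectrodeSpec, TissueModel, place_electrode


class SolverError(RuntimeError):
    pass


def _face_conductance(s_a, s_b, h_m):
    """Conductance (S) of the face between two voxels, edge h_m meters."""
    return 2.0 * s_a * s_b / (s_a + s_b) * h_m


def solve_potential(
    tissue: TissueModel,
    contact_mask: np.ndarray | None = None,
    injection: np.ndarray | None = None,
    rtol: float = 1e-8,
    maxiter: int = 20000,
    contact_value: float = 1.0,
    boundary_field=None,
) -> tuple[np.ndarray, float]:
    """Solve for phi (V) with Dirichlet conditions on the domain boundary.

    Either ``contact_mask`` (voxels held at ``contact_value`` volts, an
    equipotential platinum contact) or ``injection`` (a per-voxel current
    source in amperes) must be given.  The outer boundary is 0 V unless
    ``boundary_field`` provides values (a coarser solution, for local
    refinement).  Returns (phi, source_current_A).  Raises SolverError on
    non-convergence or an empty source.
    """
    if contact_mask is None and injection is None:
        raise SolverError("either contact_mask or injection is required")
    if contact_mask is None:
        contact_mask = np.zeros(tissue.shape, dtype=bool)
        if not np.any(injection):
            raise SolverError("injection source is identically zero")
    elif not contact_mask.any() and boundary_field is None:
        raise SolverError("contact surface has zero area after discretization")
    nx, ny, nz = tissue.shape
    h_m = tissue.resolution * 1e-3
    sx, st = tissue.sigma_x, tissue.sigma_t

    free = ~contact_mask
    idx = -np.ones(tissue.shape, dtype=np.int64)
    idx[free] = np.arange(free.sum())
    nfree = int(free.sum())

    rows, cols, vals = [], [], []
    diag = np.zeros(nfree)
    b = np.zeros(nfree)

    def couple(sl_a, sl_b, sigma):
        """Accumulate matrix entries for all faces between voxel slabs a, b."""
        g = _face_conductance(sigma[sl_a], sigma[sl_b], h_m)
        ia, ib = idx[sl_a], idx[sl_b]
        fa, fb = ia >= 0, ib >= 0
        both = fa & fb
        np.add.at(diag, ia[both], g[both])
        np.add.at(diag, ib[both], g[both])
        rows.append(ia[both]); cols.append(ib[both]); vals.append(-g[both])
        rows.append(ib[both]); cols.append(ia[both]); vals.append(-g[both])
        # faces against the fixed-potential contact: diagonal + RHS
        a_only = fa & ~fb
        np.add.at(diag, ia[a_only], g[a_only])
        np.add.at(b, ia[a_only], g[a_only] * contact_value)
        b_only = fb & ~fa
        np.add.at(diag, ib[b_only], g[b_only])
        np.add.at(b, ib[b_only], g[b_only] * contact_value)

    couple((slice(0, -1), slice(None), slice(None)),
           (slice(1, None), slice(None), slice(None)), sx)
    couple((slice(None), slice(0, -1), slice(None)),
           (slice(None), slice(1, None), slice(None)), st)
    couple((slice(None), slice(None), slice(0, -1)),
           (slice(None), slice(None), slice(1, None)), st)

    # Dirichlet at the outer box: ghost faces using the voxel's own sigma;
    # boundary values are 0 V or sampled from a coarser solution
    ax_x, ax_y, ax_z = tissue.axes
    for axis, sigma in ((0, sx), (1, st), (2, st)):
        for side in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = side
            sl = tuple(sl)
            g = 2.0 * sigma[sl] * h_m  # half-cell distance to the boundary
            ii = idx[sl]
            f = ii >= 0
            np.add.at(diag, ii[f], g[f])
            if boundary_field is not None:
                grids = np.meshgrid(ax_x, ax_y, ax_z, indexing="ij")
                pts = np.stack([gr[sl].ravel() for gr in grids], axis=1)
                bc = boundary_field.interpolate(pts).reshape(g.shape)
                np.add.at(b, ii[f], (g * bc)[f])

    if injection is not None:
        b += injection[free]

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    A = sparse.csr_matrix(
        (np.concatenate([vals, diag]),
         (np.concatenate([rows, np.arange(nfree)]),
          np.concatenate([cols, np.arange(nfree)]))),
        shape=(nfree, nfree),
    )
    M = sparse.diags(1.0 / diag)
    phi_free, info = cg(A, b, rtol=rtol, maxiter=maxiter, M=M)
    if info != 0:
        res = np.linalg.norm(A @ phi_free - b) / np.linalg.norm(b)
        raise SolverError(
            f"conjugate-gradient solve did not converge (info={info}, "
            f"relative residual {res:.2e})"
        )

    phi = np.full(tissue.shape, contact_value)
    phi[free] = phi_free

    if not contact_mask.any():
        return phi, float(injection.sum()) if injection is not None else 0.0

    # net current leaving the contact (A)
    current = 0.0
    cm = contact_mask
    for axis, sigma in ((0, sx), (1, st), (2, st)):
        for shiftdir in (1, -1):
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if shiftdir == 1:
                src[axis] = slice(0, -1); dst[axis] = slice(1, None)
            else:
                src[axis] = slice(1, None); dst[axis] = slice(0, -1)
            src, dst = tuple(src), tuple(dst)
            face = cm[src] & ~cm[dst]
            g = _face_conductance(sigma[src], sigma[dst], h_m)
            current += (g[face] * (contact_value - phi[dst][face])).sum()
    if contact_value > 0 and current <= 0:
        raise SolverError("no current leaves the contact")
    return phi, float(current)


def solve_unit_field(
    tissue: TissueModel,
    electrode: ElectrodeSpec | np.ndarray | None = None,
    injection: np.ndarray | None = None,
    rtol: float = 1e-8,
    maxiter: int = 20000,
) -> PotentialField:
    """Transfer field (V per 1 mA) for an electrode in the tissue model.

    ``electrode`` is an ElectrodeSpec (placed into the model) or a boolean
    contact mask for custom equipotential sources; alternatively
    ``injection`` distributes the source current directly (A per voxel).
    """
    contact = None
    if isinstance(electrode, ElectrodeSpec):
        contact = place_electrode(tissue, electrode)
        kind, shift = electrode.kind, tuple(electrode.shift)
    elif electrode is not None:
        contact = np.asarray(electrode, dtype=bool)
        kind, shift = "custom", (0.0, 0.0, 0.0)
    else:
        kind, shift = "custom", (0.0, 0.0, 0.0)
    phi, current = solve_potential(tissue, contact, injection=injection,
                                   rtol=rtol, maxiter=maxiter)
    scale = 1e-3 / current  # V per mA
    src = contact if contact is not None else (np.asarray(injection) != 0)
    return PotentialField(
        values=phi * scale,
        axes=tissue.axes,
        electrode_kind=kind,
        shift=shift,
        contact_center=_mask_center(src, tissue.axes),
    )


def solve_electrode_field(
    geometry=None,
    conductivities=None,
    electrode: ElectrodeSpec | None = None,
    coarse_resolution: float = 0.1,
    fine_resolution: float = 0.05,
    fine_halfwidths: tuple = (1.6, 1.3, 1.6),
    rtol: float = 1e-8,
):
    """Two-level transfer-field solve for an electrode.

    A coarse solve over the full domain captures the far field; a locally
    refined solve in a box around the contact, with boundary values taken
    from the coarse solution, resolves the steep near-contact gradients
    (essential for the penetrating tip, whose exposed height is 50 um).
    The refined solution is the superposition of (a) the contact held at
    1 V with a grounded local boundary and (b) the coarse boundary values
    with a grounded contact, scaled so the net contact current is 1 mA.
    Returns a CompositeField falling back to the coarse field outside the
    refined box.
    """
    from .geometry import TissueGeometry, ConductivityTable, build_tissue_model

    geometry = geometry or TissueGeometry()
    conductivities = conductivities or ConductivityTable()
    electrode = electrode or ElectrodeSpec()
    coarse_tissue = build_tissue_model(geometry, conductivities,
                                       coarse_resolution)
    coarse = solve_unit_field(coarse_tissue, electrode, rtol=rtol)
    if fine_resolution >= coarse_resolution:
        return coarse

    c = np.asarray(coarse.contact_center)
    hw = np.asarray(fine_halfwidths)
    lims = np.array([
        [coarse_tissue.axes[d][0], coarse_tissue.axes[d][-1]] for d in range(3)
    ])
    lo = np.maximum(c - hw, lims[:, 0] + coarse_resolution)
    hi = np.minimum(c + hw, lims[:, 1] - coarse_resolution)
    bounds = tuple((float(a), float(b)) for a, b in zip(lo, hi))
    fine_tissue = build_tissue_model(geometry, conductivities,
                                     fine_resolution, bounds=bounds)
    contact = place_electrode(fine_tissue, electrode)
    phi_a, i_a = solve_potential(fine_tissue, contact, rtol=rtol)
    phi_b, i_b = solve_potential(
        fine_tissue, contact, contact_value=0.0,
        boundary_field=coarse, rtol=rtol,
    )
    alpha = (1e-3 - i_b) / i_a
    fine = PotentialField(
        values=alpha * phi_a + phi_b,
        axes=fine_tissue.axes,
        electrode_kind=electrode.kind,
        shift=tuple(electrode.shift),
        contact_center=_mask_center(contact, fine_tissue.axes),
    )
    return CompositeField(fine=fine, coarse=coarse)


class CompositeField:
    """Locally refined field with a coarse fallback outside the fine box."""

    def __init__(self, fine: PotentialField, coarse: PotentialField):
        self.fine = fine
        self.coarse = coarse
        self.electrode_kind = fine.electrode_kind
        self.shift = fine.shift
        self.contact_center = fine.contact_center

    @property
    def axes(self):
        return self.coarse.axes

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo = np.array([ax[0] for ax in self.fine.axes])
        hi = np.array([ax[-1] for ax in self.fine.axes])
        in_fine = np.all((pts >= lo) & (pts <= hi), axis=1)
        out = np.empty(pts.shape[0])
        if in_fine.any():
            out[in_fine] = self.fine.interpolate(pts[in_fine])
        if (~in_fine).any():
            out[~in_fine] = self.coarse.interpolate(pts[~in_fine])
        return out


def _mask_center(mask, axes):
    ii = np.argwhere(mask)
    ax_x, ax_y, ax_z = axes
    return (
        float(ax_x[ii[:, 0]].mean()),
        float(ax_y[ii[:, 1]].mean()),
        float(ax_z[ii[:, 2]].mean()),
    )
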