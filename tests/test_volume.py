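"""Volume conductor: geometry labeling, solver oracles, field contracts."""

import numpy as np
import pytest

from drgstim.volume import (
    ConductivityTable,
    ElectrodeSpec,
    OutsideFieldError,
    PotentialField,
    TissueGeometry,
    build_tissue_model,
    potential_at,
    solve_unit_field,
    uniform_tissue,
)
from drgstim.volume.geometry import BONE, DRG


class TestTissueModel:
    def test_drg_voxel_count_matches_spheroid_volume(self):
        geom = TissueGeometry()
        tis = build_tissue_model(geom, resolution=0.05)
        # count DRG voxels inside the spheroid region only (roots excluded)
        ax_x = tis.axes[0]
        sel = np.abs(ax_x) < geom.root_attach_offset
        count = (tis.labels[sel] == DRG).sum()
        vol = count * 0.05**3
        a, b = geom.drg_semi_major, geom.drg_semi_minor
        # analytic volume of the spheroid slab |x| < attach offset
        x0 = geom.root_attach_offset
        ana = np.pi * b**2 * (2 * x0 - 2 * x0**3 / (3 * a**2))
        assert vol == pytest.approx(ana, rel=0.05)

    def test_probe_points_labelled_by_containment(self):
        tis = build_tissue_model(resolution=0.1)
        assert tis.label_at((0.0, 0.0, 0.0)) == DRG
        assert tis.label_at((0.0, 0.0, 5.0)) == BONE

    def test_zero_epineurium_is_degenerate_shell(self):
        geom = TissueGeometry(epineurium_thickness=0.0)
        tis = build_tissue_model(geom, resolution=0.1)
        assert tis.label_at((0.0, 0.0, 0.0)) == DRG

    def test_too_coarse_resolution_rejected(self):
        with pytest.raises(ValueError, match="too coarse"):
            build_tissue_model(resolution=0.2)

    def test_geometry_invariant_violation_rejected(self):
        with pytest.raises(ValueError):
            build_tissue_model(TissueGeometry(intraforaminal_radius=1.0),
                               resolution=0.05)

    def test_conductivity_invariants(self):
        with pytest.raises(ValueError):
            ConductivityTable(drg_transverse=0.7).validate()
        with pytest.raises(ValueError):
            ConductivityTable(bone=-1.0).validate()


class TestSolverOracles:
    def test_isotropic_point_source_matches_closed_form(self, isotropic_oracle):
        """Spherical source in a uniform 0.25 S/m medium: the solved field
        matches the grounded-box closed form (image sum) within 5% in the
        band [5 voxels, 1/3 box]."""
        fld, errs = isotropic_oracle
        assert errs.max() < 0.05
        # the pure free-space 1/r law holds for potential differences,
        # which cancel the grounded-boundary offset
        p1 = fld.interpolate(np.array([[0.5, 0, 0]]))[0]
        p2 = fld.interpolate(np.array([[1.0, 0, 0]]))[0]
        free = 1e-3 / (4 * np.pi * 0.25)
        assert (p1 - p2) == pytest.approx(free * (1 / 0.5e-3 - 1 / 1.0e-3),
                                          rel=0.05)

    def test_anisotropic_point_source_matches_rescaled_closed_form(
        self, anisotropic_oracle
    ):
        """DRG-like anisotropy (0.6 / 0.083 S/m): the field matches the
        coordinate-rescaled closed form within 5%."""
        _, errs = anisotropic_oracle
        assert errs.max() < 0.05

    def test_zero_source_rejected(self):
        tis = uniform_tissue(0.25, halfwidth=2.0, resolution=0.1)
        with pytest.raises(Exception):
            solve_unit_field(tis, injection=np.zeros(tis.shape))


@pytest.fixture(scope="module")
def small_field():
    tis = uniform_tissue(0.25, halfwidth=2.0, resolution=0.1)
    mask = np.zeros(tis.shape, dtype=bool)
    mask[tuple(s // 2 for s in tis.shape)] = True
    return solve_unit_field(tis, mask)


class TestPotentialField:

    def test_linearity_in_amplitude(self, small_field):
        pts = np.array([[0.5, 0.2, -0.3], [1.0, 0.0, 0.0]])
        v1 = potential_at(small_field, pts, 10.0)
        v2 = potential_at(small_field, pts, 20.0)
        assert np.allclose(v2, 2.0 * v1)
        assert np.all(potential_at(small_field, pts, 0.0) == 0.0)

    def test_cathodic_sign_convention(self, small_field):
        pts = np.array([[0.5, 0.0, 0.0]])
        assert potential_at(small_field, pts, 10.0, phase_sign=-1)[0] < 0
        assert potential_at(small_field, pts, 10.0, phase_sign=+1)[0] > 0

    def test_grid_point_query_returns_stored_value(self, small_field):
        i, j, k = 10, 12, 14
        p = [small_field.axes[0][i], small_field.axes[1][j],
             small_field.axes[2][k]]
        assert small_field.interpolate(np.array([p]))[0] == pytest.approx(
            small_field.values[i, j, k], rel=1e-12
        )

    def test_point_outside_volume_raises(self, small_field):
        with pytest.raises(OutsideFieldError):
            small_field.interpolate(np.array([[50.0, 0.0, 0.0]]))

    def test_hdf5_round_trip(self, small_field, tmp_path):
        path = tmp_path / "field.h5"
        small_field.save(path)
        back = PotentialField.load(path)
        assert np.allclose(back.values, small_field.values)
        assert back.electrode_kind == small_field.electrode_kind

    def test_decay_along_ray(self, small_field):
        rs = np.array([[r, 0, 0] for r in np.arange(0.3, 1.8, 0.1)])
        v = small_field.interpolate(rs)
        assert np.all(np.diff(v) < 0)


def test_penetrating_field_exceeds_epineural_near_tip(
    epineural_field, penetrating_field
):
    """For equal current the penetrating tip dominates the field in the
    DRG core (drives the electrode-threshold contrast)."""
    tip = np.asarray(penetrating_field.contact_center)
    probe = tip + np.array([0.0, -0.1, 0.0])  # 100 um below the tip
    v_pen = penetrating_field.interpolate(np.array([probe]))[0]
    v_epi = epineural_field.interpolate(np.array([probe]))[0]
    assert v_pen > v_epi


def test_encapsulation_layer_marked_when_enabled():
    from drgstim.volume.geometry import ENCAPSULATION, place_electrode

    tis = build_tissue_model(resolution=0.1)
    spec = ElectrodeSpec(kind="penetrating", encapsulation_thickness=0.1)
    place_electrode(tis, spec)
    assert (tis.labels == ENCAPSULATION).sum() > 0
    tis2 = build_tissue_model(resolution=0.1)
    place_electrode(tis2, ElectrodeSpec(kind="penetrating"))
    assert (tis2.labels == ENCAPSULATION).sum() == 0
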