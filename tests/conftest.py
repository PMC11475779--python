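import numpy as np
import pytest

from drgstim.volume import ElectrodeSpec, solve_electrode_field, solve_unit_field, uniform_tissue


@pytest.fixture(scope="session")
def epineural_field():
    """Two-level transfer field for the centered epineural electrode."""
    return solve_electrode_field(electrode=ElectrodeSpec(kind="epineural"))


@pytest.fixture(scope="session")
def penetrating_field():
    """Two-level transfer field for the centered penetrating electrode."""
    return solve_electrode_field(electrode=ElectrodeSpec(kind="penetrating"))


@pytest.fixture(scope="session")
def validation_table():
    """Single-neuron AP validation table (computed once per session)."""
    from drgstim.validation import run_ap_validation

    return run_ap_validation()


@pytest.fixture(scope="session")
def cv_scan():
    from drgstim.validation import run_cv_scan

    return run_cv_scan(np.linspace(6.0, 20.0, 8))


def image_lattice_potential(points, halfwidth_mm, sigmas, current_a=1e-3, n=8):
    """Exact potential of a point source at the center of a grounded box:
    alternating image-lattice sum, coordinate-rescaled for diagonal
    anisotropy.  Independent closed-form oracle for the FD solver."""
    sx, sy, sz = sigmas
    pts = np.atleast_2d(points) * 1e-3
    s = np.array([sx, sy, sz])
    xi = pts / np.sqrt(s)
    li = (halfwidth_mm * 1e-3) / np.sqrt(s)
    pref = current_a / (4 * np.pi * np.sqrt(sx * sy * sz))
    out = np.zeros(len(pts))
    rng = range(-n, n + 1)
    for i in rng:
        for j in rng:
            for k in rng:
                img = np.array([2 * li[0] * i, 2 * li[1] * j, 2 * li[2] * k])
                out += (-1) ** (i + j + k) * pref / np.linalg.norm(
                    xi - img, axis=1
                )
    return out


@pytest.fixture(scope="session")
def isotropic_oracle():
    """Solved isotropic point-source field + relative errors vs the
    closed form in the band [5 voxels, 1/3 box]."""
    sig = (0.25, 0.25, 0.25)
    tis = uniform_tissue(0.25, halfwidth=3.0, resolution=0.1)
    X = tis.axes[0][:, None, None]
    Y = tis.axes[1][None, :, None]
    Z = tis.axes[2][None, None, :]
    mask = X**2 + Y**2 + Z**2 <= 0.25**2
    fld = solve_unit_field(tis, mask)
    errs = []
    for r in np.arange(0.5, 1.01, 0.1):
        for p in ([r, 0, 0], [0, r, 0], [0, 0, r], [r / np.sqrt(3)] * 3):
            num = fld.interpolate(np.array([p]))[0]
            ana = image_lattice_potential(np.array([p]), 3.0, sig)[0]
            errs.append(abs(num - ana) / ana)
    return fld, np.array(errs)


@pytest.fixture(scope="session")
def anisotropic_oracle():
    """Solved DRG-anisotropy field + relative errors vs the rescaled
    closed form."""
    sig = (0.6, 0.083, 0.083)
    tis = uniform_tissue(0.6, 0.083, halfwidth=2.5, resolution=0.05)
    X = tis.axes[0][:, None, None]
    Y = tis.axes[1][None, :, None]
    Z = tis.axes[2][None, None, :]
    rho2 = X**2 / sig[0] + (Y**2 + Z**2) / sig[1]
    mask = rho2 <= (0.25 / np.sqrt(0.6)) ** 2
    inj = np.zeros(tis.shape)
    inj[mask] = 1e-3 / mask.sum()
    fld = solve_unit_field(tis, injection=inj)
    errs = []
    for r in np.arange(0.45, 0.81, 0.05):
        for p in ([r, 0, 0], [0, r, 0], [0, 0, r], [r / np.sqrt(3)] * 3):
            num = fld.interpolate(np.array([p]))[0]
            ana = image_lattice_potential(np.array([p]), 2.5, sig)[0]
            errs.append(abs(num - ana) / ana)
    return fld, np.array(errs)


@pytest.fixture(scope="session")
def population_thresholds(epineural_field, penetrating_field):
    """Reduced-scale population study: realistic and random models against
    both electrodes (the desk-scale stand-in for the full-size study)."""
    from drgstim.population import place_random, place_realistic
    from drgstim.stimulation import ModelCache, run_thresholds

    n = 500
    pops = {
        "realistic": place_realistic(n, seed=21),
        "random": place_random(n, seed=22),
    }
    fields = {"epineural": epineural_field, "penetrating": penetrating_field}
    cache = ModelCache()
    results = {}
    for mname, pop in pops.items():
        for kind, fld in fields.items():
            results[(mname, kind)] = run_thresholds(pop, fld, cache=cache)
    return {"results": results, "populations": pops, "cache": cache}


@pytest.fixture(scope="session")
def shift_thresholds(population_thresholds):
    """Electrode-shift study on a fixed subset of the realistic model."""
    from drgstim.stimulation import run_thresholds

    pop = population_thresholds["populations"]["realistic"]
    cache = population_thresholds["cache"]
    rng = np.random.default_rng(5)
    subset = np.sort(rng.choice(pop.table.index.to_numpy(), size=150,
                                replace=False))
    sub_ids = set(pop.table.loc[subset, "id"].tolist())
    out = {}
    for kind in ("epineural", "penetrating"):
        center = population_thresholds["results"][("realistic", kind)]
        out[(kind, "center")] = center[center.id.isin(sub_ids)].reset_index(
            drop=True
        )
        for label, sh in [("+0.75x", (0.75, 0, 0)), ("-0.75x", (-0.75, 0, 0)),
                          ("+0.75z", (0, 0, 0.75))]:
            fld = solve_electrode_field(
                electrode=ElectrodeSpec(kind=kind, shift=sh)
            )
            out[(kind, label)] = run_thresholds(pop, fld, cache=cache,
                                                indices=subset)
    return out
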