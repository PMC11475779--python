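"""Cable integrator: resting stability, passive oracle, propagation,
metric extraction."""

import numpy as np
import pytest

from drgstim.neuron import (
    build_axon_of_passage,
    build_neuron,
    integrate,
    measure_ap_metrics,
    resting_state,
    spike_time,
)
from drgstim.neuron.cable import _static_sums, gate_tables, _run, initial_state
from drgstim.neuron.morphology import (
    BR_DORSAL,
    BR_PERIPHERAL,
    CompartmentModel,
    T_JUNCTION,
)
from drgstim.fixtures import template_trace


@pytest.mark.parametrize("d", [6.0, 10.0, 16.0, 20.0])
def test_resting_stability_under_1mv(d):
    """Zero drive for 10 ms moves no compartment by more than 1 mV."""
    n = build_neuron(d)
    vi, vp, g = resting_state(n)
    vm0 = vi - vp
    res = integrate(n, state=(vi, vp, g), dt=0.005, duration=10.0, record=True)
    drift = np.abs(res.traces - vm0[:, None]).max()
    assert drift < 1.0


def _uniform_passive_cable(n_seg=240, seg_len=50.0, diam=10.0, gl=0.001):
    """Uniform unmyelinated leaky cable for the analytic steady-state
    oracle."""
    nseg = n_seg
    parent = np.arange(-1, nseg - 1, dtype=np.int32)
    length = np.full(nseg, seg_len)
    diameter = np.full(nseg, diam)
    area = np.pi * diam * seg_len
    rho_um = 70.0 * 1e4
    r_half = rho_um * (seg_len / 2) / (np.pi * diam**2 / 4)
    g_ax = np.zeros(nseg)
    g_ax[1:] = 1e6 / (2 * r_half)
    zeros = np.zeros(nseg)
    model = CompartmentModel(
        parent=parent, length=length, diameter=diameter,
        ctype=np.zeros(nseg, dtype=np.int8),
        branch=np.full(nseg, 1, dtype=np.int8),
        c_mem=np.full(nseg, 2.0 * area * 1e-5),
        g_axial=g_ax, g_peri=np.full(nseg, 1e-6),
        x_g=zeros.copy(), x_c=zeros.copy(),
        bare=np.ones(nseg, dtype=bool),
        gnaf=zeros.copy(), gnap=zeros.copy(), gks=zeros.copy(),
        gkf=zeros.copy(), glk=np.full(nseg, gl * area * 1e-2),
        gh=zeros.copy(),
        e_leak=np.full(nseg, -80.0),
        arc=np.arange(nseg) * seg_len,
    )
    return model


def test_passive_cable_steady_state_matches_exponential_within_2pct():
    """With active channels absent, the steady-state voltage profile decays
    as exp(-x/lambda) along a uniform leaky cable (sealed-end analytic
    solution)."""
    seg_len, diam, gl = 50.0, 10.0, 0.001
    m = _uniform_passive_cable(seg_len=seg_len, diam=diam, gl=gl)
    vi, vp, g = initial_state(m)
    res = integrate(m, state=(vi, vp, g), istim=(0, 0.5, 0.0, 100.0),
                    dt=0.05, duration=100.0, record=True)
    v = res.traces[:, -1] + 80.0  # deviation from rest
    # lambda in um for d in um, Ri Ohm*cm, gl S/cm2
    lam = np.sqrt((diam * 1e-4) / (4 * 70.0 * gl)) * 1e4
    x = m.arc
    L = x[-1]
    # sealed-end cable of finite length: cosh((L-x)/lam)/cosh(L/lam)
    ref = v[0] * np.cosh((L - x) / lam) / np.cosh(L / lam)
    sel = (x > 0.5 * lam) & (x < 2.5 * lam)
    assert np.all(np.abs(v[sel] - ref[sel]) / ref[sel] < 0.02)


def test_spike_crosses_t_junction_into_dorsal_branch():
    """A suprathreshold pulse at a mid-peripheral node propagates through
    the t-junction and continues down the dorsal root axon."""
    n = build_neuron(9.0)
    per = n.node_indices(BR_PERIPHERAL)
    dor = n.node_indices(BR_DORSAL)
    tj = np.flatnonzero(n.ctype == T_JUNCTION)[0]
    vi, vp, g = resting_state(n)
    res = integrate(
        n, state=(vi, vp, g), istim=(per[25], 10.0, 1.0, 1.1),
        dt=0.005, duration=10.0, record=np.array([tj, dor[10], dor[40]]),
    )
    t_tj = spike_time(res.traces[0], 0.005)
    t_d10 = spike_time(res.traces[1], 0.005)
    t_d40 = spike_time(res.traces[2], 0.005)
    assert t_tj is not None and t_d10 is not None and t_d40 is not None
    assert t_tj < t_d10 < t_d40  # orthodromic continuation


def test_hines_solve_matches_dense_linear_solve():
    """One implicit step of the tree solver equals a dense solve of the
    same 2x2-block system."""
    m = build_axon_of_passage(10.0, n_nodes=4)
    dt = 0.005
    rng = np.random.default_rng(0)
    vi, vp, gates = initial_state(m)
    vi += rng.normal(0, 5, m.n)
    vp += rng.normal(0, 1, m.n)
    vi0, vp0, g0 = vi.copy(), vp.copy(), gates.copy()
    ga_sum, gp_sum = _static_sums(m)
    xinf, xexp = gate_tables(dt, m.ks_beta_a)
    ft = np.empty(m.n)
    fd = np.empty(m.n)
    _run(
        m.parent, m.c_mem, m.g_axial, m.g_peri, m.x_g, m.x_c, m.bare,
        ga_sum, gp_sum, m.gnaf, m.gnap, m.gks, m.gkf, m.glk, m.gh,
        m.e_leak, m.is_axon_node, vi, vp, gates,
        np.zeros(m.n), np.zeros(2), 1, 5.0, 0, 1, dt, 1, xinf, xexp,
        0, 0, np.empty(0, dtype=np.int64), np.empty((0, 2)), ft, fd,
    )
    A, b = _dense_system(m, vi0, vp0, g0, dt, xinf, xexp, stim=(1, 5.0))
    x = np.linalg.solve(A, b)
    assert np.abs(x[0::2] - vi).max() < 1e-9
    assert np.abs(x[1::2] - vp).max() < 1e-9


def _dense_system(m, vi0, vp0, g0, dt, xinf, xexp, stim):
    from drgstim.neuron.channels import E_H, E_K, E_NA

    def lerp(tab, g, v):
        f = (v - (-500.0)) / 0.05
        k = int(f)
        return tab[g, k] + (f - k) * (tab[g, k + 1] - tab[g, k])

    vm_old = vi0 - vp0
    gates = g0.copy()
    n = m.n
    A = np.zeros((2 * n, 2 * n))
    b = np.zeros(2 * n)
    for i in range(n):
        v = vm_old[i]
        gtot = m.glk[i]
        se = m.glk[i] * m.e_leak[i]
        if m.gnaf[i] > 0 or m.gnap[i] > 0:
            for g in range(3):
                inf, ex = lerp(xinf, g, v), lerp(xexp, g, v)
                gates[g, i] = inf + (gates[g, i] - inf) * ex
            gna = m.gnaf[i] * gates[0, i] ** 3 * gates[1, i] \
                + m.gnap[i] * gates[2, i] ** 3
            gtot += gna
            se += gna * E_NA
        if m.gks[i] > 0:
            inf, ex = lerp(xinf, 3, v), lerp(xexp, 3, v)
            gates[3, i] = inf + (gates[3, i] - inf) * ex
            gk = m.gks[i] * gates[3, i]
            gtot += gk
            se += gk * E_K
        if m.gkf[i] > 0:
            inf, ex = lerp(xinf, 4, v), lerp(xexp, 4, v)
            gates[4, i] = inf + (gates[4, i] - inf) * ex
            gk = m.gkf[i] * gates[4, i] ** 4
            gtot += gk
            se += gk * E_K
        if m.gh[i] > 0:
            inf, ex = lerp(xinf, 5, v), lerp(xexp, 5, v)
            gates[5, i] = inf + (gates[5, i] - inf) * ex
            gq = m.gh[i] * gates[5, i]
            gtot += gq
            se += gq * E_H
        cdt = m.c_mem[i] / dt
        mm = cdt + gtot
        A[2 * i, 2 * i] += mm
        A[2 * i, 2 * i + 1] -= mm
        b[2 * i] += cdt * vm_old[i] + se
        if m.bare[i]:
            A[2 * i + 1, 2 * i + 1] = 1.0
        else:
            xcdt = m.x_c[i] / dt
            A[2 * i + 1, 2 * i] -= mm
            A[2 * i + 1, 2 * i + 1] += mm + xcdt + m.x_g[i]
            b[2 * i + 1] += -cdt * vm_old[i] - se + xcdt * vp0[i]
        if i == stim[0]:
            b[2 * i] += stim[1]
    for i in range(1, n):
        p = m.parent[i]
        A[2 * i, 2 * i] += m.g_axial[i]
        A[2 * i, 2 * p] -= m.g_axial[i]
        A[2 * p, 2 * p] += m.g_axial[i]
        A[2 * p, 2 * i] -= m.g_axial[i]
        if not m.bare[i]:
            A[2 * i + 1, 2 * i + 1] += m.g_peri[i]
            A[2 * i + 1, 2 * p + 1] -= m.g_peri[i]
        if not m.bare[p]:
            A[2 * p + 1, 2 * p + 1] += m.g_peri[i]
            A[2 * p + 1, 2 * i + 1] -= m.g_peri[i]
    return A, b


class TestAPMetrics:
    def test_constructed_trace_amplitude_and_ahp(self):
        tr = template_trace(rest=-80.0, peak=30.0, trough=-85.0)
        m = measure_ap_metrics(tr, 0.005, -80.0)
        assert m.amplitude == pytest.approx(110.0, abs=0.5)
        assert m.ahp == pytest.approx(5.0, abs=0.5)
        assert m.duration is not None and m.duration > 0

    def test_flat_trace_reports_no_spike(self):
        m = measure_ap_metrics(np.full(2001, -80.0), 0.005, -80.0)
        assert not m.has_spike
        assert m.amplitude is None and m.duration is None and m.ahp is None

    def test_half_width_shorter_than_base_width(self):
        tr = template_trace()
        base = measure_ap_metrics(tr, 0.005, -80.0, duration_mode="base")
        half = measure_ap_metrics(tr, 0.005, -80.0, duration_mode="half_width")
        assert half.duration < base.duration


def test_ap_metrics_consistent_across_dt_halving(validation_table):
    """Halving the 5 us step changes the AP amplitude metrics by < 2%."""
    from drgstim.validation import validate_neuron

    v5 = validation_table[validation_table.diameter_um == 7.3].iloc[0]
    v25 = validate_neuron(7.3, dt=0.0025)
    assert v25.soma_amplitude == pytest.approx(
        v5.soma_ap_amplitude_mv, rel=0.02
    )
    assert v25.axon_amplitude == pytest.approx(
        v5.axon_ap_amplitude_mv, rel=0.02
    )


def test_trace_hdf5_round_trip(tmp_path):
    import h5py

    a = build_axon_of_passage(8.0, n_nodes=11)
    vi, vp, g = resting_state(a)
    res = integrate(a, state=(vi, vp, g), dt=0.005, duration=1.0,
                    record=np.array([0, 5]))
    path = tmp_path / "traces.h5"
    res.save_traces(path, diameter=8.0)
    with h5py.File(path) as f:
        assert f["v_mV"].shape == res.traces.shape
        assert f.attrs["dt_ms"] == 0.005
        assert f.attrs["diameter"] == 8.0


def test_cv_consistent_across_node_pairs():
    """CV measured over two different mid-axon node pairs differs by < 5%
    (uniform saltatory propagation)."""
    from drgstim.neuron import measure_cv

    n = build_neuron(10.0)
    cv1 = measure_cv(n, node_a=12, node_b=30, stim_amp_na=10.0)
    cv2 = measure_cv(n, node_a=15, node_b=33, stim_amp_na=10.0)
    assert abs(cv1 - cv2) / cv1 < 0.05
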