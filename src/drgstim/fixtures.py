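"""Programmatic test fixtures: toy fields, small populations, synthetic
traces.

Everything here is generated at call time from closed forms or the
package's own generators — no stored data.  The toy field is an analytic
point-source field (not a solver product), the toy population is a small
collision-free realistic placement, and the template traces are synthetic
spike waveforms with known amplitude/AHP for exercising the AP metrics.
"""

from __future__ import annotations

import numpy as np

from .population.placement import Population, place_realistic
from .volume.field import PotentialField


def toy_field(
    sigma: float = 0.25,
    halfwidth: float = 3.0,
    resolution: float = 0.1,
    source=(0.0, 1.5, 0.0),
    seed: int = 0,
) -> PotentialField:
    """Analytic point-source transfer field on a small grid (V per mA)."""
    n = int(round(2 * halfwidth / resolution))
    ax = (np.arange(n) - (n - 1) / 2.0) * resolution
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    src = np.asarray(source)
    r = np.sqrt((X - src[0]) ** 2 + (Y - src[1]) ** 2 + (Z - src[2]) ** 2)
    r = np.maximum(r, resolution / 2.0) * 1e-3  # m
    phi = 1e-3 / (4 * np.pi * sigma * r)  # V per mA
    return PotentialField(
        values=phi, axes=(ax, ax, ax), electrode_kind="toy",
        contact_center=tuple(src),
    )


def toy_population(n: int = 20, seed: int = 0) -> Population:
    """Small collision-free realistic placement."""
    return place_realistic(n, seed=seed)


def template_trace(
    rest: float = -80.0,
    peak: float = 30.0,
    trough: float = -85.0,
    dt: float = 0.005,
    duration: float = 10.0,
    spike_time: float = 2.0,
    spike_width: float = 0.4,
    ahp_width: float = 2.0,
) -> np.ndarray:
    """Synthetic single-spike trace with known amplitude and AHP.

    Gaussian spike and AHP lobes around `spike_time`; amplitude is exactly
    peak - rest and the AHP is rest - trough.
    """
    t = np.arange(int(round(duration / dt)) + 1) * dt
    v = np.full_like(t, rest)
    v += (peak - rest) * np.exp(-0.5 * ((t - spike_time) / (spike_width / 4)) ** 2)
    t_ahp = spike_time + spike_width
    v += (trough - rest) * np.exp(-0.5 * ((t - t_ahp) / (ahp_width / 4)) ** 2)
    # ensure the exact extrema are hit regardless of sampling
    v[np.argmin(np.abs(t - spike_time))] = peak
    v[np.argmin(np.abs(t - t_ahp))] = trough
    return v


def generate_fixtures(kind: str, seed: int = 0, outdir=None):
    """CLI entry: write a fixture of the requested kind.

    kinds: toy_field (HDF5), toy_population (CSV), template_traces (CSV).
    """
    import pathlib

    outdir = pathlib.Path(outdir or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "toy_field":
        f = toy_field(seed=seed)
        path = outdir / "toy_field.h5"
        f.save(path)
    elif kind == "toy_population":
        pop = toy_population(seed=seed)
        path = outdir / "toy_population.csv"
        pop.to_csv(path)
    elif kind == "template_traces":
        import pandas as pd

        tr = template_trace()
        path = outdir / "template_traces.csv"
        pd.DataFrame({"t_ms": np.arange(tr.size) * 0.005, "v_mv": tr}).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return path
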