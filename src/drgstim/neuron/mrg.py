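"""Continuous-diameter fits to the MRG double-cable axon geometry.

The MRG model (McIntyre, Richardson & Grill) tabulates the geometry of a
myelinated mammalian axon — node/paranode dimensions, internodal spacing and
myelin lamella count — at nine discrete fiber diameters between 5.7 and
16 um.  DRG populations contain a continuum of fiber calibers, so every
geometric property is interpolated with a shape-preserving monotone cubic
(PCHIP) through the published table and extended linearly beyond it.  The
interpolant is exact at the table knots and monotone between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

# Published MRG geometry table, one column per fiber diameter (um).
MRG_DIAMETERS = np.array([5.7, 7.3, 8.7, 10.0, 11.5, 12.8, 14.0, 15.0, 16.0])
MRG_TABLE = {
    # node-to-node separation (internodal length, um)
    "internodal_length": np.array(
        [500.0, 750.0, 1000.0, 1150.0, 1250.0, 1350.0, 1400.0, 1450.0, 1500.0]
    ),
    # node of Ranvier / MYSA diameter (um)
    "node_diameter": np.array([1.9, 2.4, 2.8, 3.3, 3.7, 4.2, 4.7, 5.0, 5.5]),
    # axon (FLUT / STIN) diameter under the myelin (um)
    "axon_diameter": np.array([3.4, 4.6, 5.8, 6.9, 8.1, 9.2, 10.4, 11.5, 12.7]),
    # paranode main segment (FLUT) length (um)
    "flut_length": np.array([35.0, 38.0, 40.0, 46.0, 50.0, 54.0, 56.0, 58.0, 60.0]),
    # number of myelin lamellae
    "lamellae": np.array([80.0, 100.0, 110.0, 120.0, 130.0, 135.0, 140.0, 145.0, 150.0]),
}

NODE_LENGTH = 1.0  # um
MYSA_LENGTH = 3.0  # um
N_STIN = 6  # STIN segments per internode

# periaxonal space widths (um) by segment class
PERIAXONAL_WIDTH = {"node": 0.002, "mysa": 0.002, "flut": 0.004, "stin": 0.004}

DIAMETER_RANGE = (6.0, 20.0)


class _LinearTailPchip:
    """PCHIP interpolant with linear extrapolation beyond the knot range."""

    def __init__(self, x: np.ndarray, y: np.ndarray):
        self._x0, self._x1 = x[0], x[-1]
        self._p = PchipInterpolator(x, y, extrapolate=False)
        d = self._p.derivative()
        self._y0, self._s0 = y[0], float(d(x[0]))
        self._y1, self._s1 = y[-1], float(d(x[-1]))

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        out = self._p(np.clip(x, self._x0, self._x1))
        lo = x < self._x0
        hi = x > self._x1
        out[lo] = self._y0 + self._s0 * (x[lo] - self._x0)
        out[hi] = self._y1 + self._s1 * (x[hi] - self._x1)
        return float(out[0]) if scalar else out


@dataclass
class MorphologyFits:
    """Smooth maps from peripheral fiber diameter to axon geometry.

    Valid on ``DIAMETER_RANGE`` = [6, 20] um; linear in diameter outside the
    tabulated [5.7, 16] um span.
    """

    fits: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.fits:
            self.fits = {
                k: _LinearTailPchip(MRG_DIAMETERS, v) for k, v in MRG_TABLE.items()
            }

    def __getattr__(self, name):
        try:
            return self.fits[name]
        except KeyError:
            raise AttributeError(name) from None

    def stin_length(self, d):
        """Length of one of the six STIN segments (um)."""
        total = (
            self.fits["internodal_length"](d)
            - NODE_LENGTH
            - 2 * MYSA_LENGTH
            - 2 * self.fits["flut_length"](d)
        )
        return total / N_STIN


def fit_mrg_parameters(
    diameters: np.ndarray | None = None, table: dict | None = None
) -> MorphologyFits:
    """Fit continuous morphology curves from a tabulated MRG parameter set.

    Parameters default to the published nine-diameter MRG table.  A custom
    table must provide at least two points per property.
    """
    if diameters is None and table is None:
        return MorphologyFits()
    diameters = np.asarray(diameters, dtype=float)
    if diameters.size < 2:
        raise ValueError("need at least 2 tabulated diameters per property")
    fits = {}
    for key, values in table.items():
        values = np.asarray(values, dtype=float)
        if values.size != diameters.size:
            raise ValueError(f"property {key!r} length mismatch with diameters")
        fits[key] = _LinearTailPchip(diameters, values)
    return MorphologyFits(fits=fits)
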