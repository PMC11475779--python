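"""Fiber-diameter sampling for DRG populations.

Peripheral fiber diameters follow a lognormal distribution truncated to
the modelled [6, 20] um caliber range (Aalpha + Abeta fibers only).  The
default shape parameters place the mode near 9 um, consistent with
myelinated-fiber histograms from feline DRG histology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..neuron.mrg import DIAMETER_RANGE


@dataclass
class DiameterDistribution:
    """Truncated lognormal over [lower, upper] um.

    ``mu``/``sigma`` parametrize log-diameter; defaults give a unimodal
    density with mode ~9 um.
    """

    mu: float = 2.2597  # ln(9) + sigma^2
    sigma: float = 0.25
    lower: float = DIAMETER_RANGE[0]
    upper: float = DIAMETER_RANGE[1]

    def validate(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not (0 < self.lower < self.upper):
            raise ValueError("truncation bounds must satisfy 0 < lower < upper")

    def _dist(self):
        return stats.lognorm(s=self.sigma, scale=np.exp(self.mu))

    def cdf_bounds(self):
        d = self._dist()
        return d.cdf(self.lower), d.cdf(self.upper)

    def median(self) -> float:
        """Analytic median of the truncated distribution."""
        d = self._dist()
        lo, hi = self.cdf_bounds()
        return float(d.ppf(lo + 0.5 * (hi - lo)))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        self.validate()
        if n < 0:
            raise ValueError("n must be >= 0")
        d = self._dist()
        lo, hi = self.cdf_bounds()
        u = rng.uniform(lo, hi, size=n)
        return d.ppf(u)


def sample_diameters(
    n: int,
    distribution: DiameterDistribution | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw n fiber diameters (um); reproducible for a given seed."""
    dist = distribution or DiameterDistribution()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return dist.sample(n, rng)
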