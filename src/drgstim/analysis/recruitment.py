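"""Population-level recruitment and selectivity metrics.

Implements the electrode threshold (minimum amplitude activating one
neuron), repeated random subsampling of simulated threshold sets,
initiation-site count vectors over the five site categories for the first
k activated cells, the similarity score between two site-count vectors,
recruitment curves on a 1 uA amplitude grid with dynamic-range slopes, and
per-fiber-type recruitment curves.

The similarity score between site-count vectors N1, N2 is the coefficient
of determination of the identity line,

    S = 1 - sum((N2_i - N1_i)^2) / sum((N2_i - mean(N2))^2),

which equals 1 for identical vectors and can be negative for strongly
divergent ones.  An OLS-with-intercept R^2 mode is provided for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..neuron.morphology import (
    SITE_AIS,
    SITE_PASSAGE,
    SITE_PU_AXON,
    SITE_STEM,
    SITE_TJUNCTION,
)

SITE_CATEGORIES = (SITE_AIS, SITE_STEM, SITE_TJUNCTION, SITE_PU_AXON, SITE_PASSAGE)


@dataclass
class SubsampleSpec:
    """Repeated random subsampling of simulated neurons."""

    size: int = 2500
    repetitions: int = 100
    seed: int = 0

    def validate(self, available: int) -> None:
        if self.size > available:
            raise ValueError(
                f"subsample size {self.size} exceeds available entities "
                f"({available})"
            )


def electrode_threshold(thresholds) -> float:
    """Minimum stimulation amplitude (uA) at which one neuron is activated."""
    t = np.asarray(pd.Series(thresholds).dropna(), dtype=float)
    if t.size == 0:
        raise ValueError("no activated neuron in the threshold set")
    return float(t.min())


def subsample(results: pd.DataFrame, spec: SubsampleSpec,
              eligible=None) -> list[pd.DataFrame]:
    """Random subsamples (without replacement) of a threshold table.

    ``eligible`` restricts sampling (e.g. the region filter of the
    axon-only model).  Deterministic under the configured seed.
    """
    df = results if eligible is None else results.loc[eligible]
    spec.validate(len(df))
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.repetitions):
        idx = rng.choice(len(df), size=spec.size, replace=False)
        out.append(df.iloc[np.sort(idx)])
    return out


def site_count_vector(results: pd.DataFrame, k: int = 20) -> np.ndarray:
    """Counts over the five site categories for the first k activated cells.

    Cells are ordered by ascending threshold with ties broken by id.
    """
    act = results.dropna(subset=["threshold_ua"])
    if len(act) < k:
        raise ValueError(f"only {len(act)} activated cells, need {k}")
    first = act.sort_values(["threshold_ua", "id"]).head(k)
    counts = first.site.value_counts()
    return np.array([counts.get(c, 0) for c in SITE_CATEGORIES], dtype=float)


def first_k_sites(
    subsamples: list[pd.DataFrame], k: int = 20, aggregate: str = "median"
) -> np.ndarray:
    """Median (across repetitions) site-count vector for the first k cells."""
    vecs = np.array([site_count_vector(s, k) for s in subsamples])
    if aggregate == "median":
        return np.median(vecs, axis=0)
    if aggregate == "none":
        return vecs
    raise ValueError(f"unknown aggregate {aggregate!r}")


def similarity_score(n1, n2, mode: str = "identity") -> float:
    """Similarity S between two site-count vectors (see module docstring).

    mode "identity": coefficient of determination about the identity line
    (can be negative).  mode "ols": R^2 of an ordinary least-squares
    regression of n2 on n1 (non-negative).
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if n1.shape != n2.shape:
        raise ValueError("site-count vectors must have the same length")
    ss_tot = np.sum((n2 - n2.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("zero-variance site-count vector; S is undefined")
    if mode == "identity":
        return float(1.0 - np.sum((n2 - n1) ** 2) / ss_tot)
    if mode == "ols":
        r = np.corrcoef(n1, n2)[0, 1]
        return float(r**2)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class RecruitmentCurve:
    amplitudes: np.ndarray  # uA grid from the electrode threshold
    counts: np.ndarray  # cumulative activated neurons

    @property
    def total(self) -> int:
        return int(self.counts[-1])


@dataclass
class DynamicRangeFit:
    slope: float  # neurons per uA over the linear segment
    lo_amp: float
    hi_amp: float
    degenerate: bool = False


def recruitment_curve(thresholds, step: float = 1.0,
                      max_span: float | None = None) -> RecruitmentCurve:
    """Cumulative activated count at `step`-uA increments above threshold."""
    t = np.asarray(pd.Series(thresholds).dropna(), dtype=float)
    if t.size < 1:
        raise ValueError("no activated neurons")
    lo = t.min()
    hi = t.max() if max_span is None else min(t.max(), lo + max_span)
    amps = lo + step * np.arange(int(np.ceil((hi - lo) / step)) + 2)
    counts = np.searchsorted(np.sort(t), amps, side="right")
    return RecruitmentCurve(amplitudes=amps, counts=counts.astype(float))


def dynamic_range_slope(curve: RecruitmentCurve,
                        window: tuple = (0.10, 0.90)) -> DynamicRangeFit:
    """Least-squares slope over the linear segment of a recruitment curve.

    The linear segment is the contiguous amplitude window between the
    configured fractions (default 10%-90%) of the final count.
    """
    c = curve.counts
    total = c[-1]
    lo_c, hi_c = window[0] * total, window[1] * total
    mask = (c >= lo_c) & (c <= hi_c)
    if mask.sum() < 2:
        return DynamicRangeFit(slope=np.inf, lo_amp=curve.amplitudes[0],
                               hi_amp=curve.amplitudes[-1], degenerate=True)
    x = curve.amplitudes[mask]
    y = c[mask]
    slope = float(np.polyfit(x, y, 1)[0])
    return DynamicRangeFit(slope=slope, lo_amp=float(x[0]), hi_amp=float(x[-1]))


def fiber_type_curves(results: pd.DataFrame, step: float = 1.0) -> dict:
    """Per-fiber-type recruitment curves on a common amplitude grid.

    The per-type curves partition the total curve: at every grid amplitude
    the type counts sum to the overall count.
    """
    act = results.dropna(subset=["threshold_ua"])
    total = recruitment_curve(act.threshold_ua, step=step)
    out = {"total": total}
    for ft in ("Aalpha", "Abeta"):
        t = act.loc[act.fiber_type == ft, "threshold_ua"].to_numpy()
        counts = np.searchsorted(np.sort(t), total.amplitudes, side="right")
        out[ft] = RecruitmentCurve(amplitudes=total.amplitudes,
                                   counts=counts.astype(float))
    return out


def electrode_shift_experiment(
    population,
    electrode_kind: str,
    shifts: dict | None = None,
    spec: SubsampleSpec | None = None,
    k: int = 20,
    indices=None,
    cache=None,
    solve_kwargs: dict | None = None,
) -> dict:
    """Re-run thresholds for shifted electrode positions and compare.

    ``shifts`` maps labels to (dx, dy, dz) in mm and defaults to the
    centered position plus +-0.75 mm longitudinal and +0.75 mm lateral.
    Returns {"thresholds": {label: table}, "similarity": {label: S vs
    center}, "slopes": {label: dynamic-range slope}}.
    """
    from ..stimulation.runner import run_thresholds
    from ..volume.geometry import ElectrodeSpec
    from ..volume.solver import solve_electrode_field

    if shifts is None:
        shifts = {
            "center": (0.0, 0.0, 0.0),
            "+0.75x": (0.75, 0.0, 0.0),
            "-0.75x": (-0.75, 0.0, 0.0),
            "+0.75z": (0.0, 0.0, 0.75),
        }
    spec = spec or SubsampleSpec(size=100, repetitions=20, seed=0)
    tables = {}
    for label, sh in shifts.items():
        fld = solve_electrode_field(
            electrode=ElectrodeSpec(kind=electrode_kind, shift=sh),
            **(solve_kwargs or {}),
        )
        tables[label] = run_thresholds(population, fld, cache=cache,
                                       indices=indices)
    center = tables["center"]
    others = {lbl: t for lbl, t in tables.items() if lbl != "center"}
    sims = shift_similarities(center, others, spec, k)
    sims["center"] = 1.0
    slopes = {}
    for label, t in tables.items():
        fit = dynamic_range_slope(recruitment_curve(t.threshold_ua))
        slopes[label] = fit.slope
    return {"thresholds": tables, "similarity": sims, "slopes": slopes}


def shift_similarities(
    center_results: pd.DataFrame,
    shifted_results: dict,
    spec: SubsampleSpec,
    k: int = 20,
) -> dict:
    """Similarity of each shifted electrode's site pattern to the centered one.

    ``shifted_results`` maps shift labels to threshold tables; returns
    {label: S(center, shift)} computed on median site-count vectors across
    subsample repetitions.
    """
    n_center = first_k_sites(subsample(center_results, spec), k)
    out = {}
    for label, res in shifted_results.items():
        n_shift = first_k_sites(subsample(res, spec), k)
        out[label] = similarity_score(n_center, n_shift)
    return out
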