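"""Recruitment-analysis metrics on synthetic threshold tables."""

import numpy as np
import pandas as pd
import pytest

from drgstim.analysis import (
    SITE_CATEGORIES,
    SubsampleSpec,
    dynamic_range_slope,
    electrode_threshold,
    fiber_type_curves,
    first_k_sites,
    recruitment_curve,
    similarity_score,
    site_count_vector,
    subsample,
)


def _table(thresholds, sites=None, types=None):
    n = len(thresholds)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "threshold_ua": thresholds,
            "site": sites if sites is not None else ["AIS"] * n,
            "fiber_type": types if types is not None else ["Abeta"] * n,
        }
    )


class TestElectrodeThreshold:
    def test_single_neuron(self):
        assert electrode_threshold([5.0]) == 5.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            electrode_threshold([np.nan])

    def test_subsample_minimum_bounded_below_by_overall(self):
        rng = np.random.default_rng(0)
        df = _table(rng.uniform(5, 100, 400))
        overall = electrode_threshold(df.threshold_ua)
        for s in subsample(df, SubsampleSpec(size=100, repetitions=10, seed=1)):
            assert electrode_threshold(s.threshold_ua) >= overall


class TestSubsample:
    def test_identity_sample(self):
        df = _table([1.0, 2.0, 3.0])
        out = subsample(df, SubsampleSpec(size=3, repetitions=1, seed=0))
        assert len(out) == 1 and len(out[0]) == 3

    def test_seed_determinism(self):
        df = _table(np.arange(50, dtype=float))
        a = subsample(df, SubsampleSpec(size=10, repetitions=3, seed=5))
        b = subsample(df, SubsampleSpec(size=10, repetitions=3, seed=5))
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)
        c = subsample(df, SubsampleSpec(size=10, repetitions=3, seed=6))
        assert not all(x.equals(y) for x, y in zip(a, c))

    def test_median_invariant_to_repetition_order(self):
        df = _table(np.random.default_rng(2).uniform(1, 50, 80))
        subs = subsample(df, SubsampleSpec(size=40, repetitions=9, seed=3))
        mins = [electrode_threshold(s.threshold_ua) for s in subs]
        assert np.median(mins) == np.median(mins[::-1])

    def test_oversized_sample_rejected(self):
        df = _table([1.0, 2.0])
        with pytest.raises(ValueError):
            subsample(df, SubsampleSpec(size=5, repetitions=1, seed=0))


class TestFirstKSites:
    def test_k1_single_neuron(self):
        df = _table([4.0], sites=["stem"])
        v = site_count_vector(df, k=1)
        assert v.sum() == 1 and v[SITE_CATEGORIES.index("stem")] == 1

    def test_counts_sum_to_k_every_repetition(self):
        rng = np.random.default_rng(1)
        sites = rng.choice(SITE_CATEGORIES, 200)
        df = _table(rng.uniform(1, 90, 200), sites=sites)
        subs = subsample(df, SubsampleSpec(size=100, repetitions=5, seed=2))
        vecs = first_k_sites(subs, k=20, aggregate="none")
        assert np.all(vecs.sum(axis=1) == 20)

    def test_insufficient_activated_rejected(self):
        df = _table([1.0, np.nan, np.nan])
        with pytest.raises(ValueError):
            site_count_vector(df, k=2)


class TestSimilarityScore:
    def test_identical_vectors_give_one(self):
        v = np.array([20.0, 0.0, 0.0, 0.0, 0.0])
        assert similarity_score(v, np.array([5.0, 5.0, 4.0, 3.0, 3.0])) < 1.0
        assert similarity_score(np.array([5, 5, 4, 3, 3]),
                                np.array([5, 5, 4, 3, 3])) == 1.0

    def test_hand_computed_example(self):
        # N1=(20,0,0,0,0), N2=(0,20,0,0,0): S = 1 - 800/320 = -1.5
        s = similarity_score([20, 0, 0, 0, 0], [0, 20, 0, 0, 0])
        assert s == pytest.approx(-1.5)

    def test_matches_brute_force_arithmetic(self):
        rng = np.random.default_rng(3)
        n1 = rng.integers(0, 10, 5).astype(float)
        n2 = n1.copy()
        n2[2] += 4.0  # constant shift in one category
        expected = 1.0 - sum((b - a) ** 2 for a, b in zip(n1, n2)) / sum(
            (b - np.mean(n2)) ** 2 for b in n2
        )
        assert similarity_score(n1, n2) == pytest.approx(expected)

    def test_zero_variance_reported_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            similarity_score([1, 2, 3], [4, 4, 4])

    def test_ols_mode_non_negative(self):
        assert similarity_score([20, 0, 0, 0, 0], [0, 20, 0, 0, 0],
                                mode="ols") >= 0.0


class TestRecruitmentCurve:
    def test_uniform_spread_slope(self):
        # thresholds uniform over [T, T+100]: slope ~ n/100 per uA
        n = 400
        t = 10.0 + 100.0 * (np.arange(n) + 0.5) / n
        curve = recruitment_curve(t)
        fit = dynamic_range_slope(curve)
        assert fit.slope == pytest.approx(n / 100.0, rel=0.05)
        assert not fit.degenerate

    def test_curve_monotone_nondecreasing(self):
        rng = np.random.default_rng(4)
        curve = recruitment_curve(rng.lognormal(3, 1, 200))
        assert np.all(np.diff(curve.counts) >= 0)
        assert curve.counts[0] >= 1

    def test_single_threshold_degenerate(self):
        curve = recruitment_curve([5.0, 5.0, 5.0])
        fit = dynamic_range_slope(curve)
        assert fit.degenerate and np.isinf(fit.slope)


class TestFiberTypeCurves:
    def test_partition_conservation(self):
        rng = np.random.default_rng(5)
        n = 150
        df = _table(
            rng.uniform(1, 60, n),
            types=rng.choice(["Aalpha", "Abeta"], n),
        )
        curves = fiber_type_curves(df)
        assert np.allclose(
            curves["Aalpha"].counts + curves["Abeta"].counts,
            curves["total"].counts,
        )

    def test_single_type_population(self):
        df = _table([1.0, 2.0, 3.0], types=["Abeta"] * 3)
        curves = fiber_type_curves(df)
        assert np.all(curves["Aalpha"].counts == 0)
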