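"""Spline basis, permutation F-test, empirical p-values, pi0 and q-values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import CubicSpline
from scipy.stats import mannwhitneyu

from chronoscreen import ScreenConfig, simulate_screen
from chronoscreen.errors import ConfigurationError, InputError
from chronoscreen.qc import flag_background_tags
from chronoscreen.tagio import combine_tags, compute_profiles, mean_normalize
from chronoscreen.timecourse import (
    F_CAP,
    F_GUARD,
    empirical_pvalues,
    estimate_pi0,
    NullDistribution,
    observed_statistics,
    permutation_null,
    qvalues,
    significant_strains,
    spline_basis,
    strain_statistic,
    timecourse_test,
)

from conftest import profiles_from_layers

DAYS = (3, 9, 11, 15, 20)


def flat_noise_profiles(n=60, sigma=0.3, seed=0):
    rng = np.random.default_rng(seed)
    layers = {}
    for r in (1, 2):
        X = sigma * rng.normal(size=(n, len(DAYS)))
        X[:, 0] = 0.0
        layers[r] = X
    return profiles_from_layers(layers, DAYS)


class TestSplineBasis:
    def test_rank_and_shape(self):
        basis = spline_basis(DAYS, df=3)
        D = basis.design(np.array(DAYS, dtype=float))
        assert D.shape == (5, 4)
        assert np.linalg.matrix_rank(D) == 4

    def test_df1_is_linear(self):
        basis = spline_basis(DAYS, df=1)
        D = basis.design(np.array(DAYS, dtype=float))
        assert D.shape == (5, 2)
        assert np.allclose(D[:, 0], 1.0)
        assert np.allclose(D[:, 1], DAYS)

    def test_spans_natural_cubic_splines(self):
        # with knots at all days the basis must reproduce the natural cubic
        # spline interpolant of arbitrary data, also between the knots
        days = np.array(DAYS, dtype=float)
        rng = np.random.default_rng(5)
        y = rng.normal(size=len(days))
        # interior knots exactly at the interior days for an exact span match
        from chronoscreen.timecourse import NaturalSplineBasis

        basis = NaturalSplineBasis(knots=tuple(days))
        coef = np.linalg.solve(basis.design(days), y)
        oracle = CubicSpline(days, y, bc_type="natural")
        grid = np.linspace(3, 20, 113)
        assert np.allclose(basis.design(grid) @ coef, oracle(grid), atol=1e-10)

    def test_df_bounds(self):
        with pytest.raises(InputError):
            spline_basis(DAYS, df=4)
        with pytest.raises(InputError):
            spline_basis((3, 9), df=1)


class TestStrainStatistic:
    def test_constant_observations_zero_statistic(self):
        basis = spline_basis(DAYS)
        days = np.tile(DAYS, 2)
        f, rss0, rss1 = strain_statistic(days, np.full(10, 1.7), basis)
        assert f == 0.0 and rss0 == pytest.approx(0.0) and rss1 == pytest.approx(0.0)

    def test_exact_linear_trend_hits_guard(self):
        # y = 2t is inside the spline span: rss1 ~ 0, F ~ rss0/guard (capped)
        basis = spline_basis(DAYS)
        days = np.tile(DAYS, 2).astype(float)
        y = 2.0 * days
        f, rss0, rss1 = strain_statistic(days, y, basis)
        expected_rss0 = float(((y - y.mean()) ** 2).sum())
        assert rss0 == pytest.approx(expected_rss0)
        assert rss1 < 1e-18
        assert f == pytest.approx(min(expected_rss0 / F_GUARD, F_CAP), rel=1e-6)

    def test_opposite_trends_cancel(self):
        # replicates with equal means but opposite trends share no trend:
        # the stacked fit finds nothing
        basis = spline_basis(DAYS, df=1)
        days = np.tile(DAYS, 2).astype(float)
        t = np.array(DAYS, dtype=float)
        y = np.concatenate([t - t.mean(), -(t - t.mean())])
        f, rss0, rss1 = strain_statistic(days, y, basis)
        assert f == pytest.approx(0.0, abs=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        basis = spline_basis(DAYS)
        days = np.tile(DAYS, 2).astype(float)
        y = rng.normal(size=10)
        f1, *_ = strain_statistic(days, y, basis)
        f2, *_ = strain_statistic(days, y + 57.3, basis)
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_rss_nesting(self):
        rng = np.random.default_rng(2)
        basis = spline_basis(DAYS)
        days = np.tile(DAYS, 2).astype(float)
        for _ in range(20):
            _, rss0, rss1 = strain_statistic(days, rng.normal(size=10), basis)
            assert rss1 <= rss0 + 1e-12

    def test_too_few_observations(self):
        basis = spline_basis(DAYS)
        with pytest.raises(InputError):
            strain_statistic([3, 9, 11], [0.0, 1.0, 2.0], basis)


class TestPermutationNull:
    def test_pooled_size_bookkeeping(self):
        prof = flat_noise_profiles(n=10)
        null = permutation_null(prof, B=2, seed=0)
        assert null.values.size == 20

    def test_determinism(self):
        prof = flat_noise_profiles(n=15)
        a = permutation_null(prof, B=20, seed=3)
        b = permutation_null(prof, B=20, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_null_consistency_on_flat_data(self):
        # with no real trends the observed statistics are exchangeable with
        # the permutation null: a rank test must not tell them apart.
        # Median over independent datasets, since the pooled null reuses the
        # same strains and a single draw can fluctuate.
        ps = []
        for seed in (8, 20, 21):
            prof = flat_noise_profiles(n=150, sigma=0.3, seed=seed)
            obs = observed_statistics(prof)["F_stat"].to_numpy()
            null = permutation_null(prof, B=60, seed=seed + 100)
            ps.append(mannwhitneyu(obs, null.values, alternative="two-sided").pvalue)
        assert np.median(ps) > 0.01

    def test_invalid_B(self):
        with pytest.raises(InputError):
            permutation_null(flat_noise_profiles(n=5), B=0)


class TestEmpiricalPvalues:
    def test_formula_extremes(self):
        null = NullDistribution(values=np.arange(99.0), B=1, seed=0)
        p = empirical_pvalues([1e6, 0.0], null)
        assert p[0] == pytest.approx(1.0 / 100.0)
        assert p[1] == pytest.approx(1.0)

    def test_median_statistic_gives_half(self):
        rng = np.random.default_rng(0)
        values = rng.exponential(size=10001)
        null = NullDistribution(values=values, B=1, seed=0)
        med = np.median(values)
        p = empirical_pvalues([med], null)
        count = (values >= med).sum()
        assert p[0] == pytest.approx((1 + count) / (1 + len(values)))
        assert p[0] == pytest.approx(0.5, abs=0.01)


class TestPi0AndQvalues:
    def test_pi0_arithmetic(self):
        p = np.concatenate([np.full(50, 0.9), np.full(50, 0.1)])
        assert estimate_pi0(p, 0.5) == pytest.approx(1.0)
        p = np.concatenate([np.full(10, 0.9), np.full(90, 0.1)])
        assert estimate_pi0(p, 0.5) == pytest.approx(0.2)

    def test_pi0_uniform_near_one(self):
        rng = np.random.default_rng(11)
        vals = [estimate_pi0(rng.random(5000)) for _ in range(5)]
        assert all(0.9 <= v <= 1.0 for v in vals)

    def test_pi0_invalid_lambda(self):
        with pytest.raises(ConfigurationError):
            estimate_pi0(np.full(30, 0.5), lam=1.5)

    def test_step_up_hand_example(self):
        q = qvalues([0.01, 0.02, 0.03], pi0=1.0)
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones_give_pi0(self):
        q = qvalues(np.ones(7), pi0=0.6)
        assert np.allclose(q, 0.6)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=80))
    @settings(max_examples=50, deadline=None)
    def test_q_monotone_in_p(self, pvals):
        p = np.array(pvals)
        q = qvalues(p, pi0=1.0)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1.0 + 1e-12).all()

    def test_significant_strain_selection(self):
        res = pd.DataFrame({"q_value": [1.0, 0.05, 0.1, 0.2]},
                           index=["a", "b", "c", "d"])
        assert significant_strains(res, 0.1) == ["b", "c"]
        assert significant_strains(res, 1.0) == ["a", "b", "c", "d"]
        res["q_value"] = 1.0
        assert significant_strains(res) == []


class TestEndToEnd:
    def test_power_monotone_in_effect_size(self):
        # planted linear trends of growing magnitude raise the median F
        rng = np.random.default_rng(13)
        t = np.array(DAYS, dtype=float)
        medians = []
        for slope in (0.0, 0.1, 0.3):
            layers = {}
            for r in (1, 2):
                X = 0.3 * rng.normal(size=(40, 5)) - slope * (t - 3.0)
                X[:, 0] = 0.0
                layers[r] = X
            obs = observed_statistics(profiles_from_layers(layers, DAYS))
            medians.append(obs["F_stat"].median())
        assert medians[0] < medians[1] < medians[2]

    def test_timecourse_test_on_simulated_screen(self, small_profiles):
        cfg, combined, profiles = small_profiles
        res = timecourse_test(profiles, B=100, seed=4)
        ok = res[res["testable"]]
        assert ((ok["p_value"] > 0) & (ok["p_value"] <= 1)).all()
        assert ((ok["q_value"] > 0) & (ok["q_value"] <= 1)).all()
        # q monotone non-decreasing in p
        s = ok.sort_values("p_value")
        assert (s["q_value"].diff().dropna() >= -1e-12).all()
        # smallest attainable p respected
        assert (ok["p_value"] >= 1.0 / (res.attrs["n_null"] + 1) - 1e-15).all()
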